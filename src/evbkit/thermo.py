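"""Closed-form thermodynamic and kinetic conversions.

Eyring transition-state theory links a first-order rate constant to an
activation free energy,

    k = kappa * (k_B*T/h) * exp(-dG_ddagger / (R*T)),

with the transmission coefficient kappa in (0, 1].  Experimental
pseudo-second-order constants (s^-1 M^-1) are treated as effective
first-order at the 1 M standard state before conversion; moving a
bimolecular reference to the 55 M contact (water) concentration subtracts
RT*ln(55) from the barrier.  pKa gaps convert to free energies as
ln(10)*R*T*dpKa, and thermodynamic cycles sum their legs.

Defaults: T = 298.15 K for experiment-side conversions, 300 K on the
simulation side; both always explicit parameters, never hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import KB_OVER_H, R_KCAL, T_EXPERIMENT
from .errors import ValidationError


@dataclass(frozen=True)
class RateResult:
    """A rate constant paired with its activation free energy.

    ``k`` is an effective first-order rate in s^-1 at the stated standard
    state; round-tripping rate -> barrier -> rate is exact to 1e-10
    relative.
    """

    k: float
    dG_ddagger: float
    T: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError(f"rate constant must be positive, got {self.k}")
        if self.T <= 0:
            raise ValidationError(f"temperature must be positive, got {self.T}")
        if not (0.0 < self.kappa <= 1.0):
            raise ValidationError(f"kappa must be in (0, 1], got {self.kappa}")

    def to_dict(self) -> dict:
        return {
            "k_per_s": self.k,
            "dG_ddagger_kcal_mol": self.dG_ddagger,
            "T_kelvin": self.T,
            "kappa": self.kappa,
        }


def _check(k: float | None, dG: float | None, T: float, kappa: float) -> None:
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    if not (0.0 < kappa <= 1.0):
        raise ValidationError(f"kappa must be in (0, 1], got {kappa}")
    if k is not None and k <= 0:
        raise ValidationError(f"rate constant must be positive, got {k}")
    if dG is not None and not math.isfinite(dG):
        raise ValidationError(f"barrier must be finite, got {dG}")


def rate_to_barrier(k: float, T: float = T_EXPERIMENT, kappa: float = 1.0) -> float:
    """Activation free energy (kcal/mol) from an Eyring rate constant.

    ``dG_ddagger = -R*T*ln(k*h / (kappa*k_B*T))``; monotone decreasing in
    ``k`` and zero when ``k`` equals the prefactor ``kappa*k_B*T/h``.
    """
    _check(k, None, T, kappa)
    return -R_KCAL * T * math.log(k / (kappa * KB_OVER_H * T))


def barrier_to_rate(dG_ddagger: float, T: float = T_EXPERIMENT, kappa: float = 1.0) -> float:
    """Eyring rate constant (s^-1) from an activation free energy."""
    _check(None, dG_ddagger, T, kappa)
    return kappa * KB_OVER_H * T * math.exp(-dG_ddagger / (R_KCAL * T))


def rate_result(k: float, T: float = T_EXPERIMENT, kappa: float = 1.0) -> RateResult:
    """Bundle a rate with its derived barrier."""
    return RateResult(k=k, dG_ddagger=rate_to_barrier(k, T, kappa), T=T, kappa=kappa)


def standard_state_shift(conc_ratio: float, T: float = T_EXPERIMENT) -> float:
    """Entropic barrier correction ``R*T*ln(ratio)`` in kcal/mol.

    For ratio 55 (1 M -> 55 M contact concentration of water) at 298.15 K
    this is 2.4 kcal/mol, the amount by which a bimolecular reference
    barrier decreases.
    """
    if conc_ratio <= 0:
        raise ValidationError(f"concentration ratio must be positive, got {conc_ratio}")
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    return R_KCAL * T * math.log(conc_ratio)


def pka_gap_to_dg(delta_pka: float, T: float = T_EXPERIMENT) -> float:
    """Proton-transfer free energy ``ln(10)*R*T*dpKa`` in kcal/mol."""
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    return math.log(10.0) * R_KCAL * T * delta_pka


def cycle_free_energy(terms) -> float:
    """Sum the legs of a thermodynamic cycle (kcal/mol)."""
    total = 0.0
    for t in terms:
        if not math.isfinite(t):
            raise ValidationError(f"non-finite cycle term {t}")
        total += float(t)
    return total
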