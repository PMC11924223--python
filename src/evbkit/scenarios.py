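"""Scenario presets: reference (water) reactions and enzyme emulations.

A :class:`ScenarioSpec` bundles everything one replicate-ensemble run
needs: per-leg topologies, the driving schedule, sampler controls,
replicate count and seed, plus (for reference scenarios) calibration
targets.

The built-in registry mirrors the study design of a kinase
phosphoryl-transfer analysis:

* ``water_dissociative`` — the uncatalyzed reference in two legs
  (metaphosphate formation, then concerted deprotonation/attack), carrying
  the experimentally anchored calibration targets: activation 27.9
  kcal/mol (30.3 from the methanolysis rate minus the 2.4 kcal/mol 1 M ->
  55 M standard-state correction), intermediate plateau 0.5 kcal/mol below
  the maximum, total reaction free energy 0.6 kcal/mol (ATP hydrolysis -9
  plus 9.6 from the ~7-unit pKa gap).
* ``water_associative`` — the concerted reference (27.9 / 0.6).
* ``enzyme_*`` — named parameter presets (NOT structural models) standing
  in for active-site variants: magnesium in Site I, the dissociative
  initial step, the associative path, two magnesium ions, and magnesium in
  Site II.  They reuse the water-calibrated (alpha, H) unchanged — the
  transferability rule — and encode catalytic environment differences in
  the surrogate diabats (offsets and displacements), tuned so the ensemble
  barrier ordering reproduces the qualitative result
  Site I < dissociative-initial < associative < two-Mg < Site II ~ water.

All presets use harmonic diabats with f = 200 kcal/mol/unit^2, so a
displacement d gives reorganization energy lambda_reorg = f*d^2/2 =
100*d^2 kcal/mol, at T = 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibrate import CalibrationTarget
from .errors import ConfigurationError, UnknownScenarioError
from .evb import DiabaticState, EVBTopology
from .fep import LambdaSchedule, make_schedule
from .sampler import SamplerParams, jitter_deltas, sample_all_windows

#: Shared force constant of all preset diabats, kcal/mol/unit^2.
PRESET_F = 200.0
#: Simulation temperature, K.
PRESET_T = 300.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified surrogate study condition.

    ``legs`` holds one two-state topology per sequential reaction step
    (one for associative/concerted runs, two for the dissociative path).
    ``calibration`` optionally holds one :class:`CalibrationTarget` per leg
    (reference scenarios only).  ``reference`` names the water preset whose
    fitted parameters must be transferred before an enzyme run; the
    parameter block is applied unchanged.  ``jitter_sd`` adds a
    per-replicate normal offset to each non-reference diabat constant,
    emulating conformational heterogeneity (0 disables).
    """

    name: str
    mechanism: str
    legs: tuple[EVBTopology, ...]
    sampler: SamplerParams = field(default_factory=SamplerParams)
    n_replicates: int = 30
    master_seed: int = 2026
    calibration: tuple[CalibrationTarget, ...] | None = None
    reference: str | None = None
    jitter_sd: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.mechanism not in ("dissociative", "associative"):
            raise ConfigurationError(
                f"mechanism must be dissociative or associative, got {self.mechanism!r}"
            )
        if not self.legs:
            raise ConfigurationError("scenario needs at least one leg topology")
        if self.n_replicates < 1:
            raise ConfigurationError(
                f"n_replicates must be >= 1, got {self.n_replicates}"
            )
        if self.calibration is not None and len(self.calibration) != len(self.legs):
            raise ConfigurationError("one calibration target per leg required")
        if self.jitter_sd < 0:
            raise ConfigurationError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        object.__setattr__(self, "legs", tuple(self.legs))

    @property
    def n_legs(self) -> int:
        return len(self.legs)

    def schedule(self) -> LambdaSchedule:
        """The per-leg driving schedule of this scenario's mechanism."""
        return make_schedule(self.mechanism)

    def leg_topology(self, leg: int, replicate_index: int | None = None) -> EVBTopology:
        """Leg topology, optionally with this replicate's offset jitter."""
        topo = self.legs[leg]
        if replicate_index is None or self.jitter_sd == 0.0:
            return topo
        deltas = jitter_deltas(
            self.master_seed, replicate_index, topo.n_states, self.jitter_sd
        )
        return topo.with_offset_jitter(deltas)

    def with_parameters(
        self, alpha, coupling, legs: tuple[int, ...] | None = None
    ) -> "ScenarioSpec":
        """Copy with (alpha, coupling) replaced on the given legs (default all)."""
        idx = range(self.n_legs) if legs is None else legs
        new_legs = list(self.legs)
        for i in idx:
            new_legs[i] = new_legs[i].with_params(alpha=alpha, coupling=coupling)
        return replace(self, legs=tuple(new_legs))

    def sample_replicate(self, replicate_index: int):
        """Sample every leg of one replicate; returns a list of window lists."""
        sched = self.schedule()
        out = []
        for leg in range(self.n_legs):
            topo = self.leg_topology(leg, replicate_index)
            out.append(
                sample_all_windows(
                    topo,
                    sched,
                    self.sampler,
                    self.master_seed,
                    replicate_index,
                    leg_index=leg,
                )
            )
        return out


def _leg(
    role_a: str,
    role_b: str,
    d: float,
    alpha2: float,
    h: float,
    ids: tuple[str, str],
    desc: tuple[str, str],
) -> EVBTopology:
    states = (
        DiabaticState(id=ids[0], role=role_a, x0=0.0, f=PRESET_F, description=desc[0]),
        DiabaticState(id=ids[1], role=role_b, x0=d, f=PRESET_F, description=desc[1]),
    )
    return EVBTopology(
        states=states,
        alpha=(0.0, alpha2),
        coupling=((0.0, h), (h, 0.0)),
        temperature=PRESET_T,
    )


def _enzyme_leg(
    role_a: str, role_b: str, d: float, c2: float, alpha2: float, h: float,
    ids: tuple[str, str], desc: tuple[str, str],
) -> EVBTopology:
    """Enzyme leg: environment effect lives in the diabat offset c2; the
    gas-phase shift and coupling are the (provisionally water-valued)
    transferable parameters."""
    states = (
        DiabaticState(id=ids[0], role=role_a, x0=0.0, f=PRESET_F, description=desc[0]),
        DiabaticState(
            id=ids[1], role=role_b, x0=d, f=PRESET_F, c=c2, description=desc[1]
        ),
    )
    return EVBTopology(
        states=states,
        alpha=(0.0, alpha2),
        coupling=((0.0, h), (h, 0.0)),
        temperature=PRESET_T,
    )


# Water reference parameters (provisional values near the calibrated fix
# point; calibration refines them and the pipeline transfers the fitted
# block to the enzyme presets).
WATER_DISS_ALPHA2 = 28.0
WATER_DISS_H = 9.0
WATER_DISS_D = 0.85  # lambda_reorg = 72.25 kcal/mol
WATER_DISS2_ALPHA2 = -27.1
WATER_DISS2_H = 3.6
WATER_DISS2_D = 0.707  # lambda_reorg = 50 kcal/mol
WATER_ASSOC_ALPHA2 = 0.5
WATER_ASSOC_H = 4.9
WATER_ASSOC_D = 1.1402  # lambda_reorg = 130 kcal/mol

_WATER_TARGET_BARRIER = 27.9
_INTERMEDIATE_OFFSET = 0.5
_TOTAL_DG0 = 0.6


def _build_registry() -> dict:
    reg: dict[str, ScenarioSpec] = {}

    reg["water_dissociative"] = ScenarioSpec(
        name="water_dissociative",
        mechanism="dissociative",
        legs=(
            _leg(
                "reactant", "intermediate", WATER_DISS_D, WATER_DISS_ALPHA2,
                WATER_DISS_H, ("R", "MP"),
                ("ATP + TyrOH + Asp-", "ADP + PO3- + TyrOH + Asp-"),
            ),
            _leg(
                "intermediate", "product", WATER_DISS2_D, WATER_DISS2_ALPHA2,
                WATER_DISS2_H, ("MP", "P"),
                ("ADP + PO3- + TyrOH + Asp-", "ADP + TyrOPO3(2-) + AspH"),
            ),
        ),
        n_replicates=10,
        calibration=(
            CalibrationTarget(
                dG_ddagger_target=_WATER_TARGET_BARRIER,
                intermediate_offset_below_max=_INTERMEDIATE_OFFSET,
            ),
            CalibrationTarget(
                dG_ddagger_target=_WATER_TARGET_BARRIER
                - (_WATER_TARGET_BARRIER - _INTERMEDIATE_OFFSET),
                dG0_target=_TOTAL_DG0 - (_WATER_TARGET_BARRIER - _INTERMEDIATE_OFFSET),
            ),
        ),
        description="Uncatalyzed two-step reference reaction in water; carries "
        "the experimentally anchored calibration targets.",
    )

    reg["water_associative"] = ScenarioSpec(
        name="water_associative",
        mechanism="associative",
        legs=(
            _leg(
                "reactant", "product", WATER_ASSOC_D, WATER_ASSOC_ALPHA2,
                WATER_ASSOC_H, ("R", "P"),
                ("ATP + TyrOH + Asp-", "ADP + TyrOPO3(2-) + AspH"),
            ),
        ),
        n_replicates=10,
        calibration=(
            CalibrationTarget(
                dG_ddagger_target=_WATER_TARGET_BARRIER, dG0_target=_TOTAL_DG0
            ),
        ),
        description="Uncatalyzed concerted reference reaction in water.",
    )

    # Enzyme presets: barrier differences are encoded in diabat offsets c2
    # (and displacement), with the water (alpha, H) applied unchanged.
    enzyme = [
        # name, mechanism, d, c2, alpha2, H, reference, blurb
        # (c2 solved so the adiabatic-surface barrier under the water-fitted
        # parameter block lands at the intended emulation target)
        (
            "enzyme_site1", "dissociative", 1.0, -45.8,
            WATER_DISS_ALPHA2, WATER_DISS_H, "water_dissociative",
            "Single magnesium ion in Site I (beta/gamma phosphoryls + DFG "
            "aspartate); strongest metaphosphate stabilization.",
        ),
        (
            "enzyme_dissociative", "dissociative", 1.0, -30.4,
            WATER_DISS_ALPHA2, WATER_DISS_H, "water_dissociative",
            "Dissociative initial step (metaphosphate formation) in the "
            "enzyme active site.",
        ),
        (
            "enzyme_associative", "associative", 1.1402, -23.7,
            WATER_ASSOC_ALPHA2, WATER_ASSOC_H, "water_associative",
            "Concerted phosphoryl transfer and deprotonation in the enzyme.",
        ),
        (
            "enzyme_two_mg", "associative", 1.1402, -16.1,
            WATER_ASSOC_ALPHA2, WATER_ASSOC_H, "water_associative",
            "Both magnesium cofactors bound; extra charge compensation "
            "raises the barrier above the single-ion paths.",
        ),
        (
            "enzyme_site2", "dissociative", 1.0, -9.7,
            WATER_DISS_ALPHA2, WATER_DISS_H, "water_dissociative",
            "Single magnesium ion in Site II (alpha/gamma bridge); barely "
            "catalytic, on a par with the water reference.",
        ),
    ]
    for name, mech, d, c2, a2, h, ref, blurb in enzyme:
        role_b = "intermediate" if mech == "dissociative" else "product"
        reg[name] = ScenarioSpec(
            name=name,
            mechanism=mech,
            legs=(
                _enzyme_leg(
                    "reactant", role_b, d, c2, a2, h, ("R", "X"),
                    ("enzyme-bound reactants", "enzyme-stabilized " + role_b),
                ),
            ),
            n_replicates=30,
            reference=ref,
            jitter_sd=0.5,
            description=blurb,
        )
    return reg


_REGISTRY = _build_registry()


def scenario_names() -> list[str]:
    return sorted(_REGISTRY)


def builtin_scenario(name: str) -> ScenarioSpec:
    """Look up a preset by name; unknown names list the registry."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None
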