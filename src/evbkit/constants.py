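"""Physical constants used throughout the package.

All free energies are in kcal/mol, temperatures in kelvin, rates in s^-1.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Boltzmann constant over Planck constant, s^-1 K^-1 (Eyring prefactor per kelvin).
KB_OVER_H = 2.0837e10

#: Default temperature for experiment-side conversions (rate constants, pKa), K.
T_EXPERIMENT = 298.15

#: Default temperature for simulation-side conversions, K.
T_SIMULATION = 300.0


def beta(temperature: float) -> float:
    """Inverse temperature 1/(R*T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (R_KCAL * temperature)
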