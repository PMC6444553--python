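"""Physical constants and shared defaults.

Energies are kcal/mol, distances Å, temperatures Kelvin throughout the
package.
"""

#: Gas constant in kcal/mol/K.
R_KCAL: float = 1.9872e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 298.0

#: Coulomb constant in kcal·Å/mol/e² as used in the Born charging formula.
COULOMB_332: float = 332.0

#: Default simulation-sphere radius (Å).
DEFAULT_SPHERE_RADIUS: float = 25.0

#: Positional restraint on atoms outside the sphere (kcal/mol/Å²).
SPHERE_EXCLUSION_RESTRAINT: float = 200.0


def kT(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
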