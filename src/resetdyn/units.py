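"""Internal unit system.

Lengths are in Angstrom, times in femtoseconds, masses in g/mol.
Potential energies are dimensionless multiples of k_B*T at the simulation
temperature, so the Boltzmann constant enters the dynamics only through a
single energy scale ``kt(T)`` (the molar gas constant in internal units
times the temperature) that converts reduced forces to momentum changes.
"""

# R = 8.314462618... J/(mol K) = 1e-7 g Ang^2 fs^-2 mol^-1 K^-1
GAS_CONSTANT = 8.31446261815324e-7

FS_PER_NS = 1.0e6


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in internal units (g/mol * Ang^2 / fs^2)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT * temperature


def thermal_velocity(temperature: float, mass: float) -> float:
    """Standard deviation of each Maxwell-Boltzmann velocity component (Ang/fs)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return (kt(temperature) / mass) ** 0.5
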