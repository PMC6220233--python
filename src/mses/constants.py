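"""Physical constants and unit conversions.

Internal unit system for molecular models: energy in kcal/mol, length in
Angstrom, time in fs, temperature in K, input masses in amu.  Masses are
converted once to "simulation mass" units (kcal/mol * fs^2 / A^2) so that
acceleration = force / mass holds without further factors.  Analytic toy
systems instead run in natural units (k_B = 1, mass = 1).
"""

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872

#: kcal -> kJ.
KCAL_TO_KJ = 4.184

#: 1 kcal/mol/A of force on 1 amu gives 4.184e-4 A/fs^2 of acceleration,
#: so one amu equals 1/4.184e-4 simulation mass units.
AMU_TO_SIM = 1.0 / 4.184e-4

#: Coupling-constant ladder (kcal/mol/A^2) used for the 16-replica
#: Hamiltonian replica-exchange campaigns on the di-ubiquitin systems.
DEFAULT_LADDER = (
    0.0, 0.0002, 0.0005, 0.0011, 0.0021, 0.0037, 0.006, 0.0092,
    0.0135, 0.0192, 0.0265, 0.0357, 0.0471, 0.0611, 0.078, 0.098,
)


def scaled_ladder(k_max: float, n_rungs: int = 16) -> tuple[float, ...]:
    """Ladder with the default 16-rung shape rescaled so its top rung is
    ``k_max``.  For other rung counts the default shape is linearly
    interpolated in rung index.  Rung 0 is always exactly 0."""
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    base = DEFAULT_LADDER
    if n_rungs == len(base):
        shape = base
    else:
        import numpy as np

        x = np.linspace(0, len(base) - 1, n_rungs)
        shape = tuple(float(v) for v in np.interp(x, range(len(base)), base))
    scale = k_max / base[-1]
    out = tuple(k * scale for k in shape)
    return (0.0,) + out[1:]
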