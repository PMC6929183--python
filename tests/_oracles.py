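"""Independent brute-force oracles used by the test suite only.

The TST oracle computes the KIE as a ratio of raw partition-function
expressions (translation × rotation × harmonic vibration measured from the
potential minimum, the reaction-coordinate mode excluded) — no Bigeleisen
factorization, no explicit Teller–Redlich step.  The imaginary-frequency
ratio of the engine's factorized formula is implicit here through the
product rule, so agreement verifies that identity numerically.
"""

import numpy as np

from isokie.systems import MolecularSystem
from isokie.thermo import ThermoSettings
from isokie.vibrations import FrequencySet, IsotopeSubstitution, frequencies_from_hessian


def _partition_function(sysm: MolecularSystem, fs: FrequencySet, th: ThermoSettings) -> float:
    """q_trans·q_rot·q_vib up to isotope-independent prefactors (linear rotor)."""
    m = sysm.masses
    q_trans = m.sum() ** 1.5
    com = (m[:, None] * sysm.coords).sum(axis=0) / m.sum()
    x = sysm.coords - com
    inertia = np.zeros((3, 3))
    for mi, xi in zip(m, x):
        inertia += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
    moments = np.sort(np.linalg.eigvalsh(inertia))
    if moments[0] > 1e-8 * moments[-1]:
        raise ValueError("oracle implemented for linear toys only")
    q_rot = moments[-1]  # linear rotor: single moment of inertia
    u = th.u(fs.real)
    q_vib = np.prod(np.exp(-u / 2.0) / (1.0 - np.exp(-u)))
    return q_trans * q_rot * q_vib


def tst_kie(
    reactant: MolecularSystem,
    ts: MolecularSystem,
    sub: IsotopeSubstitution,
    th: ThermoSettings,
) -> float:
    """Brute-force harmonic-TST rate ratio k_light/k_heavy."""
    r_l = reactant.substitute(sub.atom_index, sub.light_mass)
    r_h = reactant.substitute(sub.atom_index, sub.heavy_mass)
    t_l = ts.substitute(sub.atom_index, sub.light_mass)
    t_h = ts.substitute(sub.atom_index, sub.heavy_mass)
    f_rl, f_rh = frequencies_from_hessian(r_l), frequencies_from_hessian(r_h)
    f_tl, f_th = frequencies_from_hessian(t_l), frequencies_from_hessian(t_h)
    q = _partition_function
    return (q(t_l, f_tl, th) / q(r_l, f_rl, th)) / (
        q(t_h, f_th, th) / q(r_h, f_rh, th)
    )
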