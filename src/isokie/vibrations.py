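"""Harmonic frequency analysis from Cartesian Hessians.

The Hessian is mass-weighted, rigid-body translations and rotations are
projected out in the Eckart frame, and the projected matrix is diagonalized.
Eigenvalues λ (hartree/(bohr²·amu)) map to wavenumbers via
ν̃ = 5140.49·sign(λ)·sqrt(|λ|) cm⁻¹.  A first-order saddle point carries
exactly one negative eigenvalue, reported as the magnitude of the imaginary
wavenumber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .constants import HESSIAN_EIG_TO_CM, ISOTOPE_MASSES
from .systems import MolecularSystem

#: modes with |ν̃| below this (cm⁻¹) after projection are treated as residual
#: rigid-body/free-rotor modes and dropped
RIGID_BODY_CUTOFF_CM = 1.0

#: adjacent-mode spacing below which sorted-order mode matching is unreliable
MODE_CROSSING_WARN_CM = 1.0


class HigherOrderSaddleError(ValueError):
    """More than one imaginary frequency: not a first-order saddle point."""


@dataclass(frozen=True)
class FrequencySet:
    """Harmonic wavenumbers of one isotopolog.

    Attributes
    ----------
    real : ndarray
        Real-mode wavenumbers in cm⁻¹, ascending, all > 0.
    imaginary : float or None
        Magnitude of the single imaginary wavenumber (cm⁻¹) if the species is
        a first-order saddle point, else None.
    n_projected : int
        Number of rigid-body (and residual near-zero) modes removed.
    """

    real: np.ndarray
    imaginary: Optional[float] = None
    n_projected: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "real", np.sort(np.asarray(self.real, dtype=float)))
        if np.any(self.real <= 0):
            raise ValueError("real wavenumbers must be > 0")
        if self.imaginary is not None and not self.imaginary > 0:
            raise ValueError("imaginary wavenumber magnitude must be > 0")

    @property
    def is_saddle(self) -> bool:
        return self.imaginary is not None

    @property
    def n_real(self) -> int:
        return self.real.size


@dataclass(frozen=True)
class IsotopeSubstitution:
    """A single heavy-isotope substitution at one atomic position."""

    atom_index: int
    element: str
    light_mass: float = 0.0
    heavy_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.light_mass == 0.0 or self.heavy_mass == 0.0:
            try:
                light, heavy = ISOTOPE_MASSES[self.element]
            except KeyError:
                raise ValueError(
                    f"no default isotope masses for element {self.element!r}; "
                    "provide light_mass and heavy_mass explicitly"
                ) from None
            object.__setattr__(self, "light_mass", self.light_mass or light)
            object.__setattr__(self, "heavy_mass", self.heavy_mass or heavy)
        if not (self.heavy_mass > self.light_mass > 0):
            raise ValueError("require heavy_mass > light_mass > 0")


def _rigid_body_basis(sys: MolecularSystem) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (Eckart frame)."""
    n = sys.n_atoms
    sqrt_m = np.sqrt(sys.masses)
    com = (sys.masses[:, None] * sys.coords).sum(axis=0) / sys.masses.sum()
    x = sys.coords - com  # Å; overall scale cancels after orthonormalization

    vecs = []
    for axis in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, axis] = sqrt_m
        vecs.append(v.ravel())
    for axis in range(3):  # rotations about Cartesian axes through the COM
        e = np.zeros(3)
        e[axis] = 1.0
        v = np.cross(np.broadcast_to(e, (n, 3)), x) * sqrt_m[:, None]
        vecs.append(v.ravel())

    d = np.array(vecs).T  # (3N, 6)
    # drop linearly dependent rotation(s) (linear molecules) via rank-revealing QR
    q, r = np.linalg.qr(d)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def frequencies_from_hessian(sys: MolecularSystem) -> FrequencySet:
    """Mass-weight, project rigid-body modes, diagonalize, convert to cm⁻¹.

    Raises
    ------
    HigherOrderSaddleError
        If two or more imaginary modes survive projection.
    """
    sqrt_m = np.repeat(np.sqrt(sys.masses), 3)
    h_mw = sys.hessian / np.outer(sqrt_m, sqrt_m)

    d = _rigid_body_basis(sys)
    p = np.eye(h_mw.shape[0]) - d @ d.T
    h_proj = p @ h_mw @ p
    h_proj = 0.5 * (h_proj + h_proj.T)

    eigvals = np.linalg.eigvalsh(h_proj)
    wn = HESSIAN_EIG_TO_CM * np.sign(eigvals) * np.sqrt(np.abs(eigvals))

    near_zero = np.abs(wn) < RIGID_BODY_CUTOFF_CM
    n_projected = int(near_zero.sum())
    wn = wn[~near_zero]

    imag = wn[wn < 0]
    real = np.sort(wn[wn > 0])
    if imag.size >= 2:
        raise HigherOrderSaddleError(
            f"{imag.size} imaginary modes found ({-imag} cm-1): higher-order saddle"
        )
    gaps = np.diff(real)
    # exactly degenerate pairs (symmetry doublets) match safely in sorted
    # order; warn only on near-degeneracy, where isotopic shifts could cross
    if real.size >= 2 and np.any((gaps > 1e-6) & (gaps < MODE_CROSSING_WARN_CM)):
        warnings.warn(
            "adjacent modes closer than 1 cm-1: sorted-order mode matching "
            "across isotopologs may be unreliable",
            stacklevel=2,
        )
    return FrequencySet(
        real=real,
        imaginary=float(-imag[0]) if imag.size == 1 else None,
        n_projected=n_projected,
    )


def isotopolog_frequency_sets(
    sys: MolecularSystem, sub: IsotopeSubstitution
) -> Tuple[FrequencySet, FrequencySet]:
    """Frequency sets of the light and heavy isotopolog of one substitution.

    The Hessian (a Born–Oppenheimer property) is shared; only the mass vector
    changes.  Modes are matched by sorted order, which is safe for the
    symmetry-free toy systems this package ships (a warning is raised when
    adjacent modes are close enough to cross).
    """
    if not 0 <= sub.atom_index < sys.n_atoms:
        raise ValueError(f"atom index {sub.atom_index} out of range")
    if sys.labels[sub.atom_index] != sub.element:
        raise ValueError(
            f"substitution element {sub.element!r} does not match atom "
            f"{sub.atom_index} label {sys.labels[sub.atom_index]!r}"
        )
    light = sys.substitute(sub.atom_index, sub.light_mass)
    heavy = sys.substitute(sub.atom_index, sub.heavy_mass)
    return frequencies_from_hessian(light), frequencies_from_hessian(heavy)
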