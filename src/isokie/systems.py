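"""Molecular systems: geometry, masses, Cartesian Hessian, and plain-text I/O.

The on-disk format is an extended-XYZ block (element, x, y, z, mass — one atom
per line) followed by a ``HESSIAN`` block holding the row-major lower triangle
of the symmetric 3N×3N Cartesian Hessian in hartree/bohr², one matrix row per
line.  Geometries are in Å, masses in amu.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

SYMMETRY_RTOL = 1e-8
LINEARITY_TOL = 1e-8


@dataclass
class MolecularSystem:
    """A molecule (or transition structure) ready for frequency analysis.

    Attributes
    ----------
    labels : list of str
        Element labels, one per atom.
    coords : ndarray, shape (N, 3)
        Cartesian coordinates in Å.
    masses : ndarray, shape (N,)
        Atomic masses in amu.
    hessian : ndarray, shape (3N, 3N)
        Cartesian second-derivative matrix in hartree/bohr², symmetric.
    linear : bool or None
        Linearity flag; ``None`` means "detect from the geometry".
    """

    labels: list
    coords: np.ndarray
    masses: np.ndarray
    hessian: np.ndarray
    linear: Optional[bool] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        self.hessian = np.asarray(self.hessian, dtype=float)
        n = len(self.labels)
        if self.coords.shape != (n, 3):
            raise ValueError("coords shape inconsistent with number of labels")
        if self.masses.shape != (n,):
            raise ValueError("masses length inconsistent with number of labels")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be > 0")
        if self.hessian.shape != (3 * n, 3 * n):
            raise ValueError("hessian must be 3N x 3N")
        scale = max(1.0, float(np.abs(self.hessian).max()))
        if np.abs(self.hessian - self.hessian.T).max() > SYMMETRY_RTOL * scale:
            raise ValueError("hessian is not symmetric to the required tolerance")
        # store the exactly symmetrized matrix
        self.hessian = 0.5 * (self.hessian + self.hessian.T)
        if self.linear is None:
            self.linear = self._detect_linear()

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    def _detect_linear(self) -> bool:
        if self.n_atoms < 3:
            return True
        x = self.coords - self.coords.mean(axis=0)
        s = np.linalg.svd(x, compute_uv=False)
        return bool(s[1] <= LINEARITY_TOL * max(s[0], 1.0))

    def with_masses(self, masses: Sequence[float]) -> "MolecularSystem":
        """Same geometry and Hessian, different mass vector (isotopolog)."""
        return replace(self, masses=np.asarray(masses, dtype=float), linear=self.linear)

    def substitute(self, atom_index: int, new_mass: float) -> "MolecularSystem":
        """Isotopolog with one atomic mass replaced."""
        m = self.masses.copy()
        m[atom_index] = new_mass
        return self.with_masses(m)

    # ------------------------------------------------------------------ I/O
    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write(f"{self.n_atoms}\n")
        buf.write(f"isokie molecular system; linear={self.linear}\n")
        for lab, (x, y, z), m in zip(self.labels, self.coords, self.masses):
            buf.write(f"{lab:<3s} {x: .12f} {y: .12f} {z: .12f} {m:.8f}\n")
        buf.write("HESSIAN\n")
        for i in range(3 * self.n_atoms):
            row = " ".join(f"{self.hessian[i, j]: .14e}" for j in range(i + 1))
            buf.write(row + "\n")
        return buf.getvalue()

    def write(self, path) -> None:
        Path(path).write_text(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "MolecularSystem":
        lines = text.splitlines()
        n = int(lines[0].strip())
        comment = lines[1]
        linear = None
        if "linear=" in comment:
            token = comment.split("linear=")[1].split()[0].strip().lower()
            linear = token in ("true", "1", "yes")
        labels, coords, masses = [], [], []
        for ln in lines[2 : 2 + n]:
            parts = ln.split()
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
            masses.append(float(parts[4]))
        if lines[2 + n].strip().upper() != "HESSIAN":
            raise ValueError("expected HESSIAN block after atom records")
        h = np.zeros((3 * n, 3 * n))
        for i, ln in enumerate(lines[3 + n : 3 + n + 3 * n]):
            vals = [float(v) for v in ln.split()]
            if len(vals) != i + 1:
                raise ValueError(f"HESSIAN row {i} has {len(vals)} entries, expected {i + 1}")
            h[i, : i + 1] = vals
            h[: i + 1, i] = vals
        return cls(labels=labels, coords=np.array(coords), masses=np.array(masses),
                   hessian=h, linear=linear)

    @classmethod
    def read(cls, path) -> "MolecularSystem":
        return cls.loads(Path(path).read_text())
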