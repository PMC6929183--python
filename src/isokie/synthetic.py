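"""Synthetic inputs for the whole inference chain.

Three generators, each with seed-exact determinism:

* toy molecular species and reactions — collinear chains with exact analytic
  Cartesian Hessians (diatomics, proton-transfer chains with one negative
  internal curvature at the transition structure, block composites), the raw
  material for frequency analysis and Bigeleisen KIEs;
* simulated batch-degradation experiments — first-order decay with an
  isotopolog rate ratio implied by assembled position-specific KIEs, plus
  lognormal concentration noise and Gaussian δ noise, written in the same CSV
  layout a compound-specific isotope study would tabulate;
* biased umbrella-window samples from a stated model free-energy profile,
  the input WHAM is validated against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .constants import BOHR_ANGSTROM
from .rayleigh import RayleighDataset
from .systems import MolecularSystem
from .thermo import ThermoSettings
from .wham import UmbrellaWindow

KINDS = ("diatomic", "collinear-transfer", "block-composite")


# ------------------------------------------------------------- toy species
@dataclass(frozen=True)
class ToySystemSpec:
    """A collinear toy molecule defined by bonds, masses and force constants.

    Parameters
    ----------
    kind : str
        "diatomic", "collinear-transfer" (a proton-transfer chain whose last
        two bonds are coupled), or "block-composite" (uncoupled sub-systems
        stacked block-diagonally).
    labels, masses : per-atom element labels and masses (amu).
    distances : successive internuclear distances (Å), len = n_atoms − 1.
    bond_k : per-bond harmonic constants (hartree/bohr²).
    coupling : off-diagonal stretch–stretch constant between the last two
        bonds (hartree/bohr²); only a collinear-transfer spec may make the
        internal curvature matrix indefinite, and then by exactly one
        negative eigenvalue.
    bend_k : per-interior-atom bending constants (hartree/rad²).
    blocks : sub-specs for kind="block-composite".
    """

    kind: str
    labels: Tuple[str, ...] = ()
    masses: Tuple[float, ...] = ()
    distances: Tuple[float, ...] = ()
    bond_k: Tuple[float, ...] = ()
    coupling: float = 0.0
    bend_k: Tuple[float, ...] = ()
    blocks: Tuple["ToySystemSpec", ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind == "block-composite":
            if not self.blocks:
                raise ValueError("block-composite requires sub-specs in 'blocks'")
            return
        n = len(self.labels)
        if n < 2:
            raise ValueError("need at least two atoms")
        if len(self.masses) != n or any(m <= 0 for m in self.masses):
            raise ValueError("one positive mass per atom required")
        if len(self.distances) != n - 1 or any(d <= 0 for d in self.distances):
            raise ValueError("need n-1 positive internuclear distances")
        if len(self.bond_k) != n - 1:
            raise ValueError("need one force constant per bond")
        if self.bend_k and len(self.bend_k) != n - 2:
            raise ValueError("need one bending constant per interior atom")
        neg = np.sum(np.linalg.eigvalsh(self.internal_k()) < 0)
        if neg > 1:
            raise ValueError("at most one negative internal curvature allowed")
        if neg == 1 and self.kind != "collinear-transfer":
            raise ValueError(
                "negative curvature requested for a minimum kind: only "
                "collinear-transfer species may be saddle points"
            )

    def internal_k(self) -> np.ndarray:
        """Internal stretch–stretch force-constant matrix (hartree/bohr²)."""
        k = np.diag(np.asarray(self.bond_k, dtype=float))
        if self.coupling and k.shape[0] >= 2:
            k[-1, -2] = k[-2, -1] = self.coupling
        return k


def _chain_system(spec: ToySystemSpec) -> MolecularSystem:
    n = len(spec.labels)
    z = np.concatenate([[0.0], np.cumsum(spec.distances)])  # Å
    coords = np.zeros((n, 3))
    coords[:, 2] = z
    z_bohr = z / BOHR_ANGSTROM

    h = np.zeros((3 * n, 3 * n))
    # stretches: internal coords Δr_b = z_{b+1} − z_b → B-matrix on z components
    b = np.zeros((n - 1, n))
    for i in range(n - 1):
        b[i, i], b[i, i + 1] = -1.0, 1.0
    h_z = b.T @ spec.internal_k() @ b
    idx_z = 3 * np.arange(n) + 2
    h[np.ix_(idx_z, idx_z)] = h_z
    # degenerate perpendicular bends at each interior atom; the linearized
    # bend angle has Cartesian gradient (1/r1, −(1/r1 + 1/r2), 1/r2), which is
    # exactly rotation-invariant for the collinear geometry
    for j in range(1, n - 1):
        kb = spec.bend_k[j - 1] if spec.bend_k else 0.0
        if kb == 0.0:
            continue
        r1 = z_bohr[j] - z_bohr[j - 1]
        r2 = z_bohr[j + 1] - z_bohr[j]
        v = np.zeros(n)
        v[j - 1], v[j], v[j + 1] = 1.0 / r1, -(1.0 / r1 + 1.0 / r2), 1.0 / r2
        for axis in (0, 1):
            idx = 3 * np.arange(n) + axis
            h[np.ix_(idx, idx)] += kb * np.outer(v, v)
    return MolecularSystem(
        labels=list(spec.labels), coords=coords, masses=np.array(spec.masses),
        hessian=h, meta={"kind": spec.kind},
    )


def make_toy_species(spec: ToySystemSpec) -> MolecularSystem:
    """Build the geometry and exact analytic Cartesian Hessian of a toy spec.

    Minima have positive-semidefinite Hessians apart from rigid-body modes;
    a collinear-transfer spec with an indefinite internal curvature matrix
    yields a first-order saddle.
    """
    if spec.kind != "block-composite":
        return _chain_system(spec)
    parts = [make_toy_species(b) for b in spec.blocks]
    labels, masses, coords, blocks = [], [], [], []
    z_offset = 0.0
    for p in parts:
        labels.extend(p.labels)
        masses.extend(p.masses)
        c = p.coords.copy()
        c[:, 2] += z_offset
        coords.append(c)
        blocks.append(p.hessian)
        z_offset = c[:, 2].max() + 100.0   # keep blocks mechanically separate
    n_tot = len(labels)
    h = np.zeros((3 * n_tot, 3 * n_tot))
    at = 0
    for hb in blocks:
        m = hb.shape[0]
        h[at : at + m, at : at + m] = hb
        at += m
    return MolecularSystem(
        labels=labels, coords=np.vstack(coords), masses=np.array(masses),
        hessian=h, meta={"kind": "block-composite"},
    )


def make_toy_reaction(
    spec: ToySystemSpec,
) -> Tuple[MolecularSystem, MolecularSystem]:
    """Reactant (all-positive internal curvatures) and transition structure.

    The reactant decouples the transfer bonds (coupling = 0); the transition
    structure uses the spec's coupling, which must make the internal
    curvature matrix indefinite by exactly one eigenvalue — the light-atom
    transfer coordinate.
    """
    if spec.kind != "collinear-transfer":
        raise ValueError("toy reactions require kind='collinear-transfer'")
    from dataclasses import replace

    reactant_spec = replace(spec, coupling=0.0)
    k_ts = spec.internal_k()
    eig = np.linalg.eigvalsh(k_ts)
    if np.any(np.abs(eig) < 1e-12):
        raise ValueError("zero curvature along the transfer coordinate")
    if np.sum(eig < 0) != 1:
        raise ValueError(
            "transition-structure spec must have exactly one negative "
            f"internal curvature; eigenvalues {eig}"
        )
    return make_toy_species(reactant_spec), make_toy_species(spec)


def default_transfer_spec(with_chlorine: bool = True) -> ToySystemSpec:
    """The default proton-transfer toy: (Cl–)C–H···O with a coupled TS.

    Mimics the alkaline dehydrochlorination situation at cartoon scale: a
    C–H bond being broken, an H···O bond being formed (hydroxide as the
    base), and — when ``with_chlorine`` — a spectator C–Cl bond whose
    curvature barely changes, so chlorine shows a small secondary-type
    effect while the transferring hydrogen dominates the imaginary mode.
    """
    if with_chlorine:
        return ToySystemSpec(
            kind="collinear-transfer",
            labels=("Cl", "C", "H", "O"),
            masses=(34.96885268, 12.0, 1.00782503, 15.99491462),
            distances=(1.78, 1.10, 1.30),
            bond_k=(0.16, 0.30, 0.05),
            coupling=0.15,
            bend_k=(0.02, 0.02),
        )
    return ToySystemSpec(
        kind="collinear-transfer",
        labels=("C", "H", "O"),
        masses=(12.0, 1.00782503, 15.99491462),
        distances=(1.10, 1.30),
        bond_k=(0.30, 0.05),
        coupling=0.15,
        bend_k=(0.02,),
    )


# -------------------------------------------------------- batch experiments
@dataclass(frozen=True)
class ElementKIESpec:
    """Primary/secondary KIE assembly for one element of the compound."""

    primary: float
    secondary: float = 1.0
    n: int = 6

    def __post_init__(self) -> None:
        if not (self.primary > 0 and self.secondary > 0):
            raise ValueError("KIEs must be > 0")
        if self.n < 1:
            raise ValueError("position count must be >= 1")

    @property
    def kie_av(self) -> float:
        return (self.primary + (self.n - 1) * self.secondary) / self.n

    @property
    def epsilon_permil(self) -> float:
        return (1.0 - self.kie_av) * 1000.0


@dataclass(frozen=True)
class BatchExperimentParams:
    """Design of one simulated batch-hydrolysis degradation experiment."""

    k_light_per_s: float
    elements: Dict[str, ElementKIESpec]
    times_h: Tuple[float, ...]
    c0: float = 1.0
    conc_noise_rel: float = 0.0
    delta_noise_permil: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_light_per_s > 0:
            raise ValueError("k_light must be > 0")
        if not self.c0 > 0:
            raise ValueError("initial concentration must be > 0")
        t = np.asarray(self.times_h, dtype=float)
        if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        if self.conc_noise_rel < 0 or self.delta_noise_permil < 0:
            raise ValueError("noise magnitudes must be >= 0")


def simulate_batch_experiment(p: BatchExperimentParams) -> RayleighDataset:
    """First-order decay of light/heavy pools with trace-heavy Rayleigh behavior.

    The bulk KIE implied by each element's (primary, secondary, n) sets the
    enrichment factor ε = (1 − KIE_av)·1000 ‰; the heavy-isotopolog rate is
    k_H = k_L·(1 + ε/1000), so the noise-free residual-substrate data lie
    exactly on the Rayleigh line ln(R/R₀) = (ε/1000)·ln(C/C₀).  Noise is
    multiplicative lognormal on concentrations and additive Gaussian on
    δ-values; identical seeds give byte-identical tables.
    """
    rng = np.random.default_rng(p.seed)
    t_s = np.asarray(p.times_h, dtype=float) * 3600.0
    frac = np.exp(-p.k_light_per_s * t_s)          # C/C0, light ≈ total
    conc = p.c0 * frac
    if p.conc_noise_rel > 0:
        sigma = math.sqrt(math.log(1.0 + p.conc_noise_rel**2))
        conc = conc * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=conc.size)
    deltas = {}
    for el, ek in sorted(p.elements.items()):
        eps = ek.epsilon_permil
        ratio_rel = frac ** (eps / 1000.0)          # R_t / R_0, with delta_0 = 0
        d = (ratio_rel - 1.0) * 1000.0
        if p.delta_noise_permil > 0:
            d = d + rng.normal(0.0, p.delta_noise_permil, size=d.size)
        deltas[el] = d
    return RayleighDataset(
        times_h=np.asarray(p.times_h, dtype=float),
        conc=conc,
        deltas=deltas,
        meta={
            "seed": p.seed,
            "k_light_per_s": p.k_light_per_s,
            "epsilon_true_permil": {
                el: ek.epsilon_permil for el, ek in sorted(p.elements.items())
            },
        },
    )


# --------------------------------------------------------- umbrella windows
@dataclass(frozen=True)
class ProfileSpec:
    """A stated model free-energy profile A(z) used to generate window samples.

    Forms: "harmonic" (params: kappa [kcal/mol/Å²]), "double-well"
    (params: barrier [kcal/mol], half_separation [Å]; wells at ±a with the
    barrier top at z = 0), "table" (params: z, a arrays, linear
    interpolation).  The temperature is part of the spec because the
    Boltzmann sampling is defined by β·A(z).
    """

    form: str
    params: dict
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.form not in ("harmonic", "double-well", "table"):
            raise ValueError(f"unknown profile form {self.form!r}")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")

    def energy(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.form == "harmonic":
            out = 0.5 * self.params["kappa"] * z**2
        elif self.form == "double-well":
            a = self.params["half_separation"]
            out = self.params["barrier"] * (z**2 - a**2) ** 2 / a**4
        else:
            out = np.interp(z, self.params["z"], self.params["a"])
        if not np.all(np.isfinite(out)):
            raise ValueError("profile must be finite on the sampled range")
        return out

    @property
    def thermo(self) -> ThermoSettings:
        return ThermoSettings(temperature=self.temperature)


def sample_umbrella_windows(
    profile: ProfileSpec,
    centers: Sequence[float],
    bias_k: float,
    n_per_window: int,
    seed: int,
    thin: int = 5,
) -> list:
    """Metropolis samples from each biased window density.

    Each window k samples z ∝ exp(−β[A(z) + ½·bias_k·(z − z_k)²]) with a
    Gaussian proposal auto-tuned to 30–50 % acceptance during a discarded
    burn-in of 10 % of the requested samples; every ``thin``-th state of the
    chain is kept so the stored samples are only weakly correlated.  The
    final acceptance rate and seed are recorded in the window metadata.  A
    warning is raised when adjacent windows do not overlap (WHAM would be
    ill-conditioned).
    """
    if thin < 1:
        raise ValueError("thin must be >= 1")
    centers = np.asarray(centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be strictly increasing")
    if not bias_k > 0:
        raise ValueError("bias force constant must be > 0")
    if n_per_window < 100:
        raise ValueError("need at least 100 samples per window")
    beta = profile.thermo.beta
    ss = np.random.SeedSequence(seed)
    windows = []
    for wid, (center, child) in enumerate(zip(centers, ss.spawn(centers.size))):
        rng = np.random.default_rng(child)

        def u_tot(z, _c=center):
            return float(profile.energy(z) + 0.5 * bias_k * (z - _c) ** 2)

        step = 2.0 / math.sqrt(beta * bias_k)
        n_burn = max(10, n_per_window // 10)
        chunk = max(1, n_burn // 10)
        z, uz = float(center), u_tot(center)
        for _ in range(10):
            acc = 0
            for _ in range(chunk):
                zp = z + step * rng.standard_normal()
                up = u_tot(zp)
                if math.log(rng.random()) < -beta * (up - uz):
                    z, uz = zp, up
                    acc += 1
            rate = acc / chunk
            if rate < 0.30:
                step *= 0.7
            elif rate > 0.50:
                step *= 1.4
        samples = np.empty(n_per_window)
        n_acc = 0
        n_steps = n_per_window * thin
        for i in range(n_steps):
            zp = z + step * rng.standard_normal()
            up = u_tot(zp)
            if math.log(rng.random()) < -beta * (up - uz):
                z, uz = zp, up
                n_acc += 1
            if (i + 1) % thin == 0:
                samples[(i + 1) // thin - 1] = z
        windows.append(
            UmbrellaWindow(
                window_id=wid,
                center=float(center),
                bias_k=float(bias_k),
                samples=samples,
                meta={
                    "acceptance": n_acc / n_steps,
                    "step": step,
                    "thin": thin,
                    "seed": seed,
                },
            )
        )
    for a, b in zip(windows[:-1], windows[1:]):
        if a.samples.max() < b.samples.min() or b.samples.max() < a.samples.min():
            warnings.warn(
                f"windows {a.window_id} and {b.window_id} do not overlap: "
                "WHAM will be ill-conditioned",
                stacklevel=2,
            )
    return windows
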