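"""Weighted histogram analysis of umbrella-sampling windows (1D).

Biased samples from K overlapping windows, each restrained by a harmonic
umbrella W_k(z) = ½k_b(z − z_k)², are merged into a single unbiased
probability profile by the self-consistent WHAM equations

    P(z_j) ∝ Σ_k n_k(z_j) / Σ_k N_k exp(−β[W_k(z_j) − F_k]),
    exp(−βF_k) = Σ_j P(z_j) exp(−βW_k(z_j)),

and the potential of mean force is A(z) = −k_BT ln P(z), reported with its
minimum shifted to zero.  The reaction coordinate for the
dehydrochlorination study is the antisymmetric proton-transfer combination
z = r(C1–H1) − r(H1–O); the C–Cl cleavage variable is deliberately not part
of the coordinate (1D only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .thermo import ThermoSettings


class WHAMConvergenceError(RuntimeError):
    """WHAM iteration hit max_iter; ``partial`` carries the last profile."""

    def __init__(self, message: str, partial: "PMFProfile"):
        super().__init__(message)
        self.partial = partial


class NoBarrierError(ValueError):
    """The profile has no interior maximum beyond the reactant basin."""


@dataclass(frozen=True)
class ReactionCoordinateSpec:
    """z = r(donor–transfer) − r(transfer–acceptor), in Å.

    For the proton-abstraction coordinate the donor pair is (C1, H1) and the
    acceptor pair (H1, O); z is negative while the C–H bond is shorter than
    the forming H···O contact.
    """

    donor: Tuple[int, int] = (0, 1)
    acceptor: Tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        if len({*self.donor, *self.acceptor}) < 3:
            raise ValueError("donor and acceptor pairs must involve distinct atoms")


def reaction_coordinate(coords: np.ndarray, spec: ReactionCoordinateSpec) -> float:
    """Evaluate z for one geometry (N×3 array, Å)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    i, j = spec.donor
    k, l = spec.acceptor
    r_dt = np.linalg.norm(coords[i] - coords[j])
    r_ta = np.linalg.norm(coords[k] - coords[l])
    if r_dt == 0.0 or r_ta == 0.0:
        raise ValueError("coincident atoms in reaction-coordinate pairs")
    return float(r_dt - r_ta)


@dataclass
class UmbrellaWindow:
    """Biased samples of the reaction coordinate from one umbrella window."""

    window_id: int
    center: float                 # z_k, Å
    bias_k: float                 # kcal mol^-1 Å^-2
    samples: np.ndarray           # z samples, Å
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ValueError("window must hold at least one sample")
        if not self.bias_k > 0:
            raise ValueError("bias force constant must be > 0")

    @property
    def n(self) -> int:
        return self.samples.size

    def bias(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.bias_k * (np.asarray(z) - self.center) ** 2


@dataclass
class PMFProfile:
    """Reconstructed free-energy profile A(z), min-shifted to zero."""

    z: np.ndarray                 # bin centers, Å
    a_kcal: np.ndarray            # A(z), kcal/mol
    f_k: np.ndarray               # window free energies, gauge F_1 = 0
    counts: np.ndarray            # histogram counts, (K, n_bins)
    n_iter: int
    residual: float
    converged: bool
    ill_conditioned: bool = False
    temperature: float = 298.15

    def to_tsv(self, path) -> None:
        pd.DataFrame({"z": self.z, "A_kcal_mol": self.a_kcal}).to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )


def _freedman_diaconis_edges(pooled: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(pooled, [75, 25])
    iqr = q75 - q25
    width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)
    lo, hi = pooled.min(), pooled.max()
    if width <= 0:
        width = (hi - lo) / 50 or 1.0
    n_bins = max(10, int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n_bins + 1)


def _check_overlap(windows, edges) -> bool:
    """True if every adjacent pair of windows shares a populated bin."""
    order = np.argsort([w.center for w in windows])
    hists = [np.histogram(windows[i].samples, bins=edges)[0] > 0 for i in order]
    for a, b in zip(hists[:-1], hists[1:]):
        if not np.any(a & b):
            return False
    return True


def wham(
    windows: Sequence[UmbrellaWindow],
    th: ThermoSettings,
    bins: Union[int, np.ndarray, None] = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    method: str = "iterative",
) -> PMFProfile:
    """Self-consistent WHAM solution over a shared histogram grid.

    Parameters
    ----------
    bins : int, array of edges, or None
        ``None`` selects Freedman–Diaconis binning on the pooled samples.
    tol : float
        Convergence threshold on max|ΔF_k| in kcal/mol.
    method : {"iterative", "mle"}
        Fixed-point iteration (default) or direct maximization of the WHAM
        log-likelihood over the window free energies.

    Raises
    ------
    WHAMConvergenceError
        If the iteration hits ``max_iter``; the exception carries the
        partial profile.
    """
    if len(windows) < 1:
        raise ValueError("need at least one window")
    beta = th.beta
    kt = th.kt_kcal
    pooled = np.concatenate([w.samples for w in windows])
    if bins is None:
        edges = _freedman_diaconis_edges(pooled)
    elif np.isscalar(bins):
        edges = np.linspace(pooled.min(), pooled.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    ill = False
    if len(windows) > 1 and not _check_overlap(windows, edges):
        warnings.warn(
            "adjacent umbrella windows have non-overlapping histograms: "
            "WHAM will be ill-conditioned",
            stacklevel=2,
        )
        ill = True

    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows])
    m_j = counts.sum(axis=0).astype(float)          # pooled counts per bin
    n_k = np.array([w.n for w in windows], dtype=float)
    w_kj = np.array([w.bias(centers) for w in windows])  # (K, J)
    c_kj = np.exp(-beta * w_kj)
    occupied = m_j > 0

    def profile_from_g(g_k, n_iter, residual, converged):
        # g_k = beta * F_k; P_j on occupied bins
        denom = (n_k[:, None] * np.exp(g_k)[:, None] * c_kj).sum(axis=0)
        p = np.where(occupied, m_j / np.where(denom > 0, denom, 1.0), 0.0)
        p_occ = p[occupied]
        a = -kt * np.log(p_occ / p_occ.sum())
        a -= a.min()
        return PMFProfile(
            z=centers[occupied],
            a_kcal=a,
            f_k=(g_k - g_k[0]) / beta,
            counts=counts,
            n_iter=n_iter,
            residual=residual,
            converged=converged,
            ill_conditioned=ill,
            temperature=th.temperature,
        )

    if method == "mle":
        # maximize sum_k N_k g_k - sum_j M_j ln sum_k N_k e^{g_k} c_kj over g
        def _logsumexp_weighted(g):
            arg = g[:, None] - beta * w_kj + np.log(n_k)[:, None]
            mx = arg.max(axis=0)
            return mx + np.log(np.exp(arg - mx).sum(axis=0))

        def neg_ll(g_free):
            g = np.concatenate([[0.0], g_free])
            log_den = _logsumexp_weighted(g)
            return -(n_k @ g - m_j[occupied] @ log_den[occupied])

        x0 = np.zeros(len(windows) - 1)
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B")
        g = np.concatenate([[0.0], res.x])
        return profile_from_g(g, int(res.nit), float(np.abs(res.jac).max() if res.jac is not None else 0.0), bool(res.success))
    if method != "iterative":
        raise ValueError("method must be 'iterative' or 'mle'")

    g_k = np.zeros(len(windows))     # beta * F_k
    residual = np.inf
    for it in range(1, max_iter + 1):
        denom = (n_k[:, None] * np.exp(g_k)[:, None] * c_kj).sum(axis=0)
        p = np.where(occupied & (denom > 0), m_j / np.where(denom > 0, denom, 1.0), 0.0)
        with np.errstate(divide="ignore"):
            g_new = -np.log((p[None, :] * c_kj).sum(axis=1))
        g_new -= g_new[0]
        residual = float(np.abs(g_new - g_k).max() / beta)   # kcal/mol
        g_k = g_new
        if residual < tol:
            return profile_from_g(g_k, it, residual, True)
    partial = profile_from_g(g_k, max_iter, residual, False)
    raise WHAMConvergenceError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(residual {residual:.3g} kcal/mol > tol {tol:g})",
        partial,
    )


def barrier_height(
    profile: PMFProfile, reactant_range: Tuple[float, float]
) -> float:
    """Forward activation free energy: interior maximum past the reactant basin.

    ``reactant_range`` is the (z_lo, z_hi) interval of the reactant basin;
    the barrier is the highest interior local maximum at z beyond the
    reactant minimum, minus the basin minimum.  Gauge-invariant.

    Raises
    ------
    NoBarrierError
        If the profile is monotone beyond the basin (no interior maximum).
    """
    z, a = profile.z, profile.a_kcal
    lo, hi = reactant_range
    mask = (z >= lo) & (z <= hi)
    if not mask.any():
        raise ValueError("reactant range contains no profile bins")
    i_min = np.flatnonzero(mask)[np.argmin(a[mask])]
    a_min = a[i_min]

    maxima = []
    for i in range(max(i_min + 1, 1), z.size - 1):
        if a[i] > a[i - 1] and a[i] >= a[i + 1]:
            maxima.append(a[i])
    if not maxima:
        raise NoBarrierError(
            "profile is monotone beyond the reactant basin: no barrier"
        )
    return float(max(maxima) - a_min)


# ------------------------------------------------------------------- I/O
def write_windows_tsv(path, windows: Sequence[UmbrellaWindow]) -> None:
    """TSV with one row per sample: window_id, center, bias_k, sample."""
    frames = [
        pd.DataFrame(
            {
                "window_id": w.window_id,
                "center": w.center,
                "bias_k": w.bias_k,
                "sample": w.samples,
            }
        )
        for w in windows
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_windows_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    windows = []
    for wid, grp in df.groupby("window_id", sort=True):
        windows.append(
            UmbrellaWindow(
                window_id=int(wid),
                center=float(grp["center"].iloc[0]),
                bias_k=float(grp["bias_k"].iloc[0]),
                samples=grp["sample"].to_numpy(),
            )
        )
    return windows
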