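"""Rayleigh regression of enrichment factors from batch-degradation data.

During a first-order degradation the isotope ratio of the residual substrate
follows the Rayleigh equation

    ln(R_t/R_0) = (ε/1000) · ln(C_t/C_0),

so ε (in ‰) is 1000 times the slope in double-log space.  δ-values convert to
ratios as R = R_std·(1 + δ/1000); reference ratios cancel in the regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: compound-average delta column names per element, matching the batch
#: experiment CSV layout
DELTA_COLUMNS = {"C": "d13C_permil", "Cl": "d37Cl_permil", "H": "d2H_permil"}

#: placeholder international-standard ratios (VPDB, SMOC, VSMOW); the
#: regression is invariant to these because delta arithmetic cancels R_std
R_STD_DEFAULT = {"C": 0.0111802, "Cl": 0.319766, "H": 1.5576e-4}


def delta_to_ratio(delta_permil, r_std: float):
    """R = R_std·(1 + δ/1000); δ must exceed −1000 ‰."""
    delta_permil = np.asarray(delta_permil, dtype=float)
    if np.any(delta_permil <= -1000.0):
        raise ValueError("delta values must be > -1000 permil")
    return r_std * (1.0 + delta_permil / 1000.0)


def ratio_to_delta(ratio, r_std: float):
    """Inverse of :func:`delta_to_ratio`."""
    return (np.asarray(ratio, dtype=float) / r_std - 1.0) * 1000.0


@dataclass
class RayleighDataset:
    """Concentration and δ time series from one batch-degradation experiment."""

    times_h: np.ndarray
    conc: np.ndarray
    deltas: Dict[str, np.ndarray]          # element -> δ (‰ vs standard)
    r_std: Dict[str, float] = field(default_factory=lambda: dict(R_STD_DEFAULT))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        n = self.times_h.size
        if self.conc.size != n:
            raise ValueError("times and concentrations must align")
        if not self.conc[0] > 0:
            raise ValueError("initial concentration must be > 0")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be > 0")
        for el, d in self.deltas.items():
            d = np.asarray(d, dtype=float)
            if d.size != n:
                raise ValueError(f"delta series for {el} misaligned")
            if np.any(d <= -1000.0):
                raise ValueError(f"delta values for {el} must be > -1000 permil")
            self.deltas[el] = d

    @property
    def elements(self):
        return sorted(self.deltas)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_h": self.times_h, "conc": self.conc}
        for el in ("C", "Cl", "H"):
            if el in self.deltas:
                data[DELTA_COLUMNS[el]] = self.deltas[el]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, r_std: Optional[Dict[str, float]] = None) -> "RayleighDataset":
        df = pd.read_csv(path)
        deltas = {
            el: df[col].to_numpy()
            for el, col in DELTA_COLUMNS.items()
            if col in df.columns
        }
        return cls(
            times_h=df["time_h"].to_numpy(),
            conc=df["conc"].to_numpy(),
            deltas=deltas,
            r_std=dict(r_std or R_STD_DEFAULT),
            meta={"source": str(path)},
        )


@dataclass(frozen=True)
class EpsilonFit:
    """Regression estimate of the bulk enrichment factor for one element."""

    element: str
    epsilon_permil: float
    se_permil: float
    ci95_permil: Tuple[float, float]
    r_squared: float
    n_points: int
    through_origin: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a Rayleigh fit needs at least 3 points")
        lo, hi = self.ci95_permil
        if not (lo <= self.epsilon_permil <= hi):
            raise ValueError("confidence interval must contain the estimate")


def rayleigh_fit(
    ds: RayleighDataset, element: str, through_origin: bool = True
) -> EpsilonFit:
    """Least-squares Rayleigh regression for one element.

    The default regresses through the origin — both axes are exactly zero at
    t = 0 by construction of the ratios.  ``through_origin=False`` frees the
    intercept, which absorbs measurement error in the t = 0 sample and is the
    calibrated choice when the initial δ and concentration are themselves
    noisy.
    """
    if element not in ds.deltas:
        raise ValueError(f"dataset has no delta series for element {element!r}")
    if ds.times_h.size < 3:
        raise ValueError("need at least 3 time points")
    x = np.log(ds.conc / ds.conc[0])
    if np.count_nonzero(ds.conc < ds.conc[0]) < 2:
        raise ValueError("no dynamic range: need at least 2 points with C_t < C_0")
    ratio = 1.0 + ds.deltas[element] / 1000.0  # R/R_std; R_std cancels
    y = np.log(ratio / ratio[0])

    exog = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, exog).fit()
    slope_idx = 0 if through_origin else 1
    slope = res.params[slope_idx]
    se = res.bse[slope_idx]
    ci = res.conf_int(alpha=0.05)[slope_idx]
    with np.errstate(invalid="ignore"):
        r_squared = float(res.rsquared)  # NaN when y has no variation at all
    return EpsilonFit(
        element=element,
        epsilon_permil=1000.0 * slope,
        se_permil=1000.0 * se,
        ci95_permil=(1000.0 * ci[0], 1000.0 * ci[1]),
        r_squared=r_squared,
        n_points=int(ds.times_h.size),
        through_origin=through_origin,
    )


def epsilon_to_akie(epsilon_permil: float, n: int) -> float:
    """Apparent position-specific KIE from a bulk ε with dilution correction.

    AKIE = 1/(1 + n·ε/1000).  The linearized dilution correction breaks down
    for large effects (n·ε/1000 approaching −1); such values are flagged with
    a warning — back-infer the secondary average instead.
    """
    import warnings

    if n < 1:
        raise ValueError("n must be >= 1")
    denom = 1.0 + n * epsilon_permil / 1000.0
    if denom <= 0:
        raise ValueError(
            f"dilution-corrected denominator {denom:.4f} <= 0: AKIE undefined "
            f"for epsilon={epsilon_permil} permil at n={n}"
        )
    akie = 1.0 / denom
    if denom < 0.2:
        warnings.warn(
            f"AKIE = {akie:.3g} is beyond the applicability of the linear "
            "dilution correction; use infer_secondary_average instead",
            stacklevel=2,
        )
    return akie


def write_fit_report(path, fits) -> None:
    """CSV fit report (element, epsilon, SE, CI bounds, R2, n)."""
    pd.DataFrame(
        [
            {
                "element": f.element,
                "epsilon_permil": f.epsilon_permil,
                "se_permil": f.se_permil,
                "ci95_lo_permil": f.ci95_permil[0],
                "ci95_hi_permil": f.ci95_permil[1],
                "r_squared": f.r_squared,
                "n_points": f.n_points,
                "through_origin": f.through_origin,
            }
            for f in fits
        ]
    ).to_csv(path, index=False)
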