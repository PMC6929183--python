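"""Semiclassical (Bigeleisen) kinetic isotope effects from harmonic frequencies.

Within harmonic transition-state theory the light/heavy rate-constant ratio
for a single isotopic substitution is

    KIE = (ν̃‡_L / ν̃‡_H) · g(TS) / g(R),

where the imaginary-wavenumber ratio is the classical contribution of the
reaction-coordinate mode and g is the product over matched real modes of the
per-mode quantum-correction ratio

    g_i = (u_L/u_H) · exp((u_H − u_L)/2) · (1 − e^{−u_H}) / (1 − e^{−u_L}),

with u = hcν̃/k_BT.  Each factor equals the light/heavy ratio of
(quantum/classical) harmonic partition-function corrections, so g collects
zero-point and thermal quantization effects; no anharmonicity and no
tunneling (Wigner) correction are applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fractionation import PositionKIE
from .thermo import ThermoSettings
from .vibrations import FrequencySet


@dataclass(frozen=True)
class ModeFactorTable:
    """Per-mode u values and Bigeleisen factors for one matched pair of sets."""

    u_light: np.ndarray
    u_heavy: np.ndarray
    factors: np.ndarray
    temperature: float

    @property
    def g(self) -> float:
        """Species factor: product of the per-mode factors."""
        return float(np.prod(self.factors))


def _mode_factor(u_l: np.ndarray, u_h: np.ndarray) -> np.ndarray:
    # (u_L/u_H)·e^{(u_H−u_L)/2}·(1−e^{−u_H})/(1−e^{−u_L}); -expm1(-u) = 1−e^{−u}
    return (u_l / u_h) * np.exp((u_h - u_l) / 2.0) * (
        -np.expm1(-u_h)
    ) / (-np.expm1(-u_l))


def mode_factor_table(
    light: FrequencySet, heavy: FrequencySet, th: ThermoSettings
) -> ModeFactorTable:
    """u values and per-mode Bigeleisen factors for sorted-order matched modes."""
    if light.n_real != heavy.n_real:
        raise ValueError(
            f"mode count mismatch: {light.n_real} light vs {heavy.n_real} heavy"
        )
    u_l = th.u(light.real)
    u_h = th.u(heavy.real)
    return ModeFactorTable(
        u_light=u_l,
        u_heavy=u_h,
        factors=_mode_factor(u_l, u_h),
        temperature=th.temperature,
    )


def semiclassical_kie(
    reactant_light: FrequencySet,
    reactant_heavy: FrequencySet,
    ts_light: FrequencySet,
    ts_heavy: FrequencySet,
    th: ThermoSettings,
    position: str = "",
    element: str = "",
) -> PositionKIE:
    """Bigeleisen KIE from reactant and transition-structure frequency sets.

    The components (imaginary-frequency ratio, g(TS), g(R)) are retained on
    the returned record's ``components`` metadata for inspection.
    """
    for name, fs in (("ts_light", ts_light), ("ts_heavy", ts_heavy)):
        if not fs.is_saddle:
            raise ValueError(f"{name} has no imaginary mode: not a transition structure")
    for name, fs in (("reactant_light", reactant_light), ("reactant_heavy", reactant_heavy)):
        if fs.is_saddle:
            raise ValueError(f"{name} carries an imaginary mode: not a minimum")

    nu_ratio = ts_light.imaginary / ts_heavy.imaginary
    g_ts = mode_factor_table(ts_light, ts_heavy, th).g
    g_r = mode_factor_table(reactant_light, reactant_heavy, th).g
    kie = nu_ratio * g_ts / g_r
    record = PositionKIE(
        position=position or "pos",
        element=element or "X",
        value=kie,
        provenance="semiclassical",
    )
    object.__setattr__(
        record,
        "components",
        {"nu_ratio": nu_ratio, "g_ts": g_ts, "g_r": g_r, "T": th.temperature},
    )
    return record


def write_kie_table(path, records: Sequence[PositionKIE]) -> None:
    """Per-position KIE CSV: position, element, KIE, nu_ratio, g_TS, g_R, T."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "element", "KIE", "nu_ratio", "g_TS", "g_R", "T"])
        for r in records:
            comp = getattr(r, "components", {})
            w.writerow(
                [
                    r.position,
                    r.element,
                    f"{r.value:.8f}",
                    *(f"{comp[k]:.8f}" if k in comp else "" for k in ("nu_ratio", "g_ts", "g_r")),
                    comp.get("T", ""),
                ]
            )
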