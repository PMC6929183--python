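"""Bulk isotope quantities from position-specific KIEs.

Compound-specific isotope analysis sees only the compound-average (bulk)
isotope effect: the arithmetic mean KIE_av of the position-specific KIEs of
one element across all its positions, and the bulk enrichment factor

    ε = (1 − KIE_av) · 1000 ‰,

negative for a normal isotope effect.  γ-HCH carries six equivalent-count
positions of each of C, Cl and H, so a single large primary effect is diluted
by five secondary positions.  This module assembles bulk quantities from
mixed provenance (path-integral primary + model secondary KIEs) and inverts
the assembly to back-infer the average secondary KIE a measured bulk ε
implies for an assumed primary.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

PROVENANCES = ("semiclassical", "pi", "assumed")


@dataclass(frozen=True)
class PositionKIE:
    """One position-specific kinetic isotope effect (k_light/k_heavy)."""

    position: str
    element: str
    value: float
    provenance: str = "assumed"
    se: float = 0.0

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"KIE must be > 0, got {self.value}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class BulkKIEResult:
    """Element-wise average of position-specific KIEs."""

    element: str
    kie_av: float
    n: int
    positions: Tuple[PositionKIE, ...] = ()


@dataclass(frozen=True)
class EnrichmentResult:
    """Bulk enrichment factor ε = (1 − KIE_av)·1000 in ‰."""

    element: str
    epsilon_permil: float
    flag: Optional[str] = None


def average_kie(records: Sequence[PositionKIE]) -> BulkKIEResult:
    """Unweighted arithmetic mean of position-specific KIEs of one element."""
    if len(records) < 1:
        raise ValueError("need at least one PositionKIE record")
    elements = {r.element for r in records}
    if len(elements) > 1:
        raise ValueError(f"mixed elements in average: {sorted(elements)}")
    vals = [r.value for r in records]
    return BulkKIEResult(
        element=records[0].element,
        kie_av=sum(vals) / len(vals),
        n=len(vals),
        positions=tuple(records),
    )


def enrichment_from_kie(bulk: BulkKIEResult) -> EnrichmentResult:
    """ε = (1 − KIE_av)·1000 ‰; KIE_av > 1 gives ε < 0 (normal effect)."""
    return EnrichmentResult(
        element=bulk.element, epsilon_permil=(1.0 - bulk.kie_av) * 1000.0
    )


def kie_av_from_epsilon(epsilon_permil: float) -> float:
    """Invert ε = (1 − KIE_av)·1000."""
    return 1.0 - epsilon_permil / 1000.0


def model_ensemble_stats(per_model: Sequence[PositionKIE]) -> Tuple[float, float]:
    """Mean and sample standard deviation of one position's KIE across models.

    Used for ensembles of solvation models that each predict the same
    position's KIE (e.g. a position-specific Cl effect averaged over a set of
    microsolvation clusters).
    """
    if len(per_model) < 2:
        raise ValueError("sample standard deviation undefined for < 2 models")
    positions = {r.position for r in per_model}
    if len(positions) > 1:
        raise ValueError(f"records describe different positions: {sorted(positions)}")
    vals = [r.value for r in per_model]
    return statistics.fmean(vals), statistics.stdev(vals)


#: bulk-H enrichment beyond which the hybrid assembly is flagged as
#: overestimated relative to typical measured bulk-H fractionation
_BULK_H_OVERESTIMATE_PERMIL = -300.0


def hybrid_bulk(
    primary: PositionKIE,
    secondary: Sequence[PositionKIE],
    strict_provenance: bool = True,
) -> Tuple[BulkKIEResult, EnrichmentResult]:
    """Bulk KIE and ε from one primary (reactive-position) KIE plus secondaries.

    The intended assembly takes the primary effect from the path-integral
    route (``provenance='pi'``) and the n−1 secondary effects from cheaper
    models; ``strict_provenance=False`` relaxes the provenance requirement so
    purely semiclassical assemblies can reuse the same code path.
    """
    if strict_provenance and primary.provenance != "pi":
        raise ValueError(
            "hybrid assembly expects a path-integral primary KIE "
            "(provenance='pi'); pass strict_provenance=False to override"
        )
    bulk = average_kie([primary, *secondary])
    enr = enrichment_from_kie(bulk)
    if primary.element == "H" and enr.epsilon_permil < _BULK_H_OVERESTIMATE_PERMIL:
        enr = EnrichmentResult(
            element=enr.element,
            epsilon_permil=enr.epsilon_permil,
            flag="overestimated vs typical bulk-H measurements",
        )
    return bulk, enr


def infer_secondary_average(
    bulk_eps: EnrichmentResult, primary_kie: float, n: int
) -> Tuple[float, bool]:
    """Average secondary KIE implied by a bulk ε and an assumed primary KIE.

    Solves KIE_av = (primary + (n−1)·s̄)/n with KIE_av = 1 − ε/1000 for s̄ and
    reports whether the implied secondary average is inverse (s̄ < 1).  A
    measured bulk-H ε around −160 ‰ combined with a primary H KIE of 4–5
    implies strongly inverse secondary effects: this is the diagnostic this
    function automates.
    """
    if n < 2:
        raise ValueError("need n >= 2 positions to separate primary and secondary")
    kie_av = kie_av_from_epsilon(bulk_eps.epsilon_permil)
    s_bar = (n * kie_av - primary_kie) / (n - 1)
    if s_bar <= 0:
        raise ValueError(
            f"non-physical implied secondary KIE {s_bar:.4f} <= 0: the assumed "
            f"primary ({primary_kie}) is incompatible with bulk "
            f"epsilon={bulk_eps.epsilon_permil} permil at n={n}"
        )
    return s_bar, s_bar < 1.0


# ---------------------------------------------------------------- CSV I/O
def read_position_kies(path) -> list:
    """Read a position-KIE table (position, element, KIE[, provenance])."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                PositionKIE(
                    position=row["position"],
                    element=row["element"],
                    value=float(row["KIE"]),
                    provenance=row.get("provenance", "assumed") or "assumed",
                )
            )
    return records


def write_bulk_table(path, results: Sequence[Tuple[BulkKIEResult, EnrichmentResult]]) -> None:
    """Write bulk results as CSV (element, KIE_av, epsilon_permil, n, provenance mix)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["element", "KIE_av", "epsilon_permil", "n", "provenance_mix"])
        for bulk, enr in results:
            mix = "+".join(sorted({p.provenance for p in bulk.positions}))
            w.writerow(
                [bulk.element, f"{bulk.kie_av:.6f}", f"{enr.epsilon_permil:.4f}",
                 bulk.n, mix]
            )
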