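"""Linkage-map construction from adjacent-pair recombination fractions.

Adjacent marker pairs of each chromosome are estimated with a chosen
estimator, converted to additive map distances with the Haldane mapping
function ``d = -50 * ln(1 - 2*theta)`` cM (no crossover interference), and
accumulated into per-chromosome maps.  Marker order is taken from the
physical map and never re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import math

import numpy as np
import pandas as pd

from . import estimators as est
from .io import GenotypeMatrix, MarkerMap

__all__ = [
    "CAP_THETA",
    "haldane_cm",
    "haldane_theta",
    "AdjacentEstimates",
    "LinkageMap",
    "MethodAgreement",
    "estimate_adjacent",
    "assemble_map",
    "compare_methods",
]

#: Estimates at or above this value are mapped to the cM value at the cap and
#: flagged: the Haldane function diverges at theta = 0.5, which the
#: negative-correlation clamp can produce exactly.
CAP_THETA = 0.4999

_METHOD_ALIASES = {
    "pcorr": "pcorr",
    "em_codominant": "em_codominant",
    "emcd": "em_codominant",
    "em_dominant": "em_dominant",
    "emd": "em_dominant",
}


def haldane_cm(theta: float) -> float:
    """Haldane map distance in centimorgans for a recombination fraction.

    Values at or above :data:`CAP_THETA` return the (finite) distance at the
    cap; use ``theta >= CAP_THETA`` to detect capped segments.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")
    return -50.0 * math.log(1.0 - 2.0 * min(theta, CAP_THETA))


def haldane_theta(d_cm: float) -> float:
    """Inverse Haldane function: recombination fraction at a cM distance."""
    if d_cm < 0:
        raise ValueError(f"map distance must be non-negative, got {d_cm}")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


@dataclass
class AdjacentEstimates:
    """Recombination estimates for all within-chromosome adjacent pairs.

    ``table`` has one row per pair: chromosome, left, right, theta, se,
    clamped, converged, n, failed, reason.  Failed pairs (degenerate margins,
    all-missing data) are recorded with ``failed=True`` rather than dropped.
    """

    table: pd.DataFrame = field(repr=False)
    method: str = "pcorr"

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def thetas(self) -> np.ndarray:
        return self.table["theta"].to_numpy(dtype=float)


@dataclass
class LinkageMap:
    """Per-chromosome ordered markers with adjacent and cumulative distances."""

    table: pd.DataFrame = field(repr=False)

    def total_length_cm(self) -> float:
        return float(self.table["cm_to_next"].fillna(0.0).sum())

    def chromosome_lengths(self) -> pd.Series:
        return self.table.groupby("chromosome", sort=False)["cm_cumulative"].max()


@dataclass(frozen=True)
class MethodAgreement:
    """Agreement summary between two sets of adjacent estimates."""

    pearson_r: float
    mean_abs_difference: float
    n_pairs: int
    per_chromosome: pd.DataFrame = field(repr=False)


def _estimate_pair(
    g_a: np.ndarray, g_b: np.ndarray, method: str, opts: est.EMOptions
) -> est.RecombinationEstimate:
    table = est.build_joint_table(g_a, g_b)
    if method == "pcorr":
        return est.estimate_pcorr(table)
    if method == "em_codominant":
        return est.estimate_em_codominant(table, opts)
    if method == "em_dominant":
        return est.estimate_em_dominant(est.collapse_to_phenotypes(table), opts)
    raise ValueError(f"unknown estimator {method!r}")


def estimate_adjacent(
    g: GenotypeMatrix,
    mmap: MarkerMap,
    method: str = "pcorr",
    opts: Optional[est.EMOptions] = None,
) -> AdjacentEstimates:
    """Estimate theta for every within-chromosome adjacent marker pair.

    Markers are taken in map order; pairs whose estimator preconditions fail
    are recorded as failed with the reason, never silently dropped.
    """
    if method not in _METHOD_ALIASES:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(_METHOD_ALIASES)}"
        )
    method = _METHOD_ALIASES[method]
    opts = opts or est.EMOptions()
    marker_index = {mid: k for k, mid in enumerate(g.marker_ids)}
    unknown = [mid for mid in mmap.marker_ids if mid not in marker_index]
    if unknown:
        raise ValueError(f"markers in map but not in genotypes: {unknown[:5]}")
    rows = []
    for chrom in mmap.chromosomes:
        ids = mmap.chromosome_markers(chrom)["id"].tolist()
        for left, right in zip(ids[:-1], ids[1:]):
            row = {
                "chromosome": chrom,
                "left": left,
                "right": right,
                "theta": np.nan,
                "se": np.nan,
                "clamped": False,
                "converged": False,
                "n": 0,
                "failed": False,
                "reason": "",
            }
            try:
                r = _estimate_pair(
                    g.values[:, marker_index[left]],
                    g.values[:, marker_index[right]],
                    method,
                    opts,
                )
            except est.EstimationError as exc:
                row["failed"] = True
                row["reason"] = str(exc)
            else:
                row.update(
                    theta=r.theta,
                    se=np.nan if r.se is None else r.se,
                    clamped=r.clamped,
                    converged=r.converged,
                )
                row["n"] = int(np.sum((g.values[:, marker_index[left]] != est.MISSING)
                                      & (g.values[:, marker_index[right]] != est.MISSING)))
            rows.append(row)
    return AdjacentEstimates(pd.DataFrame(rows), method=method)


def assemble_map(adj: AdjacentEstimates) -> LinkageMap:
    """Convert adjacent estimates into a per-chromosome Haldane linkage map.

    Failed pairs contribute 0 cM and keep their ``failed`` flag so dense maps
    survive isolated failures while remaining auditable; estimates at the
    clamp boundary are capped and flagged.
    """
    rows = []
    for chrom, grp in adj.table.groupby("chromosome", sort=False):
        cum = 0.0
        for _, pair in grp.iterrows():
            failed = bool(pair["failed"])
            theta = float(pair["theta"]) if not failed else np.nan
            capped = (not failed) and theta >= CAP_THETA
            cm = 0.0 if failed else haldane_cm(theta)
            rows.append(
                {
                    "chromosome": chrom,
                    "marker": pair["left"],
                    "theta_to_next": theta,
                    "se_theta": float(pair["se"]),
                    "cm_to_next": cm,
                    "cm_cumulative": cum,
                    "capped": capped,
                    "failed": failed,
                }
            )
            cum += cm
        rows.append(
            {
                "chromosome": chrom,
                "marker": grp["right"].iloc[-1],
                "theta_to_next": np.nan,
                "se_theta": np.nan,
                "cm_to_next": np.nan,
                "cm_cumulative": cum,
                "capped": False,
                "failed": False,
            }
        )
    return LinkageMap(pd.DataFrame(rows))


def compare_methods(a: AdjacentEstimates, b: AdjacentEstimates) -> MethodAgreement:
    """Agreement between two estimators over the same adjacent pairs.

    Summaries (Pearson R of the theta vectors, mean absolute difference) are
    computed over pairs where both estimators succeeded, pooled and per
    chromosome.
    """
    key = ["chromosome", "left", "right"]
    ta = a.table.set_index(key)
    tb = b.table.set_index(key)
    if not ta.index.equals(tb.index):
        raise ValueError("adjacent-estimate sets cover different marker pairs")
    ok = ~(ta["failed"].to_numpy() | tb["failed"].to_numpy())
    xa = ta["theta"].to_numpy(dtype=float)[ok]
    xb = tb["theta"].to_numpy(dtype=float)[ok]
    if xa.size < 2:
        raise ValueError("fewer than 2 jointly successful pairs")
    pooled_r = float(np.corrcoef(xa, xb)[0, 1])
    mad = float(np.abs(xa - xb).mean())
    chroms = ta.index.get_level_values("chromosome").to_numpy()[ok]
    per = []
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        entry = {
            "chromosome": chrom,
            "n_pairs": int(sel.sum()),
            "mean_abs_difference": float(np.abs(xa[sel] - xb[sel]).mean()),
            "pearson_r": float(np.corrcoef(xa[sel], xb[sel])[0, 1])
            if sel.sum() >= 2
            else np.nan,
        }
        per.append(entry)
    return MethodAgreement(
        pearson_r=pooled_r,
        mean_abs_difference=mad,
        n_pairs=int(ok.sum()),
        per_chromosome=pd.DataFrame(per),
    )
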