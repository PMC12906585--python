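"""Readers and writers for genotype tables, marker maps and linkage maps.

Formats are plain delimited text (TSV canonical, comma via ``sep=","``):

* genotype table — header row of marker ids, first column individual ids,
  cells in {0, 1, 2} (allele count of the reference parent's allele) or
  NA/empty for missing;
* marker map — columns ``id  chromosome  position_bp  [position_cm]`` with
  strictly increasing physical positions within each chromosome;
* linkage map — columns ``chromosome  marker  theta_to_next  se_theta
  cm_to_next  cm_cumulative  capped  failed`` with the trailing marker of
  each chromosome carrying empty ``*_to_next`` fields.

Lines starting with ``#`` are treated as comments in all three formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimators import MISSING

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "GenotypeParseError",
    "MapValidationError",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_map",
    "write_marker_map",
    "write_linkage_map",
    "read_linkage_map",
]

PathLike = Union[str, Path]

_MISSING_TOKENS = {"", "na", "nan", "n/a", "."}


class GenotypeParseError(ValueError):
    """A genotype cell could not be parsed into {0, 1, 2, missing}."""


class MapValidationError(ValueError):
    """A marker map violates ordering or uniqueness constraints."""


@dataclass
class GenotypeMatrix:
    """Coded genotypes for a population: individuals x markers.

    ``values`` holds allele-count codes {0, 1, 2} with ``MISSING`` (-1) for
    missing cells.  ``generation_t`` records the selfing generation when
    known (t >= 2), e.g. 2 for an F2.
    """

    values: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    generation_t: Optional[int] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int16)
        if v.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        ok = np.isin(v, (MISSING, 0, 1, 2))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise GenotypeParseError(
                f"invalid genotype code {v[i, j]} for individual "
                f"{self.individual_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )
        if v.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("id lists inconsistent with value dimensions")
        for label, ids in (("individual", self.individual_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise MapValidationError(f"duplicate {label} ids: {dup[:5]}")
        self.values = v
        if self.generation_t is not None and self.generation_t < 2:
            raise ValueError("generation_t must be >= 2 when given")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def column(self, marker_id: str) -> np.ndarray:
        """Genotype codes of one marker across all individuals."""
        return self.values[:, self.marker_ids.index(marker_id)]


@dataclass
class MarkerMap:
    """Ordered marker metadata: id, chromosome, physical (and optional cM) position."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["id", "chromosome", "position_bp"]
        missing_cols = [c for c in required if c not in t.columns]
        if missing_cols:
            raise MapValidationError(f"marker map missing columns: {missing_cols}")
        if t["id"].duplicated().any():
            dup = t["id"][t["id"].duplicated()].tolist()
            raise MapValidationError(f"duplicate marker ids: {dup[:5]}")
        if (t["position_bp"] < 0).any():
            raise MapValidationError("positions must be non-negative")
        offenders = []
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            bad = np.flatnonzero(np.diff(pos) <= 0)
            offenders += [
                f"{chrom}:{grp['id'].iloc[k]}->{grp['id'].iloc[k + 1]}" for k in bad
            ]
        if offenders:
            raise MapValidationError(
                f"non-increasing positions within chromosome: {offenders[:5]}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def has_cm(self) -> bool:
        return "position_cm" in self.table.columns

    def chromosome_markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]


def read_genotype_table(
    path: PathLike, sep: str = "\t", generation_t: Optional[int] = None
) -> GenotypeMatrix:
    """Read a delimited genotype table (individuals x markers).

    Missing cells may be empty or any of NA/NaN/N/A/"." (case-insensitive);
    any other non-{0,1,2} cell raises :class:`GenotypeParseError` naming the
    offending row and column.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, comment="#",
                      keep_default_na=False)
    individual_ids = [str(x) for x in raw.index]
    marker_ids = [str(c) for c in raw.columns]
    values = np.empty(raw.shape, dtype=np.int16)
    cells = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(cells[i, j]).strip()
            if tok.lower() in _MISSING_TOKENS:
                values[i, j] = MISSING
            elif tok in ("0", "1", "2"):
                values[i, j] = int(tok)
            else:
                raise GenotypeParseError(
                    f"cannot parse genotype cell {tok!r} at individual "
                    f"{individual_ids[i]!r}, marker {marker_ids[j]!r}"
                )
    return GenotypeMatrix(values, individual_ids, marker_ids, generation_t)


def write_genotype_table(g: GenotypeMatrix, path: PathLike, sep: str = "\t") -> None:
    """Write a genotype table; missing codes are emitted as ``NA``."""
    frame = pd.DataFrame(
        np.where(g.values == MISSING, "NA", g.values.astype(object)),
        index=pd.Index(g.individual_ids, name="individual"),
        columns=g.marker_ids,
    )
    frame.to_csv(path, sep=sep)


def read_marker_map(path: PathLike, sep: str = "\t") -> MarkerMap:
    """Read a marker map TSV with columns id, chromosome, position_bp[, position_cm]."""
    t = pd.read_csv(path, sep=sep, comment="#", dtype={"id": str, "chromosome": str},
                    float_precision="round_trip")
    t["position_bp"] = t["position_bp"].astype(np.int64)
    if "position_cm" in t.columns:
        t["position_cm"] = t["position_cm"].astype(float)
    return MarkerMap(t)


def write_marker_map(mmap: MarkerMap, path: PathLike, sep: str = "\t") -> None:
    mmap.table.to_csv(path, sep=sep, index=False)


_LINKAGE_COLUMNS = [
    "chromosome",
    "marker",
    "theta_to_next",
    "se_theta",
    "cm_to_next",
    "cm_cumulative",
    "capped",
    "failed",
]


def write_linkage_map(lmap, path: PathLike, sep: str = "\t") -> None:
    """Write a linkage map TSV; the last marker of each chromosome has empty
    ``theta_to_next``/``cm_to_next`` fields."""
    t = lmap.table.loc[:, _LINKAGE_COLUMNS].copy()
    t["capped"] = t["capped"].astype(int)
    t["failed"] = t["failed"].astype(int)
    t.to_csv(path, sep=sep, index=False, na_rep="")


def read_linkage_map(path: PathLike, sep: str = "\t"):
    """Read a linkage map TSV back into a :class:`~corrlink.linkage.LinkageMap`."""
    from .linkage import LinkageMap

    t = pd.read_csv(
        path, sep=sep, comment="#",
        dtype={"chromosome": str, "marker": str},
        na_values=[""], keep_default_na=False,
        float_precision="round_trip",
    )
    missing_cols = [c for c in _LINKAGE_COLUMNS if c not in t.columns]
    if missing_cols:
        raise MapValidationError(f"linkage map missing columns: {missing_cols}")
    t["capped"] = t["capped"].astype(bool)
    t["failed"] = t["failed"].astype(bool)
    return LinkageMap(t.loc[:, _LINKAGE_COLUMNS])
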