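"""Pairwise recombination-fraction estimators for biparental selfing populations.

All estimators operate on the 3x3 table of joint genotype counts for one
marker pair, with genotypes coded as allele counts ``X in {0, 1, 2}`` of the
reference parent's allele.  The sufficient statistic is :class:`JointCountTable`
with ``m[i, j]`` = number of individuals with ``X_A = i`` and ``X_B = j``.

Four estimators of the recombination fraction ``theta`` are provided:

``pcorr``
    The correlation-converted estimator.  In an F_t population derived by
    selfing from inbred founders (no segregation distortion, no interference)
    the Pearson correlation between the two allele-count codes is
    ``r = 1 - 2*theta`` for every generation t >= 2, so
    ``theta_hat = (1 - r_hat)/2`` with standard error
    ``(1 - r^2) / (2*sqrt(n - 3))`` from Fisher's variance of ``r_hat``.
    Negative correlations are clamped to zero (``theta_hat = 0.5``).

``em_codominant``
    The classical EM estimator for fully informative (codominant) markers.
    Only the double heterozygote cell mixes recombinant classes: it is
    non-recombinant ``AB/ab`` or doubly recombinant ``Ab/aB``.  The E-step
    imputes the expected number of double recombinants; the M-step is the
    gamete-counting maximizer of the complete-data likelihood.

``em_dominant``
    The original Dempster et al. formulation for dominant markers, where only
    four phenotype classes are observed.  It iterates on ``pi = (1-theta)^2``
    and converts back with ``theta_hat = 1 - sqrt(pi_hat)``.

``bc_direct``
    Direct gamete counting in a backcross, where recombinants are observable.

Standard errors for both EM estimators come from the Louis observed
information: expected complete-data information minus the posterior variance
of the complete-data score, evaluated at the converged estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import xlogy

__all__ = [
    "MISSING",
    "EstimationError",
    "EMOptions",
    "JointCountTable",
    "PhenotypeCounts",
    "RecombinationEstimate",
    "ChiSquareResult",
    "build_joint_table",
    "collapse_to_phenotypes",
    "estimate_pcorr",
    "estimate_em_codominant",
    "estimate_em_dominant",
    "estimate_bc_direct",
    "loglik_codominant",
    "loglik_dominant",
    "segregation_chisq",
    "pooled_correlation",
]

#: Sentinel for a missing genotype code (distinct from every valid code).
MISSING = -1

#: Boundary tolerance below which an estimate is treated as sitting on the
#: edge of the parameter space, where observed information degenerates.
_BOUNDARY_EPS = 1e-9


class EstimationError(ValueError):
    """Raised when an estimator's preconditions cannot be met by the data."""


@dataclass(frozen=True)
class EMOptions:
    """Convergence controls for the EM estimators.

    ``tol`` applies to the iterated parameter itself (theta for the
    codominant model, pi for the dominant model).
    """

    theta_init: float = 0.25
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_init < 0.5:
            raise ValueError("theta_init must lie in (0, 0.5)")
        if self.tol <= 0.0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass(frozen=True)
class JointCountTable:
    """3x3 joint genotype counts for one marker pair.

    ``m[i, j]`` counts individuals with ``X_A = i`` and ``X_B = j`` for
    allele-count codes i, j in {0, 1, 2}.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.int64)
        if m.shape != (3, 3):
            raise ValueError(f"joint count table must be 3x3, got {m.shape}")
        if (m < 0).any():
            raise ValueError("joint count table entries must be non-negative")
        object.__setattr__(self, "m", m)

    @property
    def n(self) -> int:
        """Total number of (pairwise-complete) individuals."""
        return int(self.m.sum())

    def transpose(self) -> "JointCountTable":
        """Swap the roles of the two loci."""
        return JointCountTable(self.m.T.copy())

    def flip_both(self) -> "JointCountTable":
        """Relabel alleles at both loci simultaneously (180-degree rotation)."""
        return JointCountTable(self.m[::-1, ::-1].copy())

    def flip_a(self) -> "JointCountTable":
        """Relabel alleles at the first locus only (reverse rows)."""
        return JointCountTable(self.m[::-1, :].copy())


@dataclass(frozen=True)
class PhenotypeCounts:
    """Counts of the four dominant-phenotype classes AB, Ab, aB, ab."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    def __post_init__(self) -> None:
        for name in ("n_AB", "n_Ab", "n_aB", "n_ab"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab


@dataclass
class RecombinationEstimate:
    """A recombination-fraction estimate with its uncertainty and provenance.

    ``se`` is ``None`` when the estimate sits on a boundary of the parameter
    space where the observed information degenerates.  ``clamped`` marks a
    negative correlation that was set to zero (theta forced to 0.5).
    """

    theta: float
    se: Optional[float]
    method: str
    r: Optional[float] = None
    pi: Optional[float] = None
    iterations: int = 0
    converged: bool = True
    clamped: bool = False
    loglik: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError(f"theta must lie in [0, 0.5], got {self.theta}")
        if self.se is not None and self.se < 0:
            raise ValueError("standard error must be non-negative")


@dataclass(frozen=True)
class ChiSquareResult:
    """Goodness-of-fit test of one locus' genotype counts against F_t ratios."""

    statistic: float
    df: int
    p_value: float
    expected: np.ndarray = field(repr=False)


def build_joint_table(g_a: Sequence[int], g_b: Sequence[int]) -> JointCountTable:
    """Tally the 3x3 joint genotype counts for a marker pair.

    Only pairwise-complete entries (both codes non-missing) are counted;
    missing values are ``MISSING`` (-1) or NaN.
    """
    a = np.asarray(g_a)
    b = np.asarray(g_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("genotype vectors must be 1-D and of equal length")
    if np.issubdtype(a.dtype, np.floating) or np.issubdtype(b.dtype, np.floating):
        a = np.where(np.isnan(a.astype(float)), MISSING, a).astype(np.int64)
        b = np.where(np.isnan(b.astype(float)), MISSING, b).astype(np.int64)
    else:
        a = a.astype(np.int64)
        b = b.astype(np.int64)
    bad = ~np.isin(a, (MISSING, 0, 1, 2)) | ~np.isin(b, (MISSING, 0, 1, 2))
    if bad.any():
        raise EstimationError(
            f"genotype codes outside {{0,1,2,missing}} at positions {np.flatnonzero(bad)[:5]}"
        )
    keep = (a != MISSING) & (b != MISSING)
    if not keep.any():
        raise EstimationError("no pairwise-complete genotype pairs")
    m = np.zeros((3, 3), dtype=np.int64)
    np.add.at(m, (a[keep], b[keep]), 1)
    return JointCountTable(m)


def collapse_to_phenotypes(table: JointCountTable) -> PhenotypeCounts:
    """Collapse a codominant count table to the four dominant phenotype classes.

    Assumes coupling-phase coding: the allele counted by the code is dominant
    at both loci, so any individual with ``X >= 1`` shows the dominant
    phenotype at that locus.
    """
    m = table.m
    return PhenotypeCounts(
        n_AB=int(m[1:, 1:].sum()),
        n_Ab=int(m[1:, 0].sum()),
        n_aB=int(m[0, 1:].sum()),
        n_ab=int(m[0, 0]),
    )


def _table_correlation(table: JointCountTable) -> float:
    m = table.m
    n = table.n
    codes = np.arange(3, dtype=float)
    wa = m.sum(axis=1)
    wb = m.sum(axis=0)
    mean_a = float(wa @ codes) / n
    mean_b = float(wb @ codes) / n
    var_a = float(wa @ (codes - mean_a) ** 2) / n
    var_b = float(wb @ (codes - mean_b) ** 2) / n
    if var_a <= 0 or var_b <= 0:
        raise EstimationError("degenerate margin: zero variance at one locus")
    dev = np.outer(codes - mean_a, codes - mean_b)
    cov = float((m * dev).sum()) / n
    # rounding can push |r| past 1 by an ulp; keep theta = (1-r)/2 in domain
    return min(max(cov / math.sqrt(var_a * var_b), -1.0), 1.0)


def estimate_pcorr(table: JointCountTable) -> RecombinationEstimate:
    """Correlation-converted estimator ``theta_hat = (1 - r_hat)/2``.

    A negative sample correlation would map above 0.5, outside the parameter
    domain; it is clamped by setting ``r := 0`` (hence ``theta_hat = 0.5``)
    before the Fisher standard-error formula is applied.
    """
    n = table.n
    if n < 4:
        raise EstimationError("pcorr requires at least 4 complete pairs (SE needs n > 3)")
    r = _table_correlation(table)
    clamped = r < 0.0
    if clamped:
        r = 0.0
    theta = (1.0 - r) / 2.0
    se = (1.0 - r * r) / (2.0 * math.sqrt(n - 3))
    return RecombinationEstimate(theta=theta, se=se, method="pcorr", r=r, clamped=clamped)


def _codominant_sufficient(table: JointCountTable) -> tuple[int, int, int]:
    """Return (m0, m2, m22): gamete-count weights and the mixed centre cell.

    ``m0`` weights non-recombinant gametes, ``m2`` recombinant gametes from
    the unambiguous cells; the double heterozygote ``m22`` is the mixture cell.
    """
    m = table.m
    sides = int(m[0, 1] + m[1, 0] + m[1, 2] + m[2, 1])
    m0 = 2 * int(m[0, 0] + m[2, 2]) + sides
    m2 = 2 * int(m[0, 2] + m[2, 0]) + sides
    return m0, m2, int(m[1, 1])


def loglik_codominant(theta: float, table: JointCountTable) -> float:
    """Observed-data log-likelihood of the codominant F2 mixture model.

    Cells are pooled by recombinant class; the double-heterozygote cell is the
    mixture ``(theta^2 + (1-theta)^2)/2``.  Constant factors are kept so the
    value is a true log-likelihood (up to the multinomial coefficient).
    """
    m = table.m
    corners_c = int(m[0, 0] + m[2, 2])
    corners_r = int(m[0, 2] + m[2, 0])
    sides = int(m[0, 1] + m[1, 0] + m[1, 2] + m[2, 1])
    centre = int(m[1, 1])
    return float(
        xlogy(corners_c, 0.5 * (1.0 - theta) ** 2)
        + xlogy(corners_r, 0.5 * theta**2)
        + xlogy(sides, 2.0 * theta * (1.0 - theta))
        + xlogy(centre, 0.5 * (theta**2 + (1.0 - theta) ** 2))
    )


def _louis_se_codominant(theta: float, m0: int, m2: int, m22: int) -> Optional[float]:
    if theta <= _BOUNDARY_EPS or theta >= 0.5 - _BOUNDARY_EPS:
        return None
    rho = theta**2 / (theta**2 + (1.0 - theta) ** 2)
    complete_info = (m2 + 2.0 * rho * m22) / theta**2 + (m0 + 2.0 * (1.0 - rho) * m22) / (
        1.0 - theta
    ) ** 2
    score_var = (2.0 / (theta * (1.0 - theta))) ** 2 * m22 * rho * (1.0 - rho)
    info = complete_info - score_var
    if info <= 0:
        return None
    return 1.0 / math.sqrt(info)


def estimate_em_codominant(
    table: JointCountTable, opts: EMOptions = EMOptions()
) -> RecombinationEstimate:
    """EM estimator for codominant markers with Louis-information SE.

    The E-step imputes the expected number of double recombinants in the
    double-heterozygote cell with posterior probability
    ``rho = theta^2 / (theta^2 + (1-theta)^2)``; the M-step is recombinant
    gamete counting: ``theta <- (m2 + 2*rho*m22) / (2n)``.
    """
    n = table.n
    if n < 1:
        raise EstimationError("empty count table")
    m0, m2, m22 = _codominant_sufficient(table)
    theta = opts.theta_init
    converged = False
    iterations = 0
    for iterations in range(1, opts.max_iter + 1):
        denom = theta**2 + (1.0 - theta) ** 2
        rho = theta**2 / denom
        new = (m2 + 2.0 * rho * m22) / (2.0 * n)
        new = min(max(new, 0.0), 0.5)
        if abs(new - theta) < opts.tol:
            theta = new
            converged = True
            break
        theta = new
    se = _louis_se_codominant(theta, m0, m2, m22)
    return RecombinationEstimate(
        theta=theta,
        se=se,
        method="em_codominant",
        iterations=iterations,
        converged=converged,
        loglik=loglik_codominant(theta, table),
    )


def loglik_dominant(pi: float, counts: PhenotypeCounts) -> float:
    """Observed-data log-likelihood of the dominant four-class model in pi."""
    return float(
        xlogy(counts.n_AB, 0.5 + 0.25 * pi)
        + xlogy(counts.n_Ab + counts.n_aB, 0.25 * (1.0 - pi))
        + xlogy(counts.n_ab, 0.25 * pi)
    )


def _louis_se_dominant(pi: float, counts: PhenotypeCounts) -> Optional[float]:
    if pi <= _BOUNDARY_EPS or pi >= 1.0 - _BOUNDARY_EPS:
        return None
    rho = pi / (2.0 + pi)
    info = (
        (rho * counts.n_AB + counts.n_ab) / pi**2
        + (counts.n_Ab + counts.n_aB) / (1.0 - pi) ** 2
        - counts.n_AB * rho * (1.0 - rho) / pi**2
    )
    if info <= 0:
        return None
    var_pi = 1.0 / info
    var_theta = var_pi / (4.0 * pi)
    return math.sqrt(var_theta)


def estimate_em_dominant(
    counts: PhenotypeCounts, opts: EMOptions = EMOptions()
) -> RecombinationEstimate:
    """Dempster's EM for dominant markers, on ``pi = (1 - theta)^2``.

    The dominant AB class mixes a constant-probability component with a
    ``pi/4`` component; the E-step imputes the latter's count.  The SE comes
    from Louis information on pi mapped through the delta method
    ``var(theta) = var(pi) / (4*pi)``.
    """
    total = counts.total
    if total < 1:
        raise EstimationError("empty phenotype counts")
    pi = (1.0 - opts.theta_init) ** 2
    converged = False
    iterations = 0
    for iterations in range(1, opts.max_iter + 1):
        num = pi * counts.n_AB + (2.0 + pi) * counts.n_ab
        den = pi * counts.n_AB + (2.0 + pi) * (counts.n_ab + counts.n_Ab + counts.n_aB)
        if den == 0.0:
            # Only the AB class is occupied: complete linkage, pi -> 1.
            pi = 1.0
            converged = True
            break
        new = num / den
        if abs(new - pi) < opts.tol:
            pi = new
            converged = True
            break
        pi = new
    theta = min(max(1.0 - math.sqrt(pi), 0.0), 0.5)
    se = _louis_se_dominant(pi, counts)
    return RecombinationEstimate(
        theta=theta,
        se=se,
        method="em_dominant",
        pi=pi,
        iterations=iterations,
        converged=converged,
        loglik=loglik_dominant(pi, counts),
    )


def estimate_bc_direct(
    n_AB: int, n_Ab: int, n_aB: int, n_ab: int
) -> RecombinationEstimate:
    """Direct recombinant counting in a backcross.

    The four counts are the two-locus BC genotype classes AB/ab, Ab/ab,
    aB/ab and ab/ab; Ab/ab and aB/ab carry the recombinant gamete.
    """
    total = n_AB + n_Ab + n_aB + n_ab
    if total < 1:
        raise EstimationError("empty backcross counts")
    if min(n_AB, n_Ab, n_aB, n_ab) < 0:
        raise EstimationError("backcross counts must be non-negative")
    theta = (n_Ab + n_aB) / total
    clamped = theta > 0.5
    if clamped:
        theta = 0.5
    se = math.sqrt(theta * (1.0 - theta) / total)
    return RecombinationEstimate(theta=theta, se=se, method="bc_direct", clamped=clamped)


def segregation_chisq(counts: Sequence[int], generation: int = 2) -> ChiSquareResult:
    """Chi-square goodness of fit of one locus' genotype counts to F_t ratios.

    The expected proportions at generation t are ((1-H)/2, H, (1-H)/2) with
    heterozygosity ``H = (1/2)^(t-1)`` (1:2:1 for an F2).  The count order is
    (homozygote, heterozygote, homozygote); df = 2.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (3,):
        raise ValueError("expected exactly 3 genotype counts")
    if (obs < 0).any() or obs.sum() < 1:
        raise EstimationError("counts must be non-negative with total >= 1")
    if generation < 2:
        raise ValueError("generation must be >= 2")
    h = 0.5 ** (generation - 1)
    expected = obs.sum() * np.array([(1.0 - h) / 2.0, h, (1.0 - h) / 2.0])
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return ChiSquareResult(
        statistic=statistic,
        df=2,
        p_value=float(stats.chi2.sf(statistic, 2)),
        expected=expected,
    )


def pooled_correlation(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]]
) -> float:
    """Pooled within-family correlation between two marker codes.

    Cross-products of within-group deviations are summed over groups and
    normalized by the pooled within-group sums of squares.  With a single
    group this is the ordinary Pearson correlation.  Intended for estimating
    recombination in collections of families where linkage disequilibrium is
    maintained within, but not between, families.
    """
    if len(groups) < 1:
        raise EstimationError("at least one group is required")
    sxy = sxx = syy = 0.0
    for k, (x, y) in enumerate(groups):
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape or xv.ndim != 1:
            raise ValueError(f"group {k}: vectors must be 1-D and of equal length")
        keep = ~(np.isnan(xv) | np.isnan(yv)) & (xv != MISSING) & (yv != MISSING)
        xv, yv = xv[keep], yv[keep]
        if xv.size < 2:
            raise EstimationError(f"group {k}: fewer than 2 complete pairs")
        dx = xv - xv.mean()
        dy = yv - yv.mean()
        sxy += float(dx @ dy)
        sxx += float(dx @ dx)
        syy += float(dy @ dy)
    if sxx <= 0 or syy <= 0:
        raise EstimationError("zero pooled within-group variance")
    return sxy / math.sqrt(sxx * syy)
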