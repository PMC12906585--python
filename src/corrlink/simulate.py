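"""Synthetic F_t biparental populations for estimator validation.

Two complementary simulation modes are provided.

*Table mode* (:func:`simulate_ft_pair` without distortion) draws i.i.d.
two-locus genotypes from the generalized F_t joint probability table, in
which ``theta`` is the generation-t *effective* recombination fraction: the
table has single-locus margins ``((1-H)/2, H, (1-H)/2)`` with heterozygosity
``H = (1/2)^(t-1)``, allele-count correlation exactly ``1 - 2*theta``, and a
double-heterozygote cell that splits into non-recombinant and doubly
recombinant classes in the proportions the codominant EM assumes.  At t = 2
it coincides with the classical F2 table built from two independent F1
gametes.  This is the fast mode used for estimator calibration.

*Mechanistic mode* tracks meioses explicitly.  For a marker pair,
:func:`ft_recursion_table` iterates the exact 16-state haplotype-pair selfing
recursion with a per-meiosis recombination fraction (this is also where
gamete-level segregation distortion enters); for whole chromosomes,
:func:`simulate_ft_genome` advances single-seed-descent lines through the
Poisson-crossover meiosis engine.  Only the mechanistic mode reproduces the
expansion of the estimated map across generations, because recombination
accumulates: the generation-t effective fraction exceeds the per-meiosis one
(``2*theta/(1+2*theta)`` in the inbred limit).  :func:`effective_theta` and
:func:`meiotic_theta` convert between the two scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import estimators as est
from . import mating
from .io import GenotypeMatrix, MarkerMap

__all__ = [
    "DistortionSpec",
    "FtPairConfig",
    "SimStudyResult",
    "heterozygosity",
    "gamete_probabilities",
    "ft_joint_table",
    "ft_recursion_table",
    "effective_theta",
    "meiotic_theta",
    "simulate_ft_pair",
    "simulate_ft_genome",
    "run_bias_study",
]

#: Gamete (haplotype) class order used throughout: AB, Ab, aB, ab.
GAMETE_CLASSES = ("AB", "Ab", "aB", "ab")


def heterozygosity(t: int) -> float:
    """Expected per-locus heterozygosity ``H_t = (1/2)^(t-1)`` at generation t."""
    if t < 2:
        raise ValueError("generation t must be >= 2")
    return 0.5 ** (t - 1)


@dataclass(frozen=True)
class DistortionSpec:
    """Multiplicative re-weighting of gamete classes before renormalization.

    ``allelic`` favours gametes carrying the A allele (AB and Ab);
    ``nonrecombinant`` favours parental gametes (AB and ab).  Weight 1 leaves
    the baseline untouched.
    """

    kind: str
    weight: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("allelic", "nonrecombinant"):
            raise ValueError("kind must be 'allelic' or 'nonrecombinant'")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class FtPairConfig:
    """One two-locus simulation: effective theta, generation, sample size, seed."""

    theta: float
    n: int
    t: int = 2
    seed: int = 0
    distortion: Optional[DistortionSpec] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must lie in [0, 0.5]")
        if self.t < 2 or self.n < 1:
            raise ValueError("need t >= 2 and n >= 1")


@dataclass
class SimStudyResult:
    """Per-(theta, method) means and SDs of replicated estimates."""

    table: pd.DataFrame
    n: int
    reps: int

    def cell(self, theta: float, method: str) -> pd.Series:
        t = self.table
        match = t[(np.isclose(t["theta"], theta)) & (t["method"] == method)]
        if len(match) != 1:
            raise KeyError(f"no unique study cell for theta={theta}, method={method}")
        return match.iloc[0]


def gamete_probabilities(
    theta: float, distortion: Optional[DistortionSpec] = None
) -> np.ndarray:
    """Gamete class probabilities (AB, Ab, aB, ab) from a coupling-phase parent.

    Baseline ``((1-theta)/2, theta/2, theta/2, (1-theta)/2)``; distortion
    multiplies the favoured classes by its weight and renormalizes.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    p = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    if distortion is not None:
        w = np.ones(4)
        if distortion.kind == "allelic":
            w[[0, 1]] = distortion.weight
        else:
            w[[0, 3]] = distortion.weight
        p = p * w
        p /= p.sum()
    return p


def ft_joint_table(theta: float, t: int = 2) -> np.ndarray:
    """Generalized F_t 3x3 joint genotype table at effective theta.

    Rows index ``X_A``, columns ``X_B``.  Closed form: with
    ``rho = theta^2/(theta^2 + (1-theta)^2)`` the side cells are
    ``H*(theta-rho)/(1-2*rho)``, the centre ``H*(1-2*theta)/(1-2*rho)``, the
    coupling corners ``((1-H)*(1-theta) - side)/2`` and the repulsion corners
    complete the margins.  Reduces to the classical F2 table at t = 2.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    h = heterozygosity(t)
    if theta >= 0.5:
        side, centre = h / 4.0, h / 2.0
    else:
        rho = theta**2 / (theta**2 + (1.0 - theta) ** 2)
        side = h * (theta - rho) / (1.0 - 2.0 * rho)
        centre = h * (1.0 - 2.0 * theta) / (1.0 - 2.0 * rho)
    coupling = ((1.0 - h) * (1.0 - theta) - side) / 2.0
    repulsion = (1.0 - h) / 2.0 - coupling - side
    q = np.array(
        [
            [coupling, side, repulsion],
            [side, centre, side],
            [repulsion, side, coupling],
        ]
    )
    if (q < -1e-12).any():
        raise ValueError(f"no valid F_t table at theta={theta}, t={t}")
    q = np.clip(q, 0.0, None)
    return q / q.sum()


def _haplotype_alleles(h: int) -> tuple[int, int]:
    # class index -> (A-allele count contribution, B-allele count contribution)
    return (1 if h < 2 else 0, 1 if h % 2 == 0 else 0)


def _gamete_distribution(
    h1: int, h2: int, theta: float, distortion: Optional[DistortionSpec]
) -> np.ndarray:
    a1, b1 = _haplotype_alleles(h1)
    a2, b2 = _haplotype_alleles(h2)

    def cls(a: int, b: int) -> int:
        return (1 - a) * 2 + (1 - b)

    p = np.zeros(4)
    p[cls(a1, b1)] += (1.0 - theta) / 2.0
    p[cls(a2, b2)] += (1.0 - theta) / 2.0
    p[cls(a1, b2)] += theta / 2.0
    p[cls(a2, b1)] += theta / 2.0
    if distortion is not None:
        w = np.ones(4)
        if distortion.kind == "allelic":
            w[[0, 1]] = distortion.weight
        else:
            w[[0, 3]] = distortion.weight
        p = p * w
        p /= p.sum()
    return p


def ft_recursion_table(
    theta_meiotic: float, t: int, distortion: Optional[DistortionSpec] = None
) -> np.ndarray:
    """Exact F_t two-locus genotype distribution from the selfing recursion.

    The state is the ordered pair of parental haplotypes; each generation an
    individual is replaced by two independent gametes of its own meiosis
    (per-meiosis recombination ``theta_meiotic``; optional gamete-level
    distortion applied at every meiosis).  Starts from the coupling F1 AB/ab.
    """
    if not 0.0 <= theta_meiotic <= 0.5:
        raise ValueError("theta_meiotic must lie in [0, 0.5]")
    if t < 2:
        raise ValueError("generation t must be >= 2")
    cur = np.zeros((4, 4))
    cur[0, 3] = 1.0
    for _ in range(t - 1):
        nxt = np.zeros((4, 4))
        for h1 in range(4):
            for h2 in range(4):
                w = cur[h1, h2]
                if w == 0.0:
                    continue
                g = _gamete_distribution(h1, h2, theta_meiotic, distortion)
                nxt += w * np.outer(g, g)
        cur = nxt
    table = np.zeros((3, 3))
    for h1 in range(4):
        a1, b1 = _haplotype_alleles(h1)
        for h2 in range(4):
            a2, b2 = _haplotype_alleles(h2)
            table[a1 + a2, b1 + b2] += cur[h1, h2]
    return table


def _table_correlation(table: np.ndarray) -> float:
    codes = np.arange(3.0)
    pa = table.sum(axis=1)
    pb = table.sum(axis=0)
    ma, mb = pa @ codes, pb @ codes
    va = pa @ (codes - ma) ** 2
    vb = pb @ (codes - mb) ** 2
    cov = float((table * np.outer(codes - ma, codes - mb)).sum())
    return cov / math.sqrt(va * vb)


def effective_theta(theta_meiotic: float, t: int) -> float:
    """Generation-t effective recombination fraction of a per-meiosis theta.

    Defined through the allele-count correlation of the exact recursion
    distribution, ``theta_eff = (1 - r_t)/2``; equals the per-meiosis value
    at t = 2 and approaches ``2*theta/(1+2*theta)`` as t grows.
    """
    if theta_meiotic == 0.0:
        return 0.0
    return (1.0 - _table_correlation(ft_recursion_table(theta_meiotic, t))) / 2.0


def meiotic_theta(theta_effective: float, t: int) -> float:
    """Per-meiosis recombination fraction whose generation-t effect is given."""
    if not 0.0 <= theta_effective <= 0.5:
        raise ValueError("theta_effective must lie in [0, 0.5]")
    if t == 2 or theta_effective in (0.0, 0.5):
        return theta_effective
    return float(
        brentq(lambda x: effective_theta(x, t) - theta_effective, 0.0, 0.5, xtol=1e-13)
    )


def simulate_ft_pair(cfg: FtPairConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw n two-locus genotype code pairs from an F_t population.

    Without distortion, draws come from the generalized table at effective
    ``cfg.theta`` (table mode).  With distortion, draws come from the
    mechanistic selfing recursion with per-meiosis ``cfg.theta`` and
    distorted gametes at every meiosis — at t = 2 this is exactly two
    independent distorted F1 gametes per individual.
    """
    if cfg.distortion is None:
        cells = ft_joint_table(cfg.theta, cfg.t)
    else:
        cells = ft_recursion_table(cfg.theta, cfg.t, cfg.distortion)
    rng = np.random.default_rng(cfg.seed)
    counts = rng.multinomial(cfg.n, cells.ravel())
    flat = np.repeat(np.arange(9), counts)
    rng.shuffle(flat)
    return flat // 3, flat % 3


def simulate_ft_genome(
    mmap: MarkerMap, t: int, n: int, seed: int = 0
) -> GenotypeMatrix:
    """Simulate n single-seed-descent F_t lines over a marker map (cM needed).

    Founders are fixed for alternative alleles at every marker, the F1 is
    fully heterozygous, and each generation advances every line by one
    selfing (one offspring per line) through the Poisson-crossover meiosis
    engine.
    """
    if t < 2:
        raise ValueError("generation t must be >= 2")
    if not mmap.has_cm:
        raise ValueError("marker map needs position_cm for mechanistic simulation")
    rng = np.random.default_rng(seed)
    m = len(mmap.marker_ids)
    haps = np.empty((n, 2, m), dtype=np.int8)
    haps[:, 0, :] = 1
    haps[:, 1, :] = 0
    for _ in range(t - 1):
        haps = mating.self_population(haps, mmap, rng)
    values = haps.sum(axis=1).astype(np.int16)
    ids = [f"line{i + 1}" for i in range(n)]
    return GenotypeMatrix(values, ids, list(mmap.marker_ids), generation_t=t)


_STUDY_METHODS = ("pcorr", "em_codominant", "em_dominant")


def run_bias_study(
    theta_grid: Sequence[float],
    n: int = 200,
    reps: int = 100,
    methods: Sequence[str] = _STUDY_METHODS,
    seed: int = 0,
    distortion: Optional[DistortionSpec] = None,
    t: int = 2,
    opts: Optional[est.EMOptions] = None,
) -> SimStudyResult:
    """Replicated bias/SE study of the estimators over a theta grid.

    For each theta, ``reps`` F_t populations of ``n`` individuals are drawn
    and every requested estimator is applied to each; the replicate mean and
    SD are tabulated per (theta, method).  Randomness is split per replicate
    from the single seed, so results are reproducible and order-independent.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    unknown = [m for m in methods if m not in _STUDY_METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    opts = opts or est.EMOptions()
    rows = []
    root = np.random.SeedSequence(seed)
    for theta in theta_grid:
        estimates: dict[str, list[float]] = {m: [] for m in methods}
        child_seeds = root.spawn(reps)
        for rep in range(reps):
            rep_seed = int(child_seeds[rep].generate_state(1)[0]) % 2**31
            cfg = FtPairConfig(
                theta=float(theta), n=n, t=t,
                seed=rep_seed, distortion=distortion,
            )
            g_a, g_b = simulate_ft_pair(cfg)
            table = est.build_joint_table(g_a, g_b)
            for method in methods:
                if method == "pcorr":
                    r = est.estimate_pcorr(table)
                elif method == "em_codominant":
                    r = est.estimate_em_codominant(table, opts)
                else:
                    r = est.estimate_em_dominant(
                        est.collapse_to_phenotypes(table), opts
                    )
                estimates[method].append(r.theta)
        for method in methods:
            vals = np.asarray(estimates[method])
            rows.append(
                {
                    "theta": float(theta),
                    "method": method,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if reps > 1 else np.nan,
                    "reps": reps,
                }
            )
    return SimStudyResult(pd.DataFrame(rows), n=n, reps=reps)
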