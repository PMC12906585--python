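"""Worked-example data: two-locus genotype counts from a rice F2 population.

Two adjacent marker-bin pairs from a 191-plant rice F2 population (a
Zhenshan97 x Minghui63 cross), one pair from chromosome 1 and one from
chromosome 4.  The chromosome 4 pair shows marked segregation distortion at
both loci and is the standard demonstration of where the correlation
estimator and the EM estimators part ways.

Counts are stored in allele-count orientation: row i = ``X_A = i``,
column j = ``X_B = j`` for i, j in {0, 1, 2}.
"""

from __future__ import annotations

import numpy as np

from .estimators import JointCountTable

__all__ = ["rice_pair_chr1", "rice_pair_chr4"]


def rice_pair_chr1() -> JointCountTable:
    """Bin151/Bin152 pair on chromosome 1 (n = 191, near-Mendelian ratios)."""
    return JointCountTable(
        np.array(
            [
                [41, 4, 0],
                [0, 100, 3],
                [0, 2, 41],
            ]
        )
    )


def rice_pair_chr4() -> JointCountTable:
    """Bin747/Bin748 pair on chromosome 4 (n = 191, strong distortion)."""
    return JointCountTable(
        np.array(
            [
                [18, 0, 0],
                [3, 103, 4],
                [2, 2, 59],
            ]
        )
    )
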