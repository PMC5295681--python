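"""Two-level analysis of molecular variance (AMOVA) with a permutation
test on the fixation index.

Follows the classical distance-based decomposition for haplotypic data:
squared inter-individual distances are summed into total and within-group
sums of squares, variance components are extracted with the unequal-sample-
size correction, and significance is assessed by permuting individuals
among groups with group sizes held fixed.  For sequence data the number of
pairwise differences is conventionally used directly as the squared
distance; pass ``square=True`` to square a metric distance instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import LineagePartition
from .distances import DistanceMatrix

__all__ = ["AmovaResult", "amova_two_level"]


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    Va: float
    Vb: float
    pct_among: float
    pct_within: float
    Fst: float
    p_value: float
    n_permutations: int
    degenerate: bool = False
    negative_Va: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"source": "among groups", "df": self.df_among,
             "sum_of_squares": self.ss_among, "variance_component": self.Va,
             "pct_variation": self.pct_among, "Fst": self.Fst,
             "p_value": self.p_value},
            {"source": "within groups", "df": self.df_within,
             "sum_of_squares": self.ss_within, "variance_component": self.Vb,
             "pct_variation": self.pct_within, "Fst": np.nan,
             "p_value": np.nan},
        ])


def _ss_decomposition(D2: np.ndarray, group_idx: list[np.ndarray]):
    N = D2.shape[0]
    iu, ju = np.triu_indices(N, k=1)
    ss_total = D2[iu, ju].sum() / N
    ss_within = 0.0
    for idx in group_idx:
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, k=1).sum() / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def _fst(D2: np.ndarray, group_idx: list[np.ndarray]):
    N = D2.shape[0]
    P = len(group_idx)
    sizes = np.array([len(g) for g in group_idx])
    ss_total, ss_within, ss_among = _ss_decomposition(D2, group_idx)
    Vb = ss_within / (N - P)
    n_bar = (N - (sizes ** 2).sum() / N) / (P - 1)
    Va = (ss_among / (P - 1) - Vb) / n_bar
    denom = Va + Vb
    Fst = Va / denom if denom != 0 else 0.0
    return ss_total, ss_within, ss_among, Va, Vb, Fst


def amova_two_level(
    D: DistanceMatrix,
    part: LineagePartition,
    n_perm: int = 20000,
    seed: int | None = None,
    square: bool = False,
) -> AmovaResult:
    """One-level grouping AMOVA (among / within groups) from distances.

    ``D`` typically holds pairwise difference counts, used directly as
    squared distances (``square=False``).  The permutation p-value is
    ``(# permuted Fst >= observed + 1) / (n_perm + 1)`` under random
    reassignment of individuals to groups of fixed sizes.
    """
    pos = {s: i for i, s in enumerate(D.ids)}
    groups = part.groups()
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    missing = set(D.ids) - set(part.group_of)
    if missing:
        raise ValueError(f"partition does not cover: {sorted(missing)}")
    if np.isnan(D.values).any():
        raise ValueError("distance matrix is incomplete")
    group_idx = [np.array(sorted(pos[s] for s in mem))
                 for _, mem in sorted(groups.items())]
    N = D.n
    P = len(group_idx)
    D2 = D.values ** 2 if square else D.values.astype(float)

    ss_total, ss_within, ss_among, Va, Vb, Fst = _fst(D2, group_idx)
    degenerate = ss_total == 0.0
    negative_Va = Va < 0

    total_var = Va + Vb
    if total_var != 0:
        pct_among = 100.0 * Va / total_var
        pct_within = 100.0 * Vb / total_var
    else:
        pct_among = pct_within = 0.0

    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        sizes = [len(g) for g in group_idx]
        bounds = np.cumsum([0] + sizes)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            pidx = [perm[bounds[i]:bounds[i + 1]] for i in range(P)]
            f = _fst(D2, pidx)[5]
            if f >= Fst:
                exceed += 1
        p_value = (exceed + 1) / (n_perm + 1)
    else:
        p_value = np.nan

    return AmovaResult(
        df_among=P - 1, df_within=N - P,
        ss_among=float(ss_among), ss_within=float(ss_within),
        ss_total=float(ss_total),
        Va=float(Va), Vb=float(Vb),
        pct_among=float(pct_among), pct_within=float(pct_within),
        Fst=float(Fst) if not degenerate else 0.0,
        p_value=p_value, n_permutations=n_perm,
        degenerate=degenerate, negative_Va=negative_Va,
    )
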