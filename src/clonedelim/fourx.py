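"""Birky's 4x rule for delimiting parthenogenetic species.

Two clades of a clonal organism are judged separate species when the
corrected between-clade distance K exceeds four times the within-clade
diversity parameter theta, estimated from nucleotide diversity as
``theta = pi / (1 - 4 pi / 3)``.  When the two clades' theta values differ,
the larger is used.  Exactly-4 ratios get an explicit ``boundary`` verdict
because the published statements of the rule overlap at the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import Alignment, LineagePartition
from .distances import CladeDiversity, DistanceMatrix, nucleotide_diversity

__all__ = [
    "FourXResult", "theta_estimator", "k_between", "four_x_test",
    "four_x_all_pairs", "clade_diversity_table",
]

_BOUNDARY_TOL = 1e-9


@dataclass
class FourXResult:
    clade_a: str
    clade_b: str
    K: float
    theta: float
    ratio: float
    verdict: str  # same_species | different_species | boundary

    def as_row(self) -> dict:
        return {
            "clade_a": self.clade_a, "clade_b": self.clade_b,
            "K": self.K, "theta": self.theta, "K_over_theta": self.ratio,
            "verdict": self.verdict,
        }


def theta_estimator(pi: float) -> float:
    """theta = pi / (1 - 4 pi / 3); pole at pi = 0.75."""
    if pi < 0:
        raise ValueError("pi must be non-negative")
    if pi >= 0.75:
        raise ValueError("pi >= 0.75: theta estimator undefined (pole)")
    return pi / (1.0 - 4.0 * pi / 3.0)


def k_between(
    D_corrected: DistanceMatrix, part: LineagePartition, a: str, b: str
) -> float:
    """Mean corrected distance over all cross pairs of clades a and b."""
    if a == b:
        raise ValueError("clades must differ")
    groups = part.groups()
    for g in (a, b):
        if g not in groups or not groups[g]:
            raise ValueError(f"clade '{g}' is empty or unknown")
    pos = {s: i for i, s in enumerate(D_corrected.ids)}
    ia = [pos[s] for s in groups[a]]
    ib = [pos[s] for s in groups[b]]
    block = D_corrected.values[np.ix_(ia, ib)]
    if np.isnan(block).any():
        bad = [(D_corrected.ids[ia[i]], D_corrected.ids[ib[j]])
               for i, j in zip(*np.where(np.isnan(block)))]
        raise ValueError(f"missing corrected distances for cross pairs: {bad}")
    return float(block.mean())


def four_x_test(K: float, theta_a: float, theta_b: float,
                clade_a: str = "a", clade_b: str = "b") -> FourXResult:
    """Apply the 4x decision rule to one clade pair.

    Uses the larger of the two theta values.  ratio > 4 -> different
    species; ratio < 4 -> same species; ratio = 4 (within 1e-9) ->
    boundary.  A zero theta with positive K is treated as infinite ratio.
    """
    if K < 0 or theta_a < 0 or theta_b < 0:
        raise ValueError("K and theta must be non-negative")
    theta = max(theta_a, theta_b)
    if theta == 0.0:
        if K == 0.0:
            warnings.warn("K = 0 and theta = 0: 4x ratio undefined")
            return FourXResult(clade_a, clade_b, K, theta, np.nan, "boundary")
        return FourXResult(clade_a, clade_b, K, theta, np.inf,
                           "different_species")
    ratio = K / theta
    if abs(ratio - 4.0) <= _BOUNDARY_TOL:
        verdict = "boundary"
    elif ratio > 4.0:
        verdict = "different_species"
    else:
        verdict = "same_species"
    return FourXResult(clade_a, clade_b, K, theta, ratio, verdict)


def clade_diversity_table(
    aln: Alignment, part: LineagePartition
) -> list[CladeDiversity]:
    """Per-clade pi, d, n, L and theta (the S2-style report)."""
    return [
        nucleotide_diversity(aln, members, group=g)
        for g, members in sorted(part.groups().items())
    ]


def four_x_all_pairs(
    aln: Alignment,
    D_corrected: DistanceMatrix,
    part: LineagePartition,
):
    """Pairwise 4x tests plus the implied overall species grouping.

    Returns ``(results, species_groups, conflicts)`` where species groups
    are the connected components of the ``same_species`` relation
    (boundary verdicts do not merge) and ``conflicts`` lists clade pairs
    judged different inside a merged component (non-transitive verdicts).
    """
    labels = sorted(part.groups())
    if len(labels) < 2:
        raise ValueError("need at least 2 clades")
    div = {cd.group: cd for cd in clade_diversity_table(aln, part)}
    results: list[FourXResult] = []
    parent = {g: g for g in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            K = k_between(D_corrected, part, a, b)
            res = four_x_test(K, div[a].theta, div[b].theta, a, b)
            results.append(res)
            if res.verdict == "same_species":
                parent[find(a)] = find(b)

    comps: dict[str, list[str]] = {}
    for g in labels:
        comps.setdefault(find(g), []).append(g)
    species_groups = sorted(comps.values())
    conflicts = [
        (r.clade_a, r.clade_b) for r in results
        if r.verdict == "different_species" and find(r.clade_a) == find(r.clade_b)
    ]
    return results, species_groups, conflicts


def fourx_report(results: list[FourXResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def diversity_report(divs: list[CladeDiversity]) -> pd.DataFrame:
    return pd.DataFrame([
        {"clade": d.group, "n": d.n, "L": d.L, "pi": d.pi,
         "d": d.mean_within_d, "theta": d.theta}
        for d in divs
    ])
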