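"""Pairwise genetic distances, group summaries, nucleotide diversity and
substitution-model fitting.

Distances are proportions of substituted sites ("substitutions per site").
Uncorrected p-distances use pairwise deletion of gap/``N`` sites by default,
matching how per-pair observed distances are usually reported.  Corrected
distances are available as JC69 and K2P closed forms and as per-pair
maximum-likelihood branch lengths under a fixed GTR model with discrete
gamma rate variation (GTR+G, optionally +I).

Model fitting uses a composite (independent-pairs) likelihood: the model
parameters here only feed distance correction, so a full tree likelihood is
deliberately avoided.  This is an approximation and is documented as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import gamma as _gamma_dist

from .alignment_io import Alignment, LineagePartition

__all__ = [
    "DistanceMatrix", "CladeDiversity", "SubstitutionModel",
    "p_distance_matrix", "group_mean_distances", "nucleotide_diversity",
    "corrected_distance", "fit_model", "LineagePartition",
]

# byte-level encoding: A,C,G,T -> 0..3; other IUPAC letters get literal
# codes >= 4 (valid for p-distance comparison, excluded from model-based
# computations); '-', 'N', '?' -> -1 (excluded everywhere)
_CODE = np.full(256, -2, dtype=np.int8)
for i, ch in enumerate("ACGT"):
    _CODE[ord(ch)] = i
for i, ch in enumerate("RYSWKMBDHV"):
    _CODE[ord(ch)] = 4 + i
for ch in "-N?":
    _CODE[ord(ch)] = -1


def encode_alignment(aln: Alignment) -> np.ndarray:
    """(n, L) int8 matrix; -1 marks excluded (gap/N) sites."""
    arr = np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n, aln.length)
    out = _CODE[arr]
    if (out == -2).any():
        bad = sorted({chr(c) for c in arr[out == -2]})
        raise ValueError(f"non-nucleotide characters in alignment: {bad}")
    return out


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in substitutions per site."""

    ids: list[str]
    values: np.ndarray
    kind: str = "p"  # p | JC69 | K2P | GTRG
    unit: str = "substitutions/site"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(v)
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T], atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if self.kind == "p" and np.nanmax(v, initial=0.0) > 1.0 + 1e-12:
            raise ValueError("p-distances must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def to_square_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.6f"
        )

    def to_phylip_lower(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{sid:<12s} {row}".rstrip() + "\n")


@dataclass
class CladeDiversity:
    """Within-clade diversity summary (per-group row of an S2-style table)."""

    group: str
    n: int
    L: int
    pi: float
    mean_within_d: float
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.pi < 0:
            raise ValueError("nucleotide diversity must be >= 0")


@dataclass
class SubstitutionModel:
    """Time-reversible nucleotide model (GTR) with gamma rate variation.

    ``exchangeabilities`` follow the order AC, AG, AT, CG, CT, GT; the rate
    matrix is normalised to mean rate 1 at the stationary frequencies, so
    branch lengths are expected substitutions per site.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float = np.inf
    p_invariant: float = 0.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        self.base_frequencies = np.asarray(self.base_frequencies, float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities < 0).any():
            raise ValueError("need 6 non-negative exchangeabilities")
        if abs(self.base_frequencies.sum() - 1.0) > 1e-6:
            raise ValueError("base frequencies must sum to 1")
        if not (0 <= self.p_invariant < 1):
            raise ValueError("p_invariant must be in [0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Normalised GTR generator Q (rows sum to zero, mean rate 1)."""
        R = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.exchangeabilities, pairs):
            R[i, j] = R[j, i] = r
        Q = R * self.base_frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(np.diag(Q) * self.base_frequencies).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def eigensystem(self):
        """Symmetric-form eigendecomposition for fast P(t)."""
        pi = self.base_frequencies
        Q = self.rate_matrix()
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        S = (S + S.T) / 2.0
        lam, U = np.linalg.eigh(S)
        # P(t) = diag(1/d) U exp(lam t) U' diag(d)
        A = U / d[:, None]
        B = U.T * d[None, :]
        return lam, A, B

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (quantile midpoints, mean 1),
        rescaled for the invariant-sites proportion so the overall mean
        rate stays 1."""
        k = self.n_categories
        if np.isinf(self.gamma_shape):
            rates = np.ones(k)
        else:
            qs = (np.arange(k) + 0.5) / k
            rates = _gamma_dist.ppf(qs, self.gamma_shape,
                                    scale=1.0 / self.gamma_shape)
            rates = rates / rates.mean()
        return rates / (1.0 - self.p_invariant)

    def transition_matrices(self, t: float) -> np.ndarray:
        """(k, 4, 4) stack of P(t * r_c) over gamma categories."""
        lam, A, B = self.eigensystem()
        rates = self.category_rates()
        expl = np.exp(lam[None, :] * t * rates[:, None])  # (k, 4)
        return np.einsum("il,kl,lj->kij", A, expl, B)


JC69 = SubstitutionModel()  # equal rates, uniform frequencies, no gamma


# ---------------------------------------------------------------------------
# p-distances and summaries
# ---------------------------------------------------------------------------

def p_distance_matrix(
    aln: Alignment, pairwise_deletion: bool = True
) -> DistanceMatrix:
    """Uncorrected proportion of differing sites for every pair.

    Sites with a gap or ``N`` in either sequence of a pair are excluded
    (pairwise deletion, the default) or globally (complete deletion).
    A pair with zero comparable sites is a hard error naming the pair.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    arr = encode_alignment(aln)
    valid = arr >= 0
    if not pairwise_deletion:
        cols = valid.all(axis=0)
        arr = arr[:, cols]
        valid = valid[:, cols]
    n = aln.n
    D = np.zeros((n, n))
    for i in range(n):
        vi = valid[i]
        both = vi & valid[i + 1:]
        comp = both.sum(axis=1)
        diff = ((arr[i] != arr[i + 1:]) & both).sum(axis=1)
        if (comp == 0).any():
            j = i + 1 + int(np.argmax(comp == 0))
            raise ValueError(
                f"no comparable sites for pair "
                f"({aln.sample_ids[i]}, {aln.sample_ids[j]})"
            )
        D[i, i + 1:] = diff / comp
        D[i + 1:, i] = D[i, i + 1:]
    return DistanceMatrix(list(aln.sample_ids), D, kind="p")


def difference_count_matrix(
    aln: Alignment, pairwise_deletion: bool = True
) -> DistanceMatrix:
    """Raw pairwise difference counts (the AMOVA input for haplotypic data)."""
    arr = encode_alignment(aln)
    valid = arr >= 0
    if not pairwise_deletion:
        cols = valid.all(axis=0)
        arr, valid = arr[:, cols], valid[:, cols]
    n = aln.n
    D = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = ((arr[i] != arr[i + 1:]) & both).sum(axis=1)
        D[i, i + 1:] = diff
        D[i + 1:, i] = diff
    return DistanceMatrix(list(aln.sample_ids), D, kind="count",
                          unit="differences")


def group_mean_distances(
    D: DistanceMatrix, part: LineagePartition
) -> pd.DataFrame:
    """Within- and between-group mean pairwise distances.

    Returns one row per unordered group pair (including within-group rows
    with ``group_i == group_j``) with the mean and population standard
    deviation over the relevant pair set.  Singleton groups get a within
    mean of 0 flagged ``degenerate``.
    """
    pos = {s: i for i, s in enumerate(D.ids)}
    missing = set(D.ids) - set(part.group_of)
    if missing:
        raise ValueError(f"partition does not cover: {sorted(missing)}")
    groups = {g: [pos[s] for s in mem if s in pos]
              for g, mem in part.groups().items()}
    labels = sorted(groups)
    rows = []
    for a_i, ga in enumerate(labels):
        for gb in labels[a_i:]:
            ia, ib = groups[ga], groups[gb]
            if ga == gb:
                if len(ia) < 2:
                    rows.append({"group_i": ga, "group_j": gb, "mean": 0.0,
                                 "sd": 0.0, "n_pairs": 0, "degenerate": True})
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                vals = D.values[np.ix_(ia, ia)][iu, ju]
            else:
                vals = D.values[np.ix_(ia, ib)].ravel()
            rows.append({
                "group_i": ga, "group_j": gb,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals)),  # population sd over pair values
                "n_pairs": int(vals.size),
                "degenerate": False,
            })
    return pd.DataFrame(rows)


def nucleotide_diversity(
    aln: Alignment, members: Sequence[str], group: str = ""
) -> CladeDiversity:
    """Within-group nucleotide diversity pi and mean pairwise difference d.

    pi is the mean pairwise p-distance over all member pairs; d is the mean
    raw difference count.  Both are 0 for a single member.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    sub = aln.subset(members)
    if sub.n == 1:
        pi, d = 0.0, 0.0
    else:
        P = p_distance_matrix(sub)
        C = difference_count_matrix(sub)
        iu, ju = np.triu_indices(sub.n, k=1)
        pi = float(P.values[iu, ju].mean())
        d = float(C.values[iu, ju].mean())
    from .fourx import theta_estimator  # deferred: fourx imports distances
    theta = theta_estimator(pi) if pi < 0.75 else None
    return CladeDiversity(group=group or "all", n=sub.n, L=aln.length,
                          pi=pi, mean_within_d=d, theta=theta)


# ---------------------------------------------------------------------------
# corrected distances
# ---------------------------------------------------------------------------

def _jc69(p: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    bad = p >= 0.75
    if bad.any():
        warnings.warn("p >= 0.75: JC69 distance undefined, reported as NaN")
        d = np.where(bad, np.nan, d)
    return d


def _k2p_counts(aln: Alignment):
    arr = encode_alignment(aln)
    valid = (arr >= 0) & (arr < 4)
    n = aln.n
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    purine = (arr == 0) | (arr == 2)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        comp = both.sum(axis=1)
        diff = (arr[i] != arr[i + 1:]) & both
        ts = diff & (purine[i] == purine[i + 1:])  # A<->G or C<->T
        comp = np.where(comp == 0, 1, comp)
        P[i, i + 1:] = ts.sum(axis=1) / comp
        Q[i, i + 1:] = (diff & ~ts).sum(axis=1) / comp
    P = P + P.T
    Q = Q + Q.T
    return P, Q


def _pair_counts(arr_i: np.ndarray, arr_j: np.ndarray) -> np.ndarray:
    """4x4 site-pattern counts over sites where both states are ACGT."""
    ok = (arr_i >= 0) & (arr_i < 4) & (arr_j >= 0) & (arr_j < 4)
    return np.bincount(
        (arr_i[ok] * 4 + arr_j[ok]).astype(np.int64), minlength=16
    ).reshape(4, 4).astype(float)


def _gtrg_pair_distance(N: np.ndarray, model: SubstitutionModel,
                        eig, rates, weights) -> float:
    """ML branch length for one pair under fixed GTR+G(+I) by bounded 1-D
    optimisation of the pair likelihood."""
    if N.sum() == 0:
        raise ValueError("no comparable ACGT sites for a pair")
    if (N - np.diag(np.diag(N))).sum() == 0:
        return 0.0
    lam, A, B = eig
    pi = model.base_frequencies
    pinv = model.p_invariant
    ident = np.eye(4)

    def nll(t):
        expl = np.exp(lam[None, :] * t * rates[:, None])
        P = np.einsum("il,kl,lj->kij", A, expl, B)
        P = np.clip(P, 1e-300, None)
        like = np.einsum("k,kij->ij", weights, P) * pi[:, None]
        if pinv > 0:
            like = (1 - pinv) * like + pinv * pi[:, None] * ident
        return -(N * np.log(np.clip(like, 1e-300, None))).sum()

    res = minimize_scalar(nll, bounds=(1e-8, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def corrected_distance(
    source: Alignment | DistanceMatrix,
    kind: str = "JC69",
    model: SubstitutionModel | None = None,
) -> DistanceMatrix:
    """Multiple-hit-corrected distances.

    ``JC69`` accepts an alignment or a p-distance matrix; ``K2P`` and
    ``GTRG`` require the alignment.  ``GTRG`` computes, for every pair, the
    maximum-likelihood branch length under the fixed `model` with discrete
    gamma categories (identical sequences share one computation, so large
    clonal alignments stay cheap).
    """
    if kind == "JC69":
        if isinstance(source, DistanceMatrix):
            if source.kind != "p":
                raise ValueError("JC69 correction needs p-distances")
            pmat, ids = source.values, source.ids
        else:
            pm = p_distance_matrix(source)
            pmat, ids = pm.values, pm.ids
        return DistanceMatrix(list(ids), _jc69(pmat), kind="JC69")

    if not isinstance(source, Alignment):
        raise ValueError(f"{kind} correction requires an alignment")

    if kind == "K2P":
        P, Q = _k2p_counts(source)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = -0.5 * np.log((1 - 2 * P - Q) * np.sqrt(1 - 2 * Q))
        bad = ~np.isfinite(d)
        np.fill_diagonal(bad, False)
        if bad.any():
            warnings.warn("K2P distance undefined for saturated pairs (NaN)")
            d = np.where(bad, np.nan, d)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(source.sample_ids), d, kind="K2P")

    if kind != "GTRG":
        raise ValueError(f"unknown correction kind '{kind}'")
    if model is None:
        raise ValueError("GTRG correction requires a SubstitutionModel")

    arr = encode_alignment(source)
    n = source.n
    # collapse identical rows: clonal data has few unique sequences
    uniq: dict[bytes, int] = {}
    rep_of = np.zeros(n, dtype=int)
    reps: list[int] = []
    for i in range(n):
        key = arr[i].tobytes()
        if key not in uniq:
            uniq[key] = len(reps)
            reps.append(i)
        rep_of[i] = uniq[key]
    m = len(reps)
    eig = model.eigensystem()
    rates = model.category_rates()
    weights = np.full(len(rates), 1.0 / len(rates))
    sub = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            N = _pair_counts(arr[reps[a]], arr[reps[b]])
            sub[a, b] = sub[b, a] = _gtrg_pair_distance(
                N, model, eig, rates, weights)
    D = sub[np.ix_(rep_of, rep_of)]
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(source.sample_ids), D, kind="GTRG")


# ---------------------------------------------------------------------------
# model fitting (composite pairwise likelihood)
# ---------------------------------------------------------------------------

def _fitch_site_counts(tree, arr: np.ndarray, tip_index: dict[int, int]) -> np.ndarray:
    """Per-site Fitch parsimony substitution counts on a guide tree.

    States are 4-bit sets per site; missing/ambiguous tips are wildcards.
    """
    L = arr.shape[1]
    n = tree.n_tips
    masks = np.empty((2 * n - 1, L), dtype=np.int8)
    counts = np.zeros(L, dtype=np.int64)
    for tip in range(n):
        row = arr[tip_index[tip]]
        m = np.where((row >= 0) & (row < 4), np.left_shift(1, np.clip(row, 0, 3)), 15)
        masks[tip] = m.astype(np.int8)
    for v in range(2 * n - 2, n - 1, -1):      # internal nodes, children first
        a, b = tree.children[v]
        inter = masks[a] & masks[b]
        empty = inter == 0
        counts += empty
        masks[v] = np.where(empty, masks[a] | masks[b], inter)
    return counts


def estimate_gamma_shape(aln: Alignment) -> float:
    """Gamma shape from the overdispersion of per-site parsimony counts.

    Site substitution counts on a JC/UPGMA guide tree are treated as a
    Poisson mixture over site rates; the negative-binomial moment estimator
    ``alpha = mean^2 / (var - mean)`` recovers the shape of the mixing
    distribution.  Under- or equi-dispersed counts give ``inf`` (rate
    homogeneity).  Parsimony undercounts at fast sites, so the estimate is
    mildly conservative (biased toward homogeneity).
    """
    from .clock import upgma_chronogram  # local import: clock uses distances

    arr = encode_alignment(aln)
    uniq: dict[bytes, int] = {}
    for i in range(aln.n):
        uniq.setdefault(arr[i].tobytes(), i)
    rep_rows = sorted(uniq.values())
    if len(rep_rows) < 3:
        return np.inf
    sub = aln.subset([aln.sample_ids[i] for i in rep_rows])
    guide = upgma_chronogram(p_distance_matrix(sub))  # topology-only guide
    tip_index = {t: rep_rows[sub.sample_ids.index(guide.labels[t])]
                 for t in range(guide.n_tips)}
    counts = _fitch_site_counts(guide, arr, tip_index)
    mean = counts.mean()
    var = counts.var()
    if var <= mean or mean == 0:
        return np.inf
    return float(np.clip(mean * mean / (var - mean), 0.05, 100.0))


def _composite_nll(params, Ns, pi, alpha, n_cat):
    """Negative composite log likelihood over independent pairs.

    params = [log ex_AC, ..., log ex_CT (5, GT fixed at 1),
    log t_1 ... log t_m]; the gamma shape is held fixed.
    """
    ex = np.exp(np.append(params[:5], 0.0))
    ts = np.exp(params[5:])
    model = SubstitutionModel(ex, pi, gamma_shape=alpha, n_categories=n_cat)
    lam, A, B = model.eigensystem()
    rates = model.category_rates()
    w = 1.0 / len(rates)
    total = 0.0
    for N, t in zip(Ns, ts):
        expl = np.exp(lam[None, :] * t * rates[:, None])
        P = np.einsum("il,kl,lj->kij", A, expl, B)
        like = w * P.sum(axis=0) * pi[:, None]
        total -= (N * np.log(np.clip(like, 1e-300, None))).sum()
    return total


def fit_model(
    aln: Alignment,
    n_categories: int = 4,
    max_pairs: int = 100,
) -> SubstitutionModel:
    """Estimate a GTR+G model for distance correction.

    Base frequencies are empirical counts.  Exchangeabilities (GT fixed at
    1) are maximised by composite (independent-pairs) likelihood jointly
    with per-pair branch lengths over a deterministic subset of
    unique-sequence pairs; the gamma shape comes from
    :func:`estimate_gamma_shape` because it is only weakly identified by
    pairwise patterns.  The composite likelihood approximates the full
    tree likelihood; it is adequate here because the model only feeds
    pairwise distance correction.  Deterministic given fixed optimiser
    settings.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    arr = encode_alignment(aln)
    acgt = arr[(arr >= 0) & (arr < 4)]
    counts = np.bincount(acgt, minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous bases")
    pi = counts / counts.sum()
    pi = np.clip(pi, 1e-6, None)
    pi = pi / pi.sum()

    # unique sequences, deterministic pair subset spread over the list
    uniq: dict[bytes, int] = {}
    reps: list[int] = []
    for i in range(aln.n):
        key = arr[i].tobytes()
        if key not in uniq:
            uniq[key] = i
            reps.append(i)
    pairs = [(reps[a], reps[b]) for a in range(len(reps))
             for b in range(a + 1, len(reps))]
    if len(pairs) > max_pairs:
        step = len(pairs) / max_pairs
        pairs = [pairs[int(k * step)] for k in range(max_pairs)]
    Ns, p_obs = [], []
    for i, j in pairs:
        N = _pair_counts(arr[i], arr[j])
        Ns.append(N)
        tot = N.sum()
        p_obs.append((tot - np.trace(N)) / tot if tot else 0.0)
    p_obs = np.asarray(p_obs)
    if (p_obs == 0).all():
        warnings.warn("no variable sites: returning equal exchangeabilities")
        return SubstitutionModel(np.ones(6), pi, gamma_shape=np.inf,
                                 n_categories=n_categories)

    alpha = estimate_gamma_shape(aln) if len(reps) >= 3 else np.inf

    # JC-style starting branch lengths; saturated pairs start at 1
    with np.errstate(invalid="ignore", divide="ignore"):
        t0 = -0.75 * np.log(1 - 4 * np.minimum(p_obs, 0.70) / 3)
    t0 = np.clip(t0, 1e-4, 10.0)
    x0 = np.concatenate([np.zeros(5), np.log(t0)])
    bounds = [(-6.0, 6.0)] * 5 + [(np.log(1e-6), np.log(20.0))] * len(Ns)
    res = minimize(
        _composite_nll, x0, args=(Ns, pi, alpha, n_categories),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-10},
    )
    ex = np.exp(np.append(res.x[:5], 0.0))
    return SubstitutionModel(ex, pi, gamma_shape=alpha,
                             n_categories=n_categories)
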