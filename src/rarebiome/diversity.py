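"""Taxonomic and phylogenetic alpha/beta diversity.

Shannon entropy, patristic (cophenetic) distances, mean nearest-taxon
distance (MNTD) and its standardized effect size against a tip-label-shuffle
null, between-community MNTD (betaMNTD), and Bray-Curtis dissimilarity.

The null model used throughout shuffles taxon labels across the *whole*
distance matrix: a community of r taxa is compared against communities of r
labels drawn uniformly without replacement from all tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import Phylogeny


@dataclass
class CopheneticMatrix:
    """Symmetric patristic distance matrix with tip labels."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.index = {name: i for i, name in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.data[self.index[a], self.index[b]])

    def positions(self, labels) -> np.ndarray:
        return np.array([self.index[l] for l in labels], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class SESResult:
    mntd_obs: float
    ses: float
    null_mean: float
    null_sd: float
    p: float
    n_nulls: int
    seed: int | None
    defined: bool = True


def cophenetic_matrix(tree: Phylogeny) -> CopheneticMatrix:
    """Patristic distances between every pair of tips (path sums of branch
    lengths)."""
    for node in tree.tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length above {node.name!r}")
    dm = tree.tree.tip_tip_distances()
    return CopheneticMatrix(list(dm.ids), np.asarray(dm.data, dtype=float))


def shannon_index(abund) -> float:
    """Shannon entropy H = -sum p ln p in nats, on renormalized nonzero
    abundances."""
    a = np.asarray(abund, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity on a pair of abundance vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(counts: np.ndarray) -> np.ndarray:
    """All-pairs Bray-Curtis for a samples x OTUs matrix."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(counts, dtype=float), metric="braycurtis"))


# ---------------------------------------------------------------------------
# MNTD family
# ---------------------------------------------------------------------------

def _nearest_taxon_distances(d: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """For each taxon position in idx, distance to its nearest *other* taxon
    in idx."""
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return sub.min(axis=1)


def mntd_observed(abund, dmat: CopheneticMatrix, weighted: bool = True) -> float:
    """Mean nearest-taxon distance of one community.

    ``abund`` is a mapping/Series of taxon label -> abundance; absent and
    zero-abundance taxa are ignored.  Weighted mode averages nearest-taxon
    distances with relative-abundance weights.
    """
    s = pd.Series(abund, dtype=float)
    s = s[s > 0]
    if len(s) < 2:
        raise ValueError("MNTD undefined for < 2 present taxa")
    idx = dmat.positions(s.index)
    nd = _nearest_taxon_distances(dmat.data, idx)
    if weighted:
        w = s.to_numpy() / s.sum()
        return float(nd @ w)
    return float(nd.mean())


def ses_mntd(abund, dmat: CopheneticMatrix, n_nulls: int = 999,
             weighted: bool = True, seed: int | None = None) -> SESResult:
    """Standardized effect size of MNTD under the taxa-label-shuffle null.

    SES = (MNTD_obs - mean_null) / sd_null with sample sd; negative values
    indicate phylogenetic clustering.  When the null sd is zero (e.g. the
    community spans all tips, making the statistic shuffle-invariant) the
    result is flagged undefined.
    """
    s = pd.Series(abund, dtype=float)
    s = s[s > 0]
    if len(s) < 2:
        raise ValueError("SES.MNTD undefined for < 2 present taxa")
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    r = len(s)
    w = s.to_numpy() / s.sum()
    obs = mntd_observed(s, dmat, weighted=weighted)
    rng = np.random.default_rng(seed)
    d = dmat.data
    nulls = np.empty(n_nulls)
    for k in range(n_nulls):
        idx = rng.choice(dmat.n, size=r, replace=False)
        nd = _nearest_taxon_distances(d, idx)
        nulls[k] = nd @ w if weighted else nd.mean()
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if n_nulls > 1 else 0.0
    if sd == 0:
        return SESResult(obs, np.nan, mu, sd, np.nan, n_nulls, seed, False)
    ses = (obs - mu) / sd
    rank_p = (np.sum(nulls <= obs) + 1) / (n_nulls + 1)
    p = float(2 * min(rank_p, 1 - rank_p + 1 / (n_nulls + 1)))
    return SESResult(obs, float(ses), mu, sd, min(p, 1.0), n_nulls, seed)


def beta_mntd(abund_k, abund_l, dmat: CopheneticMatrix,
              weighted: bool = True) -> float:
    """Between-community mean nearest-taxon distance.

    betaMNTD = 0.5 * [ sum_i p_ik min_{j in l} d(i,j)
                     + sum_j p_jl min_{i in k} d(j,i) ];
    a taxon present in both communities contributes zero on both sides.
    """
    sk = pd.Series(abund_k, dtype=float)
    sl = pd.Series(abund_l, dtype=float)
    sk, sl = sk[sk > 0], sl[sl > 0]
    if len(sk) == 0 or len(sl) == 0:
        raise ValueError("betaMNTD undefined for an empty sample")
    ik = dmat.positions(sk.index)
    il = dmat.positions(sl.index)
    d = dmat.data
    min_k_to_l = d[np.ix_(ik, il)].min(axis=1)
    min_l_to_k = d[np.ix_(il, ik)].min(axis=1)
    if weighted:
        pk = sk.to_numpy() / sk.sum()
        pl = sl.to_numpy() / sl.sum()
        return float(0.5 * (pk @ min_k_to_l + pl @ min_l_to_k))
    return float(0.5 * (min_k_to_l.mean() + min_l_to_k.mean()))


def beta_mntd_matrix(rel_abund: np.ndarray, d: np.ndarray,
                     tip_positions: np.ndarray | None = None) -> np.ndarray:
    """All-pairs weighted betaMNTD for a samples x OTUs relative-abundance
    matrix whose columns map (via ``tip_positions``) onto rows/cols of the
    full patristic matrix ``d``.

    Used by the null-model loop: permuting ``tip_positions`` re-labels taxa
    across the whole tree in one shot.
    """
    P = np.asarray(rel_abund, dtype=float)
    n_samples, n_otus = P.shape
    if tip_positions is None:
        tip_positions = np.arange(n_otus, dtype=np.intp)
    present = [np.flatnonzero(P[s] > 0) for s in range(n_samples)]
    # M[s, i] = min over taxa j present in sample s of d(tip(j), tip(i))
    M = np.empty((n_samples, n_otus))
    for s in range(n_samples):
        rows = d[tip_positions[present[s]]]          # r_s x n_tips
        M[s] = rows.min(axis=0)[tip_positions]
    B = P @ M.T                                      # B[k, l] = sum_i p_ik m_l(i)
    return 0.5 * (B + B.T)
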