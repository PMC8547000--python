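"""Ecosystem multifunctionality (EMF), functional redundancy and their
linkage.

EMF is the per-sample mean of Z-scored function measurements.  The
functional redundancy index (FRI) of a sample for one function combines the
abundance of taxa capable of the function with their mean phylogenetic
distance to the other capable taxa — a documented surrogate for
reference-database redundancy scores, preserving how redundancy is *used*
(dissimilarity vs. EMF) rather than any specific database.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats_core
from .diversity import CopheneticMatrix
from .io_config import CommunityMatrix, ValidationError


def zscore_multifunctionality(functions: pd.DataFrame) -> pd.Series:
    """Per-sample EMF: mean of per-function Z-scores (sample sd)."""
    if functions.shape[0] < 2:
        raise ValueError("EMF requires >= 2 samples")
    sd = functions.std(ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        raise ValidationError(f"constant function column(s): {list(constant)}")
    z = (functions - functions.mean()) / sd
    emf = z.mean(axis=1)
    emf.name = "EMF"
    return emf


def functional_redundancy_index(cm: CommunityMatrix, dmat: CopheneticMatrix,
                                incidence: pd.DataFrame) -> pd.DataFrame:
    """FRI table: samples x functions.

    For sample s and function f with capable present taxa C:
    FRI(s, f) = sum_{i in C} p_is * mean distance from i to C \\ {i},
    with within-sample relative abundances p.  A single capable taxon (or
    none) scores 0.
    """
    missing = set(cm.otu_ids) - set(incidence.index)
    if missing:
        raise ValidationError(
            f"OTUs missing from function incidence: {sorted(missing)[:10]}")
    inc = incidence.reindex(cm.otu_ids).astype(bool)
    rel = cm.rel_abund
    pos = dmat.positions(cm.otu_ids)
    d = dmat.data[np.ix_(pos, pos)]
    out = pd.DataFrame(0.0, index=cm.sample_ids, columns=inc.columns)
    P = rel.to_numpy()
    present = P > 0
    for f in inc.columns:
        capable = inc[f].to_numpy()
        for si, sid in enumerate(cm.sample_ids):
            members = np.flatnonzero(capable & present[si])
            if len(members) < 2:
                continue
            sub = d[np.ix_(members, members)]
            mean_to_others = sub.sum(axis=1) / (len(members) - 1)
            out.loc[sid, f] = float(P[si, members] @ mean_to_others)
    return out


def unique_functions(incidence_a: pd.DataFrame, incidence_b: pd.DataFrame) -> dict:
    """Census of functions exclusive to each subcommunity and shared.

    A function belongs to a subcommunity when at least one member OTU
    carries it.
    """
    fa = set(incidence_a.columns[incidence_a.astype(bool).any(axis=0)])
    fb = set(incidence_b.columns[incidence_b.astype(bool).any(axis=0)])
    return {
        "a_only": len(fa - fb),
        "b_only": len(fb - fa),
        "shared": len(fa & fb),
    }


def function_log_ratio(fri_a: pd.DataFrame, fri_b: pd.DataFrame,
                       epsilon: float | None = None) -> pd.Series:
    """Per-function log2 ratio of mean FRI between two subcommunities.

    Positive values mean the function is more redundant in A.  ``epsilon``
    defaults to half the smallest positive FRI observed.
    """
    mean_a = fri_a.mean(axis=0)
    mean_b = fri_b.reindex(columns=mean_a.index).mean(axis=0)
    if epsilon is None:
        pooled = np.concatenate([fri_a.to_numpy().ravel(),
                                 fri_b.to_numpy().ravel()])
        positive = pooled[pooled > 0]
        epsilon = 0.5 * positive.min() if len(positive) else 1e-9
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    ratio = np.log2((mean_a + epsilon) / (mean_b + epsilon))
    ratio.name = "log2_fri_ratio"
    return ratio


def _pair_distance_vectors(fri: pd.DataFrame, emf: pd.Series,
                           metric: str = "euclidean"):
    from scipy.spatial.distance import pdist, squareform

    X = fri.to_numpy(dtype=float)
    if metric == "braycurtis" and (X < 0).any():
        raise ValueError("Bray-Curtis needs non-negative FRI values")
    dx = squareform(pdist(X, metric=metric))
    e = emf.reindex(fri.index).to_numpy(dtype=float)
    dy = np.abs(e[:, None] - e[None, :])
    return dx, dy


def fri_emf_regression(fri: pd.DataFrame, emf: pd.Series,
                       metric: str = "euclidean", n_perm: int = 999,
                       seed: int | None = None) -> dict:
    """Regression of EMF dissimilarity on FRI dissimilarity over sample
    pairs.

    Pairs are not independent, so alongside the naive OLS p a Mantel-style
    permutation p (permuting samples, not pairs) is reported.
    """
    if fri.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    dx, dy = _pair_distance_vectors(fri, emf, metric)
    iu = np.triu_indices(dx.shape[0], k=1)
    x, y = dx[iu], dy[iu]
    if np.ptp(x) == 0:
        return {"slope": np.nan, "intercept": np.nan, "R2": np.nan,
                "p_ols": np.nan, "p_perm": np.nan, "defined": False}
    reg = stats_core.ols_regression(x, y)
    mantel = stats_core.mantel_test(dx, dy, n_perm=n_perm, seed=seed)
    return {"slope": reg["slope"], "intercept": reg["intercept"],
            "R2": reg["R2"], "p_ols": reg["p"], "p_perm": mantel.p,
            "n_pairs": len(x), "defined": True}


def diversity_emf_regression(diversity, emf) -> dict:
    """OLS of EMF on an alpha-diversity metric across samples."""
    x = np.asarray(diversity, dtype=float)
    y = np.asarray(emf, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(x) == 0:
        return {"slope": np.nan, "intercept": np.nan, "R2": np.nan,
                "p": np.nan, "n": len(x), "defined": False}
    return {**stats_core.ols_regression(x, y), "defined": True}


def environment_function_permanova(fri: pd.DataFrame, env: pd.DataFrame,
                                   n_perm: int = 999,
                                   seed: int | None = None) -> pd.DataFrame:
    """Single-variable PERMANOVA of each environmental variable on the
    Bray-Curtis distances of per-sample FRI profiles."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(fri.to_numpy(dtype=float), metric="braycurtis"))
    rows = []
    for i, var in enumerate(env.columns):
        cov = env[var].reindex(fri.index).to_numpy(dtype=float)
        res = stats_core.permanova(
            d, cov, n_perm=n_perm,
            seed=None if seed is None else seed + i)
        rows.append({"variable": var, **{k: res[k] for k in
                                         ("pseudo_F", "R2", "p")}})
    return pd.DataFrame(rows)
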