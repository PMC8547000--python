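"""Phylogenetic signal of environmental preferences.

Per-OTU preference traits are Spearman correlations between relative
abundance and an environmental variable; their phylogenetic signal is
quantified with Blomberg's K (continuous) and Fritz-Purvis D (binary,
reported alongside the 1 - D transform so larger = more conserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import CommunityMatrix, EnvTable, Phylogeny

__all__ = [
    "ecological_preference", "blomberg_k", "fritz_purvis_d", "transform_d",
    "signal_profile", "phylogenetic_covariance", "pic_contrast_weights",
]


# ---------------------------------------------------------------------------
# tree machinery
# ---------------------------------------------------------------------------

@dataclass
class _TreeArrays:
    """Flat postorder view of a tree: children lists, branch lengths, tips."""

    tip_names: list[str]
    children: list[list[int]]       # per node (postorder index), child node ids
    lengths: np.ndarray             # branch length above each node (root: 0)
    postorder: list[int]            # node ids, tips first encountered postorder
    n_tips: int


def _tree_arrays(tree: Phylogeny) -> _TreeArrays:
    nodes = list(tree.tree.postorder(include_self=True))
    index = {id(n): i for i, n in enumerate(nodes)}

    # canonical child order: by smallest descendant tip label
    def min_tip(n):
        return min(t.name for t in n.tips()) if n.children else n.name

    tip_names, children, lengths = [], [], []
    for n in nodes:
        kids = sorted(n.children, key=min_tip)
        children.append([index[id(c)] for c in kids])
        lengths.append(n.length if n.length is not None else 0.0)
        if not n.children:
            tip_names.append(n.name)
    return _TreeArrays(
        tip_names=tip_names,
        children=children,
        lengths=np.asarray(lengths, dtype=float),
        postorder=list(range(len(nodes))),
        n_tips=len(tip_names),
    )


def phylogenetic_covariance(tree: Phylogeny, tip_order=None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix: C[i, j] = shared root-to-MRCA path
    length of tips i and j."""
    ta = _tree_arrays(tree)
    n_nodes = len(ta.children)
    depth = np.zeros(n_nodes)
    # root is last in postorder; compute depths via a preorder pass
    for nid in reversed(range(n_nodes)):
        for c in ta.children[nid]:
            depth[c] = depth[nid] + ta.lengths[c]
    tip_pos = {}
    k = 0
    tipsets: list[list[int]] = [[] for _ in range(n_nodes)]
    for nid in range(n_nodes):
        if not ta.children[nid]:
            tip_pos[nid] = k
            tipsets[nid] = [k]
            k += 1
    C = np.zeros((ta.n_tips, ta.n_tips))
    for nid in range(n_nodes):
        kids = ta.children[nid]
        if not kids:
            C[tipsets[nid][0], tipsets[nid][0]] = depth[nid]
            continue
        acc: list[int] = []
        for c in kids:
            cs = tipsets[c]
            if acc:
                C[np.ix_(acc, cs)] = depth[nid]
                C[np.ix_(cs, acc)] = depth[nid]
            acc.extend(cs)
        tipsets[nid] = acc
    names = ta.tip_names
    if tip_order is not None:
        order = [names.index(t) for t in tip_order]
        C = C[np.ix_(order, order)]
        names = list(tip_order)
    return C, names


def pic_contrast_weights(tree: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """Weight matrix W such that W @ x(tips) gives Felsenstein's
    phylogenetically independent contrasts.

    Nodal values in the pruning recursion are linear in tip values, so the
    whole contrast set is one matrix product; polytomies are folded by
    successive pairwise merging in canonical child order.
    """
    ta = _tree_arrays(tree)
    n_nodes = len(ta.children)
    n = ta.n_tips
    value_w = np.zeros((n_nodes, n))
    eff_len = ta.lengths.copy()
    contrasts = []
    k = 0
    for nid in range(n_nodes):
        if not ta.children[nid]:
            value_w[nid, k] = 1.0
            k += 1
    for nid in range(n_nodes):
        kids = ta.children[nid]
        if not kids:
            continue
        w1 = value_w[kids[0]]
        b1 = eff_len[kids[0]]
        for c in kids[1:]:
            w2, b2 = value_w[c], eff_len[c]
            denom = b1 + b2
            if denom <= 0:
                denom = 1e-12
            contrasts.append((w1 - w2) / np.sqrt(denom))
            w1 = (b2 * w1 + b1 * w2) / denom
            b1 = b1 * b2 / denom
        value_w[nid] = w1
        eff_len[nid] = ta.lengths[nid] + b1
    return np.asarray(contrasts), ta.tip_names


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def blomberg_k(tree: Phylogeny, trait, n_perm: int = 999,
               seed: int | None = None) -> dict:
    """Blomberg's K with a permutation test on the variance of independent
    contrasts.

    K compares the observed ratio of trait variance to its
    phylogenetically-expected counterpart; K = 1 is the Brownian-motion
    expectation, K near 0 a convergent/random pattern.  The p-value shuffles
    trait values across tips and asks how often the contrast variance is as
    small as observed (small variance = signal).  Pass ``n_perm=0`` to skip
    the test.
    """
    trait = pd.Series(trait, dtype=float).dropna()
    if len(trait) < 4:
        raise ValueError("Blomberg's K requires a trait on >= 4 tips")
    if np.ptp(trait.to_numpy()) == 0:
        raise ValueError("constant trait")
    sub = tree.prune_to(trait.index)
    C, names = phylogenetic_covariance(sub, tip_order=list(trait.index))
    x = trait.to_numpy()
    n = len(x)
    try:
        Cinv_x = np.linalg.solve(C, x)
        Cinv_1 = np.linalg.solve(C, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance (zero-length cherries?)") from exc
    a_hat = (Cinv_1 @ x) / Cinv_1.sum()
    dev = x - a_hat
    msd0 = float(dev @ dev)
    msd = float(dev @ np.linalg.solve(C, dev))
    expected = (np.trace(C) - n / Cinv_1.sum()) / (n - 1)
    k = (msd0 / msd) / expected
    result = {"K": float(k), "n": n, "n_permutations": n_perm, "seed": seed,
              "p": np.nan}
    if n_perm:
        W, tip_names = pic_contrast_weights(sub)
        xs = trait.reindex(tip_names).to_numpy()
        obs_var = np.var(W @ xs, ddof=1)
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(xs) for _ in range(n_perm)], axis=1)
        pv = np.var(W @ perms, axis=0, ddof=1)
        result["p"] = float((np.sum(pv <= obs_var + 1e-12) + 1) / (n_perm + 1))
    return result


# ---------------------------------------------------------------------------
# Fritz-Purvis D
# ---------------------------------------------------------------------------

def _sum_d(ta: _TreeArrays, values: np.ndarray) -> np.ndarray:
    """Sum over internal nodes of |sister differences| under successive
    averaging from tips to root; vectorized over trait columns."""
    n_nodes = len(ta.children)
    m = values.shape[1]
    nodal = np.zeros((n_nodes, m))
    k = 0
    for nid in range(n_nodes):
        if not ta.children[nid]:
            nodal[nid] = values[k]
            k += 1
    total = np.zeros(m)
    for nid in range(n_nodes):
        kids = ta.children[nid]
        if not kids:
            continue
        v = nodal[kids[0]]
        for c in kids[1:]:
            total += np.abs(v - nodal[c])
            v = 0.5 * (v + nodal[c])
        nodal[nid] = v
    return total


def _bm_tips(ta: _TreeArrays, n_cols: int, rng) -> np.ndarray:
    """Brownian tip values (unit rate): root-to-tip accumulation of
    Normal(0, branch length) increments; returns tips x n_cols."""
    n_nodes = len(ta.children)
    vals = np.zeros((n_nodes, n_cols))
    for nid in reversed(range(n_nodes)):
        for c in ta.children[nid]:
            bl = max(ta.lengths[c], 0.0)
            vals[c] = vals[nid] + rng.normal(0.0, np.sqrt(bl), size=n_cols)
    tips = [nid for nid in range(n_nodes) if not ta.children[nid]]
    return vals[tips]


def fritz_purvis_d(tree: Phylogeny, states, n_perm: int = 1000,
                   n_bm: int = 1000, seed: int | None = None) -> float:
    """Fritz-Purvis phylogenetic dispersion D of a binary trait.

    D = (Sd_obs - mean Sd_BM) / (mean Sd_rand - mean Sd_BM), where Sd sums
    |sister-clade differences| of nodal values obtained by averaging tip
    states rootward; Sd_rand uses uniform shuffles of the states and Sd_BM
    thresholds Brownian traits at the observed prevalence.  D = 1 for
    phylogenetically random traits, D = 0 for Brownian clumping, D < 0 for
    stronger-than-Brownian clumping.
    """
    states = pd.Series(states).dropna().astype(float)
    uniq = set(states.unique())
    if not uniq <= {0.0, 1.0}:
        raise ValueError("states must be binary 0/1")
    if len(uniq) < 2:
        raise ValueError("both states must be present")
    if len(states) < 4:
        raise ValueError("Fritz-Purvis D requires >= 4 tips")
    sub = tree.prune_to(states.index)
    ta = _tree_arrays(sub)
    x = states.reindex(ta.tip_names).to_numpy()
    n_ones = int(x.sum())
    rng = np.random.default_rng(seed)
    sd_obs = _sum_d(ta, x[:, None])[0]
    shuffles = np.stack([rng.permutation(x) for _ in range(n_perm)], axis=1)
    sd_rand = _sum_d(ta, shuffles).mean()
    bm = _bm_tips(ta, n_bm, rng)
    # threshold each Brownian trait at the observed prevalence
    order = np.argsort(-bm, axis=0, kind="stable")
    thresholded = np.zeros_like(bm)
    np.put_along_axis(thresholded, order[:n_ones], 1.0, axis=0)
    sd_bm = _sum_d(ta, thresholded).mean()
    denom = sd_rand - sd_bm
    if abs(denom) < 1e-12:
        raise ValueError("degenerate D references (shuffle and BM coincide)")
    return float((sd_obs - sd_bm) / denom)


def transform_d(d: float) -> float:
    """The -D + 1 transform: 0 = no signal, positive = conserved."""
    return 1.0 - d


# ---------------------------------------------------------------------------
# preference traits and the per-variable profile
# ---------------------------------------------------------------------------

def ecological_preference(cm: CommunityMatrix, env_table: EnvTable,
                          variable: str, alpha: float = 0.05,
                          min_occupancy: int = 5,
                          bh_correct: bool = False) -> pd.DataFrame:
    """Spearman preference trait of every sufficiently-occupied OTU.

    Returns a frame indexed by otu_id with ``rho``, ``p`` and ``label``
    (positive_preferred / negative_preferred / none); the label is ``none``
    unless p < alpha (Benjamini-Hochberg adjusted first when
    ``bh_correct``).
    """
    if variable not in env_table.env.columns:
        raise ValueError(f"unknown environmental variable {variable!r}")
    env = env_table.env[variable].reindex(cm.sample_ids)
    rel = cm.rel_abund
    occ = (cm.counts > 0).sum(axis=0)
    rows = []
    for otu in cm.otu_ids:
        if occ[otu] < min_occupancy:
            continue
        a = rel[otu].to_numpy()
        if np.ptp(a) == 0:
            rows.append({"otu_id": otu, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(a, env.to_numpy())
        rows.append({"otu_id": otu, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows, columns=["otu_id", "rho", "p"]).set_index("otu_id")
    if len(out) == 0:
        out["label"] = pd.Series(dtype=object)
        return out
    p_eff = out["p"].copy()
    if bh_correct and out["p"].notna().any():
        mask = out["p"].notna()
        pv = out.loc[mask, "p"].to_numpy()
        m = len(pv)
        order = np.argsort(pv)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((pv[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        p_eff.loc[mask] = np.minimum(adj, 1.0)
    label = pd.Series("none", index=out.index, dtype=object)
    sig = p_eff < alpha
    label[sig & (out["rho"] > 0)] = "positive_preferred"
    label[sig & (out["rho"] < 0)] = "negative_preferred"
    out["label"] = label
    return out


def signal_profile(cm: CommunityMatrix, tree: Phylogeny, env_table: EnvTable,
                   alpha: float = 0.05, min_occupancy: int = 5,
                   n_permutations: int = 999, n_bm: int = 1000,
                   seed: int | None = None, variables=None,
                   taxon_subset=None) -> pd.DataFrame:
    """K and D (reported as 1 - D) for every environmental variable.

    ``taxon_subset`` optionally restricts the analysis to a set of OTU ids
    (e.g. one phylum) before trait construction.  Cells with too few
    trait-bearing OTUs are reported as NaN.
    """
    if variables is None:
        variables = list(env_table.env.columns)
    work = cm
    if taxon_subset is not None:
        keep = [o for o in cm.otu_ids if o in set(taxon_subset)]
        work = cm.subset_otus(keep) if keep else None
    tips = set(tree.tip_names)
    rows = []
    ss = np.random.SeedSequence(seed)
    for variable, child in zip(variables, ss.spawn(len(variables))):
        row = {"variable": variable, "n_taxa": 0, "K": np.nan, "K_p": np.nan,
               "n_binary": 0, "D": np.nan, "one_minus_D": np.nan, "seed": seed}
        if work is not None:
            prefs = ecological_preference(work, env_table, variable,
                                          alpha=alpha,
                                          min_occupancy=min_occupancy)
            cont = prefs["rho"].dropna()
            cont = cont[[o in tips for o in cont.index]]
            row["n_taxa"] = len(cont)
            sd1, sd2 = (int(c.generate_state(1)[0]) for c in child.spawn(2))
            if len(cont) >= 4 and np.ptp(cont.to_numpy()) > 0:
                try:
                    kres = blomberg_k(tree, cont, n_perm=n_permutations, seed=sd1)
                    row["K"], row["K_p"] = kres["K"], kres["p"]
                except ValueError:
                    pass
            binary = prefs.loc[prefs["label"] != "none", "label"]
            binary = binary[[o in tips for o in binary.index]]
            states = (binary == "positive_preferred").astype(float)
            row["n_binary"] = len(states)
            if len(states) >= 4 and 0 < states.sum() < len(states):
                try:
                    d = fritz_purvis_d(tree, states, n_perm=n_permutations,
                                       n_bm=n_bm, seed=sd2)
                    row["D"], row["one_minus_D"] = d, transform_d(d)
                except ValueError:
                    pass
        rows.append(row)
    return pd.DataFrame(rows)
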