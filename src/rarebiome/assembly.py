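"""Community assembly inference from null models.

betaNTI (standardized betaMNTD against a tip-label shuffle across the whole
tree) and Bray-Curtis-based Raup-Crick (RC_bray) jointly classify every
sample pair into one of five assembly processes:

    betaNTI >  +2                      -> variable_selection
    betaNTI <  -2                      -> homogeneous_selection
    |betaNTI| <= 2 and RC >  0.95      -> dispersal_limitation
    |betaNTI| <= 2 and RC < -0.95      -> homogenizing_dispersal
    |betaNTI| <= 2 and |RC| <= 0.95    -> undominated

Aggregates: deterministic = both selections; stochastic = the rest;
homogenizing = homogeneous selection + homogenizing dispersal;
differentiating = variable selection + dispersal limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_core
from .diversity import CopheneticMatrix, beta_mntd, beta_mntd_matrix, bray_curtis_matrix
from .io_config import CommunityMatrix, ValidationError

logger = logging.getLogger("rarebiome")

PROCESSES = (
    "variable_selection", "homogeneous_selection",
    "dispersal_limitation", "homogenizing_dispersal", "undominated",
)


@dataclass
class ProcessFractions:
    variable_selection: float
    homogeneous_selection: float
    dispersal_limitation: float
    homogenizing_dispersal: float
    undominated: float
    n_pairs: int
    n_undefined: int = 0

    @property
    def deterministic(self) -> float:
        return self.variable_selection + self.homogeneous_selection

    @property
    def stochastic(self) -> float:
        return 1.0 - self.deterministic

    @property
    def homogenizing(self) -> float:
        return self.homogeneous_selection + self.homogenizing_dispersal

    @property
    def differentiating(self) -> float:
        return self.variable_selection + self.dispersal_limitation

    def to_dict(self) -> dict:
        d = {p: getattr(self, p) for p in PROCESSES}
        d.update(
            deterministic=self.deterministic, stochastic=self.stochastic,
            homogenizing=self.homogenizing, differentiating=self.differentiating,
            n_pairs=self.n_pairs, n_undefined=self.n_undefined,
        )
        return d


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------

def beta_nti(abund_k, abund_l, dmat: CopheneticMatrix, n_nulls: int = 999,
             seed: int | None = None, weighted: bool = True) -> dict:
    """betaMNTD and betaNTI for one sample pair.

    The null draws new tip labels for the pair's taxon pool uniformly
    without replacement from *all* tips of the tree (joint relabeling, so a
    taxon shared by both samples stays shared).  Returns a dict with
    ``beta_mntd``, ``beta_nti``, ``null_mean``, ``null_sd`` and ``defined``.
    """
    sk = pd.Series(abund_k, dtype=float)
    sl = pd.Series(abund_l, dtype=float)
    sk, sl = sk[sk > 0], sl[sl > 0]
    if len(sk) == 0 or len(sl) == 0:
        raise ValueError("betaNTI undefined for an empty sample")
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    obs = beta_mntd(sk, sl, dmat, weighted=weighted)
    union = sorted(set(sk.index) | set(sl.index))
    upos = {t: i for i, t in enumerate(union)}
    ik = np.array([upos[t] for t in sk.index], dtype=np.intp)
    il = np.array([upos[t] for t in sl.index], dtype=np.intp)
    pk = sk.to_numpy() / sk.sum()
    pl = sl.to_numpy() / sl.sum()
    d = dmat.data
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_nulls)
    for rep in range(n_nulls):
        labels = rng.choice(dmat.n, size=len(union), replace=False)
        tk, tl = labels[ik], labels[il]
        a = d[np.ix_(tk, tl)]
        if weighted:
            nulls[rep] = 0.5 * (pk @ a.min(axis=1) + pl @ a.min(axis=0))
        else:
            nulls[rep] = 0.5 * (a.min(axis=1).mean() + a.min(axis=0).mean())
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if n_nulls > 1 else 0.0
    if sd == 0:
        return {"beta_mntd": obs, "beta_nti": np.nan, "null_mean": mu,
                "null_sd": sd, "defined": False}
    return {"beta_mntd": obs, "beta_nti": float((obs - mu) / sd),
            "null_mean": mu, "null_sd": sd, "defined": True}


def beta_nti_matrix(rel_abund: np.ndarray, d: np.ndarray,
                    tip_positions: np.ndarray, n_nulls: int = 999,
                    seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs betaMNTD_obs and betaNTI.

    One tree-wide label permutation per null replicate serves every pair
    (the standard construction).  ``tip_positions`` maps matrix columns onto
    rows of the full patristic matrix ``d``.  Pairs whose null sd is zero
    get NaN betaNTI.
    """
    P = np.asarray(rel_abund, dtype=float)
    obs = beta_mntd_matrix(P, d, tip_positions)
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    run_sum = np.zeros((n, n))
    run_sq = np.zeros((n, n))
    n_tips = d.shape[0]
    for _ in range(n_nulls):
        perm = rng.permutation(n_tips)
        null = beta_mntd_matrix(P, d, perm[tip_positions])
        run_sum += null
        run_sq += null * null
    mu = run_sum / n_nulls
    var = (run_sq - n_nulls * mu * mu) / max(n_nulls - 1, 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        nti = np.where(sd > 1e-12, (obs - mu) / np.where(sd > 0, sd, 1.0), np.nan)
    np.fill_diagonal(nti, np.nan)
    return obs, nti


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def _null_community(rng, occ_w, abund_w, richness, n_reads):
    """One null assembly: draw ``richness`` taxa weighted by occupancy
    (without replacement), seed each with one read, distribute the rest
    multinomially by dataset-wide relative abundance."""
    n_otus = len(occ_w)
    if richness > np.count_nonzero(occ_w):
        raise ValidationError("sample richness exceeds metacommunity richness")
    # Efraimidis-Spirtes weighted sampling without replacement via Gumbel keys
    with np.errstate(divide="ignore"):
        keys = np.log(occ_w) + rng.gumbel(size=n_otus)
    chosen = np.argpartition(-keys, richness - 1)[:richness]
    counts = np.zeros(n_otus)
    counts[chosen] = 1
    remaining = n_reads - richness
    if remaining > 0:
        w = abund_w[chosen]
        w = w / w.sum()
        counts[chosen] += rng.multinomial(remaining, w)
    return counts


def raup_crick_bray(counts_k, counts_l, occupancy_w, abundance_w,
                    n_nulls: int = 999, seed: int | None = None) -> float:
    """RC_bray for one sample pair.

    Both communities are rebuilt from the metacommunity each replicate;
    RC_raw = (#{null < obs} + 0.5 #{null = obs}) / n_nulls is rescaled to
    [-1, 1] as 2 (RC_raw - 1/2).
    """
    ck = np.asarray(counts_k, dtype=float)
    cl = np.asarray(counts_l, dtype=float)
    occupancy_w = np.asarray(occupancy_w, dtype=float)
    abundance_w = np.asarray(abundance_w, dtype=float)
    obs = np.abs(ck - cl).sum() / (ck.sum() + cl.sum())
    rng = np.random.default_rng(seed)
    rk, nk = int(np.count_nonzero(ck)), int(ck.sum())
    rl, nl = int(np.count_nonzero(cl)), int(cl.sum())
    below = ties = 0
    for _ in range(n_nulls):
        a = _null_community(rng, occupancy_w, abundance_w, rk, nk)
        b = _null_community(rng, occupancy_w, abundance_w, rl, nl)
        null = np.abs(a - b).sum() / (a.sum() + b.sum())
        if null < obs - 1e-12:
            below += 1
        elif abs(null - obs) <= 1e-12:
            ties += 1
    rc_raw = (below + 0.5 * ties) / n_nulls
    return float(2 * (rc_raw - 0.5))


def raup_crick_bray_matrix(counts: np.ndarray, n_nulls: int = 999,
                           seed: int | None = None) -> np.ndarray:
    """All-pairs RC_bray.

    Each replicate rebuilds one null community per sample from the
    metacommunity (occupancy-weighted richness draw + abundance-weighted
    read allocation) and scores all pairs at once; per-pair null
    distributions are identical to the pairwise construction.
    """
    C = np.asarray(counts, dtype=float)
    n_samples, n_otus = C.shape
    occ = (C > 0).sum(axis=0).astype(float)
    abund = C.sum(axis=0).astype(float)
    abund = abund / abund.sum()
    rich = (C > 0).sum(axis=1)
    reads = C.sum(axis=1)
    obs = bray_curtis_matrix(C)
    rng = np.random.default_rng(seed)
    below = np.zeros((n_samples, n_samples))
    ties = np.zeros((n_samples, n_samples))
    nullC = np.empty_like(C)
    for _ in range(n_nulls):
        for s in range(n_samples):
            nullC[s] = _null_community(rng, occ, abund, int(rich[s]), int(reads[s]))
        null_bc = bray_curtis_matrix(nullC)
        below += null_bc < obs - 1e-12
        ties += np.abs(null_bc - obs) <= 1e-12
    rc = 2 * ((below + 0.5 * ties) / n_nulls - 0.5)
    np.fill_diagonal(rc, 0.0)
    return rc


# ---------------------------------------------------------------------------
# classification and fractions
# ---------------------------------------------------------------------------

def classify_pair(beta_nti_value: float, rc_bray_value: float) -> str:
    """Five-process label for one (betaNTI, RC_bray) pair.

    Boundary convention: |betaNTI| = 2 exactly is stochastic-side;
    |RC| = 0.95 exactly is undominated.
    """
    b, r = float(beta_nti_value), float(rc_bray_value)
    if np.isnan(b) or np.isnan(r):
        return "undefined"
    if b > 2:
        return "variable_selection"
    if b < -2:
        return "homogeneous_selection"
    if r > 0.95:
        return "dispersal_limitation"
    if r < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def process_fractions(labels) -> ProcessFractions:
    """Fractions of each assembly process over classified sample pairs."""
    labels = pd.Series(list(labels))
    n_undefined = int((labels == "undefined").sum())
    labels = labels[labels != "undefined"]
    if len(labels) == 0:
        raise ValidationError("no classified sample pairs")
    unknown = set(labels) - set(PROCESSES)
    if unknown:
        raise ValueError(f"unknown process labels: {sorted(unknown)}")
    counts = labels.value_counts()
    frac = {p: float(counts.get(p, 0)) / len(labels) for p in PROCESSES}
    return ProcessFractions(**frac, n_pairs=len(labels), n_undefined=n_undefined)


def pairwise_assembly(cm: CommunityMatrix, dmat: CopheneticMatrix,
                      n_nulls: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Full pairwise assembly table for one (sub)community.

    Long format: sample_i, sample_j, beta_mntd, beta_nti, bray_curtis,
    rc_bray, process.
    """
    otus = cm.otu_ids
    missing = set(otus) - set(dmat.ids)
    if missing:
        raise ValidationError(f"OTUs missing from tree: {sorted(missing)[:5]} ...")
    tip_positions = dmat.positions(otus)
    P = cm.rel_abund.to_numpy()
    ss = np.random.SeedSequence(seed)
    s_nti, s_rc = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    obs_bmntd, nti = beta_nti_matrix(P, dmat.data, tip_positions,
                                     n_nulls=n_nulls, seed=s_nti)
    rc = raup_crick_bray_matrix(cm.counts.to_numpy(), n_nulls=n_nulls, seed=s_rc)
    bc = bray_curtis_matrix(cm.counts.to_numpy())
    rows = []
    ids = cm.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append({
                "sample_i": ids[i], "sample_j": ids[j],
                "beta_mntd": obs_bmntd[i, j], "beta_nti": nti[i, j],
                "bray_curtis": bc[i, j], "rc_bray": rc[i, j],
                "process": classify_pair(nti[i, j], rc[i, j]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# environment links
# ---------------------------------------------------------------------------

def env_mantel(beta_nti_square: pd.DataFrame, env: pd.Series,
               method: str = "pearson", n_perm: int = 999,
               seed: int | None = None) -> stats_core.TestResult:
    """Mantel test of the betaNTI pair matrix against |dE| for one variable."""
    env = env.reindex(beta_nti_square.index)
    if env.isna().any():
        raise ValidationError("environment values missing for some samples")
    if np.ptp(env.to_numpy()) == 0:
        return stats_core.TestResult(np.nan, np.nan, len(env), "mantel",
                                     defined=False)
    b = beta_nti_square.to_numpy(dtype=float).copy()
    np.fill_diagonal(b, 0.0)
    ok = ~np.isnan(b).any(axis=1)
    if not ok.all():
        logger.warning("env_mantel: dropping %d samples with undefined betaNTI",
                       (~ok).sum())
        b = b[np.ix_(ok, ok)]
        env = env[ok]
    e = np.abs(env.to_numpy()[:, None] - env.to_numpy()[None, :])
    return stats_core.mantel_test(b, e, method=method, n_perm=n_perm, seed=seed)


def salinity_bin_analysis(pair_table: pd.DataFrame, ec: pd.Series,
                          n_bins: int = 4) -> dict:
    """Within-bin betaNTI distributions across salinity (EC) quantile bins.

    Returns per-bin summaries plus Kruskal-Wallis omnibus and pairwise
    Wilcoxon rank-sum p-values.  Bins with fewer than 2 samples are dropped
    with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ec = ec.sort_index()
    if np.ptp(ec.to_numpy()) == 0:
        raise ValidationError("EC constant: cannot form salinity bins")
    bins = pd.qcut(ec, q=n_bins, labels=False, duplicates="drop")
    if bins.nunique() < 2:
        raise ValidationError("EC quantiles degenerate: fewer than 2 bins")
    groups: dict[int, np.ndarray] = {}
    summaries = []
    for b in sorted(bins.unique()):
        members = set(bins.index[bins == b])
        if len(members) < 2:
            logger.warning("salinity bin %s has < 2 samples; dropped", b)
            continue
        mask = pair_table["sample_i"].isin(members) & pair_table["sample_j"].isin(members)
        vals = pair_table.loc[mask, "beta_nti"].dropna().to_numpy()
        if len(vals) == 0:
            continue
        groups[b] = vals
        summaries.append({
            "bin": int(b), "n_samples": len(members), "n_pairs": len(vals),
            "ec_min": float(ec[bins == b].min()),
            "ec_max": float(ec[bins == b].max()),
            "beta_nti_mean": float(vals.mean()),
            "beta_nti_median": float(np.median(vals)),
        })
    if len(groups) < 2:
        raise ValidationError("fewer than 2 usable salinity bins")
    kw = stats_core.kruskal_wallis(list(groups.values()))
    pairwise = {}
    keys = sorted(groups)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            res = stats_core.wilcoxon_rank_sum(groups[keys[a]], groups[keys[b]])
            pairwise[(keys[a], keys[b])] = res.p
    return {"bins": pd.DataFrame(summaries), "kruskal_wallis": kw,
            "pairwise_wilcoxon": pairwise}
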