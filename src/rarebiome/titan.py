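"""Threshold indicator taxon analysis.

Per-taxon IndVal change points along an environmental gradient, permutation
z-scores, bootstrap purity/reliability, community-level sum(z) thresholds
and the breadth between the z- and z+ community change points.

Conventions (documented tie rules): candidate change points are midpoints
between consecutive distinct sorted environment values leaving at least
``min_split`` samples on each side; all argmax ties break toward the lowest
candidate, and an exact tie between sides prefers the decreasing (z-) side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import CommunityMatrix, EnvTable, ValidationError

logger = logging.getLogger("rarebiome")


@dataclass
class Candidates:
    """Candidate split positions over env-sorted samples."""

    order: np.ndarray      # sample order sorting env ascending
    env_sorted: np.ndarray
    positions: np.ndarray  # split index k: left = sorted samples [0, k)
    values: np.ndarray     # candidate change-point env values (midpoints)


def _candidates(env: np.ndarray, min_split: int) -> Candidates:
    env = np.asarray(env, dtype=float)
    n = len(env)
    if np.ptp(env) == 0:
        raise ValidationError("environment values all equal")
    if n < 2 * min_split:
        raise ValidationError(f"need >= {2 * min_split} samples")
    order = np.argsort(env, kind="stable")
    es = env[order]
    ks = np.flatnonzero(es[1:] > es[:-1]) + 1
    ks = ks[(ks >= min_split) & (n - ks >= min_split)]
    if len(ks) == 0:
        raise ValidationError("no admissible change-point candidates")
    return Candidates(order, es, ks, 0.5 * (es[ks - 1] + es[ks]))


def _indval_curves(a_sorted: np.ndarray, cand: Candidates) -> tuple[np.ndarray, np.ndarray]:
    """IndVal (0-100) at each candidate for the left and right groups.

    ``a_sorted`` may be (n,) or (m, n) for m vectors at once (permutations);
    returns arrays shaped like (..., n_candidates).
    """
    a = np.atleast_2d(np.asarray(a_sorted, dtype=float))
    n = a.shape[1]
    ks = cand.positions
    ca = np.cumsum(a, axis=1)
    cp = np.cumsum(a > 0, axis=1)
    total_a = ca[:, -1:]
    total_p = cp[:, -1:]
    left_sum = ca[:, ks - 1]
    left_occ = cp[:, ks - 1]
    lm = left_sum / ks
    rm = (total_a - left_sum) / (n - ks)
    denom = lm + rm
    with np.errstate(invalid="ignore", divide="ignore"):
        a_left = np.where(denom > 0, lm / denom, 0.0)
        a_right = np.where(denom > 0, rm / denom, 0.0)
    b_left = left_occ / ks
    b_right = (total_p - left_occ) / (n - ks)
    iv_left = 100.0 * a_left * b_left
    iv_right = 100.0 * a_right * b_right
    if np.asarray(a_sorted).ndim == 1:
        return iv_left[0], iv_right[0]
    return iv_left, iv_right


def _max_indval(iv_left: np.ndarray, iv_right: np.ndarray) -> tuple[int, int, float]:
    """(candidate index, side, value); side 0 = left/z-, 1 = right/z+."""
    best = np.maximum(iv_left, iv_right)
    ci = int(np.argmax(best))  # argmax takes first == lowest candidate on ties
    side = 0 if iv_left[ci] >= iv_right[ci] else 1
    return ci, side, float(best[ci])


def indval_changepoint(abund, env, min_split: int = 5) -> dict:
    """Change point maximizing IndVal for one taxon.

    Returns ``change_point``, ``indval`` (0-100), ``direction`` ("z-" for
    taxa indicating the low side, "z+" for the high side) and the candidate
    index used.
    """
    a = np.asarray(abund, dtype=float)
    if a.sum() == 0:
        raise ValidationError("taxon absent from every sample")
    cand = _candidates(np.asarray(env, dtype=float), min_split)
    ivl, ivr = _indval_curves(a[cand.order], cand)
    ci, side, iv = _max_indval(ivl, ivr)
    return {
        "change_point": float(cand.values[ci]),
        "indval": iv,
        "direction": "z-" if side == 0 else "z+",
        "candidate_index": ci,
    }


def taxon_z(abund, env, min_split: int = 5, n_perm: int = 250,
            seed: int | None = None) -> dict:
    """Permutation z-score and p for a taxon's maximal IndVal."""
    a = np.asarray(abund, dtype=float)
    env = np.asarray(env, dtype=float)
    base = indval_changepoint(a, env, min_split)
    cand = _candidates(env, min_split)
    a_sorted = a[cand.order]
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(a_sorted) for _ in range(n_perm)])
    ivl, ivr = _indval_curves(perms, cand)
    perm_max = np.maximum(ivl, ivr).max(axis=1)
    mu = float(perm_max.mean())
    sd = float(perm_max.std(ddof=1)) if n_perm > 1 else 0.0
    z = np.nan if sd == 0 else (base["indval"] - mu) / sd
    p = float((np.sum(perm_max >= base["indval"] - 1e-12) + 1) / (n_perm + 1))
    return {**base, "z": float(z) if sd else np.nan, "p": p,
            "perm_mean": mu, "perm_sd": sd, "defined": sd > 0}


def bootstrap_purity_reliability(abund, env, min_split: int = 5,
                                 n_boot: int = 500, n_perm: int = 250,
                                 alpha: float = 0.05,
                                 seed: int | None = None) -> dict:
    """Bootstrap consistency of a taxon's response direction and
    significance.

    purity = fraction of bootstrap replicates recovering the full-data
    direction; reliability = fraction with permutation p <= alpha.
    Degenerate replicates (taxon absent or no admissible split) are skipped
    and logged.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    a = np.asarray(abund, dtype=float)
    env = np.asarray(env, dtype=float)
    full = indval_changepoint(a, env, min_split)
    rng = np.random.default_rng(seed)
    n = len(a)
    match = reliable = valid = skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ab, eb = a[idx], env[idx]
        try:
            res = taxon_z(ab, eb, min_split=min_split, n_perm=n_perm,
                          seed=int(rng.integers(2 ** 31)))
        except ValidationError:
            skipped += 1
            continue
        valid += 1
        if res["direction"] == full["direction"]:
            match += 1
        if res["p"] <= alpha:
            reliable += 1
    if skipped:
        logger.info("bootstrap: skipped %d degenerate replicates", skipped)
    if valid == 0:
        raise ValidationError("every bootstrap replicate was degenerate")
    purity = match / valid
    reliability = reliable / valid
    return {"purity": purity, "reliability": reliability,
            "pure_and_reliable": purity >= 0.95 and reliability >= 0.95,
            "n_valid": valid, "n_skipped": skipped}


def titan_analysis(cm: CommunityMatrix, env, min_split: int = 5,
                   n_perm: int = 250, n_boot: int = 500, alpha: float = 0.05,
                   seed: int | None = None) -> pd.DataFrame:
    """Per-taxon TITAN table for one environmental variable."""
    env = np.asarray(pd.Series(env).reindex(cm.sample_ids), dtype=float)
    rel = cm.rel_abund
    ss = np.random.SeedSequence(seed)
    rows = []
    for otu, child in zip(cm.otu_ids, ss.spawn(cm.n_otus)):
        a = rel[otu].to_numpy()
        if a.sum() == 0:
            continue
        s1, s2 = (int(c.generate_state(1)[0]) for c in child.spawn(2))
        res = taxon_z(a, env, min_split=min_split, n_perm=n_perm, seed=s1)
        boot = bootstrap_purity_reliability(
            a, env, min_split=min_split, n_boot=n_boot, n_perm=n_perm,
            alpha=alpha, seed=s2)
        rows.append({
            "otu_id": otu, "change_point": res["change_point"],
            "direction": res["direction"], "indval": res["indval"],
            "z": res["z"], "p": res["p"], "purity": boot["purity"],
            "reliability": boot["reliability"],
            "pure_and_reliable": boot["pure_and_reliable"],
        })
    return pd.DataFrame(rows)


def community_thresholds(cm: CommunityMatrix, env, taxa: pd.DataFrame,
                         min_split: int = 5, n_perm: int = 250,
                         seed: int | None = None) -> dict:
    """Community-level sum(z) change points and breadth.

    For every candidate change point, each pure-and-reliable taxon
    contributes the z-score of its direction-side IndVal at that candidate
    (permutation-standardized); the z- and z+ sums peak at the lower and
    upper community thresholds, and breadth is the distance between them.
    """
    env = np.asarray(pd.Series(env).reindex(cm.sample_ids), dtype=float)
    cand = _candidates(env, min_split)
    qual = taxa[taxa["pure_and_reliable"]]
    if len(qual) == 0:
        raise ValidationError(
            f"no pure-and-reliable taxa ({len(taxa)} tested)")
    rel = cm.rel_abund
    rng = np.random.default_rng(seed)
    nc = len(cand.values)
    sum_z = {"z-": np.zeros(nc), "z+": np.zeros(nc)}
    for _, row in qual.iterrows():
        a_sorted = rel[row["otu_id"]].to_numpy()[cand.order]
        ivl, ivr = _indval_curves(a_sorted, cand)
        perms = np.stack([rng.permutation(a_sorted) for _ in range(n_perm)])
        pl, pr = _indval_curves(perms, cand)
        obs = ivl if row["direction"] == "z-" else ivr
        pm = pl if row["direction"] == "z-" else pr
        mu, sd = pm.mean(axis=0), pm.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (obs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        sum_z[row["direction"]] += z
    curves = {k: np.maximum(v, 0.0) for k, v in sum_z.items()}
    cp = {k: float(cand.values[int(np.argmax(v))]) for k, v in curves.items()}
    return {
        "candidates": cand.values,
        "sum_z_minus": curves["z-"], "sum_z_plus": curves["z+"],
        "cp_z_minus": cp["z-"], "cp_z_plus": cp["z+"],
        "breadth": abs(cp["z+"] - cp["z-"]),
        "n_taxa": {"z-": int((qual["direction"] == "z-").sum()),
                   "z+": int((qual["direction"] == "z+").sum())},
    }


def environmental_breadth_profile(cm: CommunityMatrix, env_table: EnvTable,
                                  variables=None, min_split: int = 5,
                                  n_perm: int = 250, n_boot: int = 500,
                                  alpha: float = 0.05,
                                  seed: int | None = None) -> pd.DataFrame:
    """Breadth summary per environmental variable.

    Emits both candidate breadth definitions: the sum(z) change-point span
    (primary) and the 5th-95th percentile range of individual
    pure-and-reliable taxon change points (secondary).
    """
    if variables is None:
        variables = list(env_table.env.columns)
    ss = np.random.SeedSequence(seed)
    rows = []
    for variable, child in zip(variables, ss.spawn(len(variables))):
        s1, s2 = (int(c.generate_state(1)[0]) for c in child.spawn(2))
        row = {"variable": variable, "breadth": np.nan, "cp_z_minus": np.nan,
               "cp_z_plus": np.nan, "taxon_cp_p5": np.nan,
               "taxon_cp_p95": np.nan, "taxon_cp_range": np.nan,
               "n_pure_reliable": 0}
        env = env_table.env[variable]
        try:
            taxa = titan_analysis(cm, env, min_split=min_split, n_perm=n_perm,
                                  n_boot=n_boot, alpha=alpha, seed=s1)
            comm = community_thresholds(cm, env, taxa, min_split=min_split,
                                        n_perm=n_perm, seed=s2)
        except ValidationError as exc:
            logger.warning("titan %s: %s", variable, exc)
            rows.append(row)
            continue
        cps = taxa.loc[taxa["pure_and_reliable"], "change_point"].to_numpy()
        lo, hi = np.percentile(cps, [5, 95])
        row.update(breadth=comm["breadth"], cp_z_minus=comm["cp_z_minus"],
                   cp_z_plus=comm["cp_z_plus"], taxon_cp_p5=float(lo),
                   taxon_cp_p95=float(hi), taxon_cp_range=float(hi - lo),
                   n_pure_reliable=len(cps))
        rows.append(row)
    return pd.DataFrame(rows)
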