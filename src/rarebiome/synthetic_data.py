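"""Synthetic gradient metacommunities with known assembly regimes.

Generates everything the downstream stages consume — a pure-birth tree,
a lognormal species-abundance distribution shaped by a selection (Gaussian
niche, optima evolved by Brownian motion on the tree), dispersal
(exponential distance decay from random home locations) or neutral kernel,
multinomially-sampled counts, environment/function metadata, and
phylogenetically structured function annotations — together with the truth
needed for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .io_config import (
    ENV_VARIABLES, FUNCTION_VARIABLES, CommunityMatrix, EnvTable, Phylogeny,
)

REGIMES = ("selection", "dispersal", "neutral", "mixed")


@dataclass
class SimulationConfig:
    n_samples: int = 90
    n_otus: int = 800
    gradient_min: float = 0.09
    gradient_max: float = 19.91
    regime: str = "selection"
    niche_breadth: float = 2.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    birth_rate: float = 1.0
    bm_rate: float = 1.0
    dispersal_scale: float = 0.08
    depth: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.gradient_min < self.gradient_max:
            raise ValueError("gradient_min must be < gradient_max")
        if self.niche_breadth <= 0 or self.lognormal_sigma <= 0:
            raise ValueError("niche_breadth and lognormal_sigma must be > 0")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")


@dataclass
class SyntheticDataset:
    community: CommunityMatrix
    tree: Phylogeny
    env: EnvTable
    truth: pd.DataFrame
    regime: str
    config: SimulationConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  seed: int | None = None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with exponential waiting times.

    Epoch k (k = 2..n lineages) lasts Exp(birth_rate * k); the final epoch
    stretches all pendant branches, so the expected root-to-tip depth is
    sum_{k=2..n} 1/(birth_rate * k).  Tips are labeled OTU_1..OTU_n.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    root = skbio.TreeNode(length=None)
    a, b = skbio.TreeNode(length=0.0), skbio.TreeNode(length=0.0)
    root.extend([a, b])
    active = [a, b]
    for k in range(2, n_tips + 1):
        dt = rng.exponential(1.0 / (birth_rate * k))
        for tip in active:
            tip.length += dt
        if k < n_tips:
            split = active[rng.integers(len(active))]
            c1, c2 = skbio.TreeNode(length=0.0), skbio.TreeNode(length=0.0)
            split.extend([c1, c2])
            active.remove(split)
            active.extend([c1, c2])
    order = rng.permutation(n_tips)
    for i, tip in enumerate(active):
        tip.name = f"OTU_{order[i] + 1}"
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait_bm(tree: Phylogeny, rate: float = 1.0,
                      seed: int | None = None) -> pd.Series:
    """Continuous trait from root-to-tip Brownian accumulation:
    increments ~ Normal(0, rate * branch length)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    values = {id(tree.tree): 0.0}
    out = {}
    for node in tree.tree.preorder(include_self=False):
        bl = node.length if node.length is not None else 0.0
        step = rng.normal(0.0, np.sqrt(rate * bl)) if rate * bl > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
        if not node.children:
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait").reindex(tree.tip_names)


def simulate_binary_trait(tree: Phylogeny, mode: str = "random",
                          prevalence: float = 0.5,
                          seed: int | None = None) -> pd.Series:
    """Binary trait on tips.

    ``random`` shuffles a fixed-prevalence state vector uniformly across
    tips; ``threshold_bm`` thresholds a Brownian trait at its prevalence
    quantile, producing phylogenetically clumped states.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    n = tree.n_tips
    n_ones = int(round(prevalence * n))
    if n_ones < 1:
        raise ValueError("prevalence * n_tips must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "random":
        states = np.zeros(n)
        states[:n_ones] = 1
        rng.shuffle(states)
        return pd.Series(states, index=tree.tip_names, name="state")
    if mode == "threshold_bm":
        trait = simulate_trait_bm(tree, rate=1.0,
                                  seed=int(rng.integers(2 ** 31)))
        order = np.argsort(-trait.to_numpy(), kind="stable")
        states = np.zeros(n)
        states[order[:n_ones]] = 1
        return pd.Series(states, index=trait.index, name="state")
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if np.ptp(x) == 0:
        return np.full_like(x, 0.5 * (lo + hi))
    return lo + (x - x.min()) * (hi - lo) / np.ptp(x)


def simulate_gradient_metacommunity(config: SimulationConfig) -> SyntheticDataset:
    """Counts, tree, metadata and truth for one assembly regime.

    Expected abundance of OTU i in sample s is the lognormal base abundance
    times a regime kernel: Gaussian niche exp(-(E_s - mu_i)^2 / (2 sigma^2))
    with Brownian niche optima (selection), exponential distance decay from
    a random home coordinate on a 1-D transect (dispersal), nothing
    (neutral), or both with transect position tied to the gradient (mixed).
    Counts are multinomial at the configured depth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_otus, cfg.birth_rate,
                         seed=int(rng.integers(2 ** 31)))
    otus = [f"OTU_{i + 1}" for i in range(cfg.n_otus)]
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    E = np.linspace(cfg.gradient_min, cfg.gradient_max, cfg.n_samples)

    base = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, cfg.n_otus)

    bm = simulate_trait_bm(tree, rate=cfg.bm_rate,
                           seed=int(rng.integers(2 ** 31)))
    optima = pd.Series(
        _rescale(bm.to_numpy(), cfg.gradient_min, cfg.gradient_max),
        index=bm.index).reindex(otus).to_numpy()

    if cfg.regime == "mixed":
        coords = (E - cfg.gradient_min) / (cfg.gradient_max - cfg.gradient_min)
    else:
        coords = rng.uniform(0, 1, cfg.n_samples)
    homes = coords[rng.integers(0, cfg.n_samples, cfg.n_otus)]

    W = np.tile(base, (cfg.n_samples, 1)).astype(float)
    if cfg.regime in ("selection", "mixed"):
        W *= np.exp(-(E[:, None] - optima[None, :]) ** 2
                    / (2 * cfg.niche_breadth ** 2))
    if cfg.regime in ("dispersal", "mixed"):
        W *= np.exp(-np.abs(coords[:, None] - homes[None, :])
                    / cfg.dispersal_scale)

    counts = np.empty((cfg.n_samples, cfg.n_otus), dtype=np.int64)
    for s in range(cfg.n_samples):
        p = W[s] / W[s].sum()
        counts[s] = rng.multinomial(cfg.depth, p)
    community = CommunityMatrix(
        pd.DataFrame(counts, index=samples, columns=otus))

    env = _metadata_frame(E, coords, samples, rng)
    truth = pd.DataFrame({
        "otu_id": otus, "base_abundance": base, "niche_optimum": optima,
        "niche_breadth": cfg.niche_breadth, "home_coord": homes,
    }).set_index("otu_id")
    return SyntheticDataset(community, tree, env, truth, cfg.regime, cfg)


def _metadata_frame(E, coords, samples, rng) -> EnvTable:
    """Environment table: EC is the gradient; other variables are noisy
    affine responses to it; function measurements are placeholders that
    simulate_function_data can overwrite."""
    n = len(samples)
    env = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    env["EC"] = E
    env["pH"] = 7.5 + 0.05 * (E - E.mean()) + rng.normal(0, 0.2, n)
    for var in ENV_VARIABLES:
        if var in env.columns:
            continue
        slope = rng.normal(0, 0.3)
        env[var] = np.abs(10 + slope * (E - E.mean()) + rng.normal(0, 1.5, n))
    functions = pd.DataFrame(
        rng.normal(10, 2, (n, len(FUNCTION_VARIABLES))),
        index=env.index, columns=FUNCTION_VARIABLES)
    extra = pd.DataFrame({"transect_coord": coords}, index=env.index)
    return EnvTable(env=env[ENV_VARIABLES], functions=functions, extra=extra)


def simulate_function_data(dataset: SyntheticDataset, n_functions: int = 17,
                           sharing: str = "clade",
                           noise_sd: float = 0.05,
                           seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OTU x function incidence plus per-sample function measurements.

    ``clade`` sharing gains each function on a random clade of the tree
    (phylogenetically clustered carriers) plus a small random background;
    ``random`` assigns carriers uniformly.  Per-sample measurements are
    abundance-weighted sums of capable OTUs with Normal noise, rescaled to
    the measurement columns of the dataset's metadata (first
    ``n_functions`` of them).
    """
    if n_functions < 1:
        raise ValueError("n_functions must be >= 1")
    rng = np.random.default_rng(seed)
    tree = dataset.tree
    otus = dataset.community.otu_ids
    nodes = [n for n in tree.tree.non_tips(include_self=True)]
    names = (FUNCTION_VARIABLES[:n_functions]
             if n_functions <= len(FUNCTION_VARIABLES)
             else [f"F{i + 1}" for i in range(n_functions)])
    inc = pd.DataFrame(False, index=pd.Index(otus, name="otu_id"),
                       columns=names)
    for f in names:
        if sharing == "clade":
            node = nodes[rng.integers(len(nodes))]
            carriers = {t.name for t in node.tips()}
            background = rng.random(len(otus)) < 0.02
            col = np.array([o in carriers for o in otus]) | background
        elif sharing == "random":
            col = rng.random(len(otus)) < 0.3
        else:
            raise ValueError(f"unknown sharing model {sharing!r}")
        if not col.any():
            col[rng.integers(len(otus))] = True
        inc[f] = col
    rel = dataset.community.rel_abund.to_numpy()
    raw = rel @ inc.to_numpy(dtype=float)
    raw += rng.normal(0, noise_sd, raw.shape)
    measurements = pd.DataFrame(raw, index=dataset.community.sample_ids,
                                columns=names)
    return inc, measurements
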