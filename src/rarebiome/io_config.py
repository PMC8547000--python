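"""Core data containers, file I/O, run configuration and the pipeline driver.

Formats handled here are deliberately plain: tab-separated tables for
community counts, sample metadata and every result table, and newick for
trees.  The internal orientation convention is samples x OTUs everywhere;
readers transpose on request so no downstream code ever has to guess.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("rarebiome")

#: Environmental variables recognised in sample metadata.
ENV_VARIABLES = [
    "pH", "EC", "TC", "TN", "IP", "OP", "TP", "AP", "TK", "AK", "NH4", "NO3",
]

#: The 17 ecosystem-function measurements (C-, N- and P-cycling).
FUNCTION_VARIABLES = [
    "TC", "bG", "CBH", "bF", "PhOx",
    "TN", "NH4", "NO3", "urease", "Ary", "NAG",
    "TP", "AP", "IP", "OP", "Pho", "Phy",
]


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Samples x OTUs count table with derived relative abundances.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = sample ids, columns = OTU ids.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate OTU ids")
        if (c.to_numpy() < 0).any():
            raise ValidationError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def rel_abund(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1 for non-empty samples)."""
        totals = self.counts.sum(axis=1)
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=0)

    @property
    def total_reads(self) -> pd.Series:
        """Dataset-wide read total per OTU."""
        return self.counts.sum(axis=0)

    def subset_otus(self, otu_ids) -> "CommunityMatrix":
        return CommunityMatrix(self.counts.loc[:, list(otu_ids)].copy())

    def subset_samples(self, sample_ids) -> "CommunityMatrix":
        return CommunityMatrix(self.counts.loc[list(sample_ids), :].copy())


@dataclass
class Phylogeny:
    """Rooted tree over OTU labels, backed by a scikit-bio ``TreeNode``."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if any(n is None for n in names):
            raise ValidationError("tree has unnamed tips")
        if len(names) != len(set(names)):
            raise ValidationError("duplicate tip labels in tree")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValidationError("negative branch length")

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.tips())

    def prune_to(self, labels) -> "Phylogeny":
        """Return a copy of the tree restricted to ``labels`` (shears other tips)."""
        keep = set(labels)
        missing = keep - set(self.tip_names)
        if missing:
            raise ValidationError(f"labels absent from tree: {sorted(missing)}")
        return Phylogeny(self.tree.shear(keep))

    def write(self, path) -> None:
        self.tree.write(str(path), format="newick")


@dataclass
class EnvTable:
    """Per-sample environmental variables plus ecosystem-function measurements."""

    env: pd.DataFrame
    functions: pd.DataFrame
    extra: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.env.index)

    def validate_against(self, cm: CommunityMatrix) -> None:
        mismatch = set(self.sample_ids) ^ set(cm.sample_ids)
        if mismatch:
            raise ValidationError(
                f"sample id mismatch between metadata and community table: {sorted(mismatch)}"
            )


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, with the defaults used throughout."""

    community_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    outdir: str = "results"
    min_reads: int = 20
    rare_threshold: float = 1e-4
    abundant_threshold: float = 1e-3
    n_nulls: int = 999
    n_permutations: int = 999
    n_bootstrap: int = 500
    seed: int = 0
    alpha: float = 0.05
    renormalize_subcommunities: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.rare_threshold < self.abundant_threshold < 1):
            raise ValidationError(
                "thresholds must satisfy 0 < rare < abundant < 1"
            )
        for name in ("n_nulls", "n_permutations", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_community_table(path, samples_as_rows: bool = False) -> CommunityMatrix:
    """Read a tab-separated OTU count table.

    The on-disk convention (shared with most amplicon pipelines) is OTUs as
    rows and samples as columns; pass ``samples_as_rows=True`` if the table
    is already oriented samples x OTUs.  The result is always samples x OTUs.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty community table") from exc
    if df.empty:
        raise ValidationError(f"{path}: empty community table")
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric count at row {bad.index[0]!r}, column {col!r}"
            )
    values = df.to_numpy()
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    logger.info(
        "read community table %s: %d samples x %d OTUs (samples_as_rows=%s)",
        path, df.shape[0], df.shape[1], samples_as_rows,
    )
    return CommunityMatrix(df.astype(np.int64))


def read_newick_tree(path, midpoint_root: bool = False) -> Phylogeny:
    """Read a rooted newick tree; polytomies and zero-length branches are fine."""
    path = Path(path)
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"{path}: cannot parse newick ({exc})") from exc
    if len(tree.children) > 2 and midpoint_root:
        tree = tree.root_at_midpoint()
    elif len(tree.children) > 2 and len(tree.children) != 3:
        pass  # basal polytomy, accept as rooted
    return Phylogeny(tree)


def read_sample_metadata(
    path,
    env_variables=None,
    function_variables=None,
) -> EnvTable:
    """Read tab-separated sample metadata (samples as rows).

    Columns are partitioned into environmental variables and ecosystem
    functions by the configured name lists; a column named in both lists
    appears in both tables (e.g. TC is a soil property *and* a C-cycling
    function).  Unlisted columns are carried through in ``extra`` with a
    logged warning.  Missing values are rejected.
    """
    env_variables = ENV_VARIABLES if env_variables is None else list(env_variables)
    function_variables = (
        FUNCTION_VARIABLES if function_variables is None else list(function_variables)
    )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    env_cols = [c for c in env_variables if c in df.columns]
    fn_cols = [c for c in function_variables if c in df.columns]
    used = set(env_cols) | set(fn_cols)
    extra_cols = [c for c in df.columns if c not in used]
    if extra_cols:
        logger.warning("metadata %s: unlisted columns carried through: %s", path, extra_cols)
    for cols in (env_cols, fn_cols):
        sub = df[cols]
        if sub.isna().any().any():
            bad = sub.isna().any(axis=1)
            raise ValidationError(
                f"{path}: missing values for samples {list(df.index[bad])}"
            )
    env = df[env_cols].astype(float)
    if "EC" in env.columns and (env["EC"] < 0).any():
        raise ValidationError(f"{path}: negative EC values")
    return EnvTable(
        env=env,
        functions=df[fn_cols].astype(float),
        extra=df[extra_cols] if extra_cols else None,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_results_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table as TSV (6 significant digits) plus a lossless
    JSON sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    sidecar = path.with_suffix(path.suffix + ".json")
    df.reset_index().to_json(sidecar, orient="split", double_precision=15)


def write_community_table(cm: CommunityMatrix, path, samples_as_rows: bool = False) -> None:
    df = cm.counts if samples_as_rows else cm.counts.T
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

STAGES = ("classification", "diversity", "assembly", "signals", "titan", "emf")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on the configured inputs and write one TSV per stage.

    Returns the output directory.  Identical config + seed reproduce
    byte-identical numeric outputs.
    """
    from . import abundance_partition as ap
    from . import assembly as asm
    from . import diversity as dv
    from . import emf_function as emf
    from . import phylosignal as ps
    from . import titan as tt

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.community_path is None or config.metadata_path is None:
        raise ValidationError("community_path and metadata_path are required")
    if config.tree_path is None:
        raise ValidationError(
            "tree_path is required: diversity/assembly/signal stages are phylogenetic"
        )

    cm = read_community_table(config.community_path)
    tree = read_newick_tree(config.tree_path)
    meta = read_sample_metadata(config.metadata_path)
    meta.validate_against(cm)

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(c.generate_state(1)[0]) for s, c in
                   zip(STAGES, ss.spawn(len(STAGES)))}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # --- classification ---
    def do_classify():
        filtered = ap.filter_low_read_otus(cm, config.min_reads)
        cls = ap.classify_otus(
            filtered, config.rare_threshold, config.abundant_threshold
        )
        write_results_table(cls.table, outdir / "classification.tsv")
        return filtered, cls

    filtered, cls = _stage("classification", do_classify)
    dmat = dv.cophenetic_matrix(tree.prune_to(
        [o for o in filtered.otu_ids if o in set(tree.tip_names)]))
    subs = {}
    for klass in ("rare", "abundant"):
        try:
            subs[klass] = ap.extract_subcommunity(
                filtered, cls, klass,
                renormalize=config.renormalize_subcommunities)
        except ValidationError:
            logger.warning("no OTUs in class %s; stage outputs limited", klass)

    # --- diversity ---
    def do_diversity():
        rows = []
        for klass, sub in subs.items():
            rel = sub.rel_abund
            for sid in sub.sample_ids:
                p = rel.loc[sid]
                present = p[p > 0]
                if len(present) < 2:
                    continue
                res = dv.ses_mntd(
                    p, dmat, n_nulls=config.n_nulls,
                    seed=stage_seeds["diversity"],
                )
                rows.append({
                    "sample": sid, "subcommunity": klass,
                    "shannon": dv.shannon_index(p.to_numpy()),
                    "mntd_obs": res.mntd_obs, "ses_mntd": res.ses,
                    "null_mean": res.null_mean, "null_sd": res.null_sd,
                })
        out = pd.DataFrame(rows)
        write_results_table(out, outdir / "diversity.tsv", index=False)
        return out

    alpha_table = _stage("diversity", do_diversity)

    # --- assembly ---
    def do_assembly():
        frames = []
        for klass, sub in subs.items():
            pa = asm.pairwise_assembly(
                sub, dmat, n_nulls=config.n_nulls, seed=stage_seeds["assembly"])
            pa.insert(0, "subcommunity", klass)
            frames.append(pa)
        out = pd.concat(frames, ignore_index=True)
        write_results_table(out, outdir / "assembly.tsv", index=False)
        fr = pd.DataFrame([
            {"subcommunity": k,
             **asm.process_fractions(
                 out.loc[out.subcommunity == k, "process"]).to_dict()}
            for k in subs
        ])
        write_results_table(fr, outdir / "assembly_fractions.tsv", index=False)
        return out

    _stage("assembly", do_assembly)

    # --- phylogenetic signal ---
    def do_signal():
        frames = []
        for klass, sub in subs.items():
            prof = ps.signal_profile(
                sub, tree, meta, alpha=config.alpha,
                n_permutations=min(config.n_permutations, 999),
                seed=stage_seeds["signals"],
            )
            prof.insert(0, "subcommunity", klass)
            frames.append(prof)
        out = pd.concat(frames, ignore_index=True)
        write_results_table(out, outdir / "signals.tsv", index=False)
        return out

    _stage("signals", do_signal)

    # --- titan ---
    def do_titan():
        frames = []
        for klass, sub in subs.items():
            prof = tt.environmental_breadth_profile(
                sub, meta, n_perm=250, n_boot=min(config.n_bootstrap, 500),
                seed=stage_seeds["titan"],
            )
            prof.insert(0, "subcommunity", klass)
            frames.append(prof)
        out = pd.concat(frames, ignore_index=True)
        write_results_table(out, outdir / "titan.tsv", index=False)
        return out

    _stage("titan", do_titan)

    # --- emf ---
    def do_emf():
        emf_vec = emf.zscore_multifunctionality(meta.functions)
        out = emf_vec.to_frame("EMF")
        rows = []
        for klass, sub in subs.items():
            shn = alpha_table.query("subcommunity == @klass").set_index("sample")
            for metric in ("shannon", "ses_mntd"):
                x = shn[metric].reindex(out.index).to_numpy(dtype=float)
                ok = np.isfinite(x)
                if ok.sum() >= 3 and np.ptp(x[ok]) > 0:
                    reg = emf.diversity_emf_regression(
                        x[ok], emf_vec.to_numpy()[ok])
                    rows.append({"subcommunity": klass, "metric": metric, **reg})
        write_results_table(out, outdir / "emf.tsv")
        write_results_table(pd.DataFrame(rows), outdir / "emf_regressions.tsv",
                            index=False)
        return out

    _stage("emf", do_emf)

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "version": __version__,
        "stages": list(STAGES),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
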