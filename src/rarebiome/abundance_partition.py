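"""Read filtering, rare/abundant/intermediate classification, occupancy and
abundance-occupancy regressions.

Classification uses dataset-wide relative abundance (OTU reads / total
retained reads) with strict thresholds: below the rare cutoff -> rare, above
the abundant cutoff -> abundant, everything else (including exact boundary
hits) -> intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_core
from .io_config import CommunityMatrix, ValidationError

CLASSES = ("rare", "intermediate", "abundant")


@dataclass
class AbundanceClassification:
    """Per-OTU classification table.

    ``table`` columns: ``reads`` (dataset-wide total), ``rel_abund``
    (dataset-wide fraction), ``otu_class``, ``occupancy``.
    """

    table: pd.DataFrame
    rare_threshold: float
    abundant_threshold: float

    def otus_in_class(self, klass: str) -> list[str]:
        if klass not in CLASSES:
            raise ValueError(f"unknown class {klass!r}")
        return list(self.table.index[self.table["otu_class"] == klass])

    def richness_share(self, klass: str) -> float:
        """Fraction of retained OTUs in a class."""
        return len(self.otus_in_class(klass)) / len(self.table)

    def abundance_share(self, klass: str) -> float:
        """Fraction of retained reads carried by a class."""
        return float(self.table.loc[self.table["otu_class"] == klass,
                                    "rel_abund"].sum())

    def summary(self) -> pd.DataFrame:
        rows = []
        for klass in CLASSES:
            rows.append({
                "otu_class": klass,
                "n_otus": len(self.otus_in_class(klass)),
                "richness_share": self.richness_share(klass),
                "abundance_share": self.abundance_share(klass),
            })
        return pd.DataFrame(rows).set_index("otu_class")


def filter_low_read_otus(cm: CommunityMatrix, min_reads: int = 20) -> CommunityMatrix:
    """Drop OTUs whose dataset-wide read total is strictly below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = cm.total_reads
    keep = totals.index[totals >= min_reads]
    if len(keep) == 0:
        raise ValidationError("read filter removed every OTU")
    return cm.subset_otus(keep)


def occupancy(cm: CommunityMatrix) -> pd.Series:
    """Per-OTU fraction of samples with a nonzero count."""
    return (cm.counts > 0).sum(axis=0) / cm.n_samples


def classify_otus(cm: CommunityMatrix, rare_threshold: float = 1e-4,
                  abundant_threshold: float = 1e-3) -> AbundanceClassification:
    """Assign each retained OTU to rare / intermediate / abundant.

    Dataset-wide relative abundance r_i = reads_i / total reads; r_i strictly
    below ``rare_threshold`` is rare, strictly above ``abundant_threshold``
    is abundant, the rest intermediate.
    """
    if not rare_threshold < abundant_threshold:
        raise ValueError("rare_threshold must be < abundant_threshold")
    totals = cm.total_reads
    grand = totals.sum()
    if grand == 0:
        raise ValidationError("community table has zero total reads")
    rel = totals / grand
    klass = pd.Series("intermediate", index=totals.index, name="otu_class")
    klass[rel < rare_threshold] = "rare"
    klass[rel > abundant_threshold] = "abundant"
    table = pd.DataFrame({
        "reads": totals, "rel_abund": rel, "otu_class": klass,
        "occupancy": occupancy(cm),
    })
    table.index.name = "otu_id"
    return AbundanceClassification(table, rare_threshold, abundant_threshold)


def extract_subcommunity(cm: CommunityMatrix, classification: AbundanceClassification,
                         klass: str, renormalize: bool = True) -> CommunityMatrix:
    """Restrict the community matrix to OTUs of one abundance class.

    With ``renormalize=True`` (default) the returned matrix's relative
    abundances are proper within-subcommunity distributions; with ``False``
    downstream code should divide by the whole-community sample totals
    itself (the raw counts are identical either way — renormalization only
    matters for the derived ``rel_abund``, which is always computed
    within-matrix, so the flag is recorded for callers that need the
    whole-community denominators).
    """
    otus = classification.otus_in_class(klass)
    if not otus:
        raise ValidationError(f"no OTUs in class {klass!r}")
    sub = cm.subset_otus(otus)
    sub.renormalized = renormalize  # advisory flag for reporting
    return sub


def abundance_occupancy_regression(classification: AbundanceClassification,
                                   klass: str) -> dict:
    """OLS of occupancy on log10(total reads) over the OTUs of one class."""
    sub = classification.table[classification.table["otu_class"] == klass]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 OTUs in class {klass!r}")
    x = np.log10(sub["reads"].to_numpy(dtype=float))
    y = sub["occupancy"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "R2": 0.0,
                "p": np.nan, "n": len(sub)}
    return stats_core.ols_regression(x, y)
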