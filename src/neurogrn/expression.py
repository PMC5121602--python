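"""RPKM normalization, per-gene z-scores, tissue-enrichment classification,
and hierarchical ordering of expression profiles.

RPKM[g, s] = counts[g, s] / (gene_length_kb[g] * library_size_millions[s]).
z[g, s] = (RPKM[g, s] - row mean) / row sample sd (ddof = 1); constant rows
z-score to all zeros with a warning. A gene is called tissue-enriched when
(mean RPKM in group A + eps) / (mean RPKM in group B + eps) >= fold threshold
(inclusive, "at least"-fold), with pseudocount eps = 0.1 RPKM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

__all__ = [
    "TISSUE_GROUPS",
    "FOLD_PSEUDOCOUNT_RPKM",
    "ExpressionMatrix",
    "EnrichmentLabel",
    "rpkm",
    "zscore_rows",
    "classify_enrichment",
    "hierarchical_order",
]

logger = logging.getLogger(__name__)

TISSUE_GROUPS = ("ES", "embryonic_CNS", "adult_CNS", "other")

#: Pseudocount (RPKM) added to both group means in fold changes.
FOLD_PSEUDOCOUNT_RPKM = 0.1


@dataclass
class ExpressionMatrix:
    """Genes x samples RPKM matrix with tissue-group labels per sample.

    ``zscore`` is populated by :func:`zscore_rows`; ``rpkm`` rows index by
    gene_id and columns by sample_id.
    """

    rpkm: pd.DataFrame
    tissue_group: pd.Series  # sample_id -> group label
    gene_length_bp: pd.Series  # gene_id -> length
    library_size: pd.Series  # sample_id -> mapped reads
    zscore: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.rpkm.columns.equals(self.tissue_group.index):
            self.tissue_group = self.tissue_group.reindex(self.rpkm.columns)
        if self.tissue_group.isna().any():
            missing = list(self.tissue_group[self.tissue_group.isna()].index)
            raise ValueError(f"samples without tissue group: {missing}")
        if (self.rpkm.values < 0).any():
            raise ValueError("negative RPKM values")

    def samples_in_group(self, group: str) -> list[str]:
        hits = list(self.tissue_group[self.tissue_group == group].index)
        if not hits:
            raise ValueError(f"no samples in tissue group {group!r}")
        return hits


@dataclass
class EnrichmentLabel:
    """Per-gene fold change between two tissue groups and its call."""

    gene_id: str
    fold_change: float
    label: str  # enriched | depleted | unchanged


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads-per-kilobase-per-million normalization of a counts matrix.

    ``library_sizes`` defaults to per-sample column sums. Zero gene lengths or
    library sizes are errors.
    """
    gene_lengths = gene_lengths.reindex(counts.index)
    if gene_lengths.isna().any() or (gene_lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    kb = gene_lengths.values[:, None] / 1e3
    millions = library_sizes.values[None, :] / 1e6
    return pd.DataFrame(
        counts.values / (kb * millions), index=counts.index, columns=counts.columns
    )


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Populate per-gene z-scores across samples (sample sd, ddof = 1).

    Constant rows (sd 0) become all-zero rows; a warning is logged.
    """
    x = m.rpkm.values.astype(float)
    if x.shape[1] < 2:
        raise ValueError("z-scores require >= 2 samples")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        logger.warning("%d constant expression rows z-scored to zero", int(const.sum()))
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    z[const, :] = 0.0
    m.zscore = pd.DataFrame(z, index=m.rpkm.index, columns=m.rpkm.columns)
    return m


def classify_enrichment(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fold_threshold: float = 2.0,
    pseudocount: float = FOLD_PSEUDOCOUNT_RPKM,
) -> list[EnrichmentLabel]:
    """Call each gene enriched/depleted/unchanged in group A relative to B.

    fold = (mean_A + eps) / (mean_B + eps); ``fold >= threshold`` -> enriched,
    ``fold <= 1/threshold`` -> depleted, else unchanged. Thresholds are
    inclusive ("at least N-fold").
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    a = m.rpkm[m.samples_in_group(group_a)].mean(axis=1)
    b = m.rpkm[m.samples_in_group(group_b)].mean(axis=1)
    fold = (a + pseudocount) / (b + pseudocount)
    out = []
    for gene_id, f in fold.items():
        if f >= fold_threshold:
            label = "enriched"
        elif f <= 1.0 / fold_threshold:
            label = "depleted"
        else:
            label = "unchanged"
        out.append(EnrichmentLabel(gene_id=gene_id, fold_change=float(f), label=label))
    return out


def hierarchical_order(
    m: ExpressionMatrix, gene_subset: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Leaf order and linkage of agglomerative clustering on z-score rows.

    Euclidean distance, average linkage; deterministic given input order.
    Returns (ordered gene ids, scipy linkage matrix).
    """
    if m.zscore is None:
        m = zscore_rows(m)
    z = m.zscore if gene_subset is None else m.zscore.loc[gene_subset]
    if len(z) < 2:
        raise ValueError("hierarchical ordering needs >= 2 genes")
    linkage = average(pdist(z.values, metric="euclidean"))
    order = [z.index[i] for i in leaves_list(linkage)]
    return order, linkage
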