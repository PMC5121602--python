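"""Directed TF -> target regulatory network from chromatin-association gene
sets, co-bound peaks, acetylation dependence, and expression labels.

Edges are binary regulatory-potential links: regulator R -> target gene G
whenever G is in R's chromatin-associated gene set and passes the target
filters (by default: G encodes a transcription factor and shows
embryonic-CNS-enriched expression). Node attributes record TF status, the
CNS-enrichment label, and knockdown-sensitive acetylation; edge attributes
record the supporting peaks and whether the site is co-bound by a second
factor.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .annotation import GenomeAnnotation, nearest_tss
from .intervals import IntervalSet, intersect
from .peaks import PeakSet

__all__ = [
    "GeneSetCatalog",
    "GRNFilters",
    "build_grn",
    "cobound_targets",
    "shared_target_summary",
    "export_grn",
    "import_edge_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCatalog:
    """Factor name -> associated gene set, with per-set provenance.

    Provenance is ``"chip"`` for sets derived from an in-package nearest-TSS
    run and ``"imported"`` for externally published gene lists.
    """

    sets: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, factor: str, genes: set[str], provenance: str = "chip") -> None:
        self.sets[factor] = set(genes)
        self.provenance[factor] = provenance

    def factors(self) -> list[str]:
        return sorted(self.sets)


@dataclass
class GRNFilters:
    """Target admission rules for network edges."""

    require_tf: bool = True
    require_cns_enriched: bool = True


def build_grn(
    catalog: GeneSetCatalog,
    tf_list: set[str],
    enrichment_labels: dict[str, str],
    acetylation_genes: set[str] = frozenset(),
    cobound_genes: set[str] = frozenset(),
    filters: GRNFilters | None = None,
) -> nx.DiGraph:
    """Edge regulator -> target for every catalog gene passing the filters.

    ``enrichment_labels`` maps gene_id -> {enriched, depleted, unchanged}
    (group A = embryonic CNS vs group B = ES). Candidate targets without a
    label are skipped with a warning. Output node/edge ordering is
    deterministic (sorted insertion).
    """
    if not catalog.sets:
        raise ValueError("empty gene-set catalog")
    if filters is None:
        filters = GRNFilters()
    g = nx.DiGraph()
    n_unlabelled = 0
    for factor in catalog.factors():
        for gene in sorted(catalog.sets[factor]):
            label = enrichment_labels.get(gene)
            if label is None:
                n_unlabelled += 1
                continue
            if filters.require_tf and gene not in tf_list:
                continue
            if filters.require_cns_enriched and label != "enriched":
                continue
            for node in (factor, gene):
                if node not in g:
                    g.add_node(
                        node,
                        is_TF=node in tf_list or node in catalog.sets,
                        CNS_label=enrichment_labels.get(node, "unknown"),
                        acetylation_dependent=node in acetylation_genes,
                    )
            if g.has_edge(factor, gene):
                continue
            g.add_edge(
                factor, gene,
                co_bound=gene in cobound_genes,
                provenance=catalog.provenance.get(factor, "chip"),
            )
    if n_unlabelled:
        logger.warning("%d candidate targets skipped: no enrichment label", n_unlabelled)
    return g


def cobound_targets(
    peaks_a: PeakSet, peaks_b: PeakSet, annotation: GenomeAnnotation
) -> tuple[set[str], IntervalSet]:
    """Genes nearest to peaks where both factors bind.

    Peak-level intersection (>= 1 bp) of A against B, then nearest-TSS
    assignment of the intersecting peaks. Returns (gene set, intersecting
    peaks of A).
    """
    if peaks_a.condition != peaks_b.condition:
        raise ValueError(
            f"condition mismatch: {peaks_a.condition!r} vs {peaks_b.condition!r}"
        )
    shared = intersect(peaks_a.intervals, peaks_b.intervals, min_overlap_bp=1)
    genes = {
        asg.gene_id
        for asg in nearest_tss(shared, annotation)
        if asg.gene_id is not None
    }
    return genes, shared


def shared_target_summary(catalog: GeneSetCatalog) -> pd.DataFrame:
    """Per-gene factor-membership bit vector plus combination counts.

    Returns a DataFrame indexed by gene_id with one boolean column per factor
    and a ``combination`` column (e.g. ``"factorA+factorB"``); combination
    counts sum to the size of the union of all sets.
    """
    factors = catalog.factors()
    if len(factors) < 2:
        raise ValueError("shared-target summary needs >= 2 factors")
    union = sorted(set().union(*catalog.sets.values()))
    rows = []
    for gene in union:
        bits = {f: gene in catalog.sets[f] for f in factors}
        bits["combination"] = "+".join(f for f in factors if bits[f])
        rows.append(bits)
    return pd.DataFrame(rows, index=pd.Index(union, name="gene_id"))


EDGE_TSV_COLUMNS = (
    "regulator", "target", "co_bound", "provenance",
    "target_CNS_label", "target_acetylation_flag",
)


def export_grn(grn: nx.DiGraph, path: str | Path, fmt: str = "edge_tsv") -> None:
    """Write the network as edge TSV, GraphML, or DOT."""
    path = Path(path)
    if fmt == "edge_tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(EDGE_TSV_COLUMNS)
            for u, v, data in sorted(grn.edges(data=True)):
                nd = grn.nodes[v]
                w.writerow([
                    u, v, int(data.get("co_bound", False)),
                    data.get("provenance", "chip"),
                    nd.get("CNS_label", "unknown"),
                    int(nd.get("acetylation_dependent", False)),
                ])
    elif fmt == "graphml":
        nx.write_graphml(grn, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph GRN {\n")
            for n, data in sorted(grn.nodes(data=True)):
                attrs = ",".join(f'{k}="{v}"' for k, v in sorted(data.items()))
                fh.write(f'  "{n}" [{attrs}];\n')
            for u, v, data in sorted(grn.edges(data=True)):
                attrs = ",".join(f'{k}="{v}"' for k, v in sorted(data.items()))
                fh.write(f'  "{u}" -> "{v}" [{attrs}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_edge_tsv(path: str | Path) -> nx.DiGraph:
    """Rebuild a GRN from its edge-TSV export (inverse of ``export_grn``)."""
    g = nx.DiGraph()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            reg, tgt = row["regulator"], row["target"]
            if reg not in g:
                g.add_node(reg, is_TF=True, CNS_label="unknown",
                           acetylation_dependent=False)
            g.add_node(
                tgt,
                is_TF=g.nodes[tgt]["is_TF"] if tgt in g else True,
                CNS_label=row["target_CNS_label"],
                acetylation_dependent=bool(int(row["target_acetylation_flag"])),
            )
            g.add_edge(
                reg, tgt,
                co_bound=bool(int(row["co_bound"])),
                provenance=row["provenance"],
            )
    return g
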