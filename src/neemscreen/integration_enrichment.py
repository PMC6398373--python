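"""Consolidation of the two arms, pathway over-representation, drug network.

Gene lists from the expression time course and the shRNA screen are merged
into one non-redundant, provenance-flagged list; pathways are tested for
over-representation with the exact hypergeometric upper tail and
Benjamini-Hochberg FDR control; finally a gene-gene / drug-target network
is assembled over the consolidated genes and the enriched pathways' overlap
genes. The enrichment here is a local ORA: the original analysis used
external web resources whose statistics and backgrounds are not
reproducible offline, so the universe is an explicit, logged parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, ValidationError
from .io_formats import PathwayGeneSet, write_json
from .screen_pipeline import GeneHit

logger = logging.getLogger("neemscreen")

EDGE_TYPES = ("gene-gene", "drug-target")

#: provenance flags a consolidated gene may carry
PROVENANCE_FLAGS = ("expression_serial", "expression_non_rescued",
                    "shrna_up", "shrna_down")


@dataclass
class ConsolidatedGeneList:
    """Non-redundant union of both arms' hits, sorted, with provenance flags."""

    genes: tuple[str, ...]
    provenance: dict[str, frozenset[str]]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("consolidated gene list contains duplicates")
        for gene in self.genes:
            flags = self.provenance.get(gene, frozenset())
            if not flags:
                raise ValidationError(f"gene {gene!r} carries no provenance flag")
            if unknown := flags - set(PROVENANCE_FLAGS):
                raise ValidationError(f"unknown provenance flags {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's over-representation result.

    k of the n query genes fall in a pathway of size K within a universe of
    N genes; p is the exact hypergeometric upper tail P(X >= k), fdr its
    Benjamini-Hochberg adjusted value.
    """

    pathway: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float
    overlap_genes: frozenset[str]


def harmonize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Consolidation
# ---------------------------------------------------------------------------

def consolidate_gene_lists(expression_hits: Iterable[str],
                           shrna_hits: Iterable[GeneHit],
                           non_rescued_hits: Iterable[str] = (),
                           ) -> ConsolidatedGeneList:
    """Union both arms into a sorted, deduplicated gene list with provenance.

    ``expression_hits`` are the serially-regulated genes, ``non_rescued_hits``
    the flat-after-withdrawal genes, and ``shrna_hits`` the gene-level screen
    calls (direction up/down becomes the shrna_up/shrna_down flag). Symbols
    are case-folded and whitespace-stripped before the union. An empty union
    yields an empty list with a warning, not an error.
    """
    prov: dict[str, set[str]] = {}

    def add(gene: str, flag: str) -> None:
        prov.setdefault(harmonize_symbol(gene), set()).add(flag)

    for gene in expression_hits:
        add(gene, "expression_serial")
    for gene in non_rescued_hits:
        add(gene, "expression_non_rescued")
    for hit in shrna_hits:
        add(hit.gene, "shrna_up" if hit.direction == "up" else "shrna_down")
    prov.pop("", None)
    if not prov:
        logger.warning("consolidation produced an empty gene list")
    return ConsolidatedGeneList(
        genes=tuple(sorted(prov)),
        provenance={g: frozenset(f) for g, f in prov.items()},
    )


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def hypergeometric_enrichment(query: ConsolidatedGeneList | Iterable[str],
                              gene_sets: Sequence[PathwayGeneSet],
                              universe: Iterable[str], *,
                              unique_assignment: bool = False,
                              ) -> list[EnrichmentRecord]:
    """Exact hypergeometric over-representation of the query in each gene set.

    Query genes outside the universe are dropped with a warning; each gene
    set is intersected with the universe before testing. With
    ``unique_assignment``, each query gene counts only toward the smallest
    pathway containing it (ties broken by name), mimicking a
    signature-genes-must-be-unique analysis mode. Records are sorted by
    p-value; BH adjustment runs across every tested set.
    """
    universe_set = {harmonize_symbol(g) for g in universe}
    if not universe_set:
        raise ConfigurationError("empty gene universe")
    genes = query.genes if isinstance(query, ConsolidatedGeneList) else tuple(query)
    query_set = {harmonize_symbol(g) for g in genes}
    dropped = query_set - universe_set
    if dropped:
        logger.warning("%d query genes outside the universe dropped: %s",
                       len(dropped), sorted(dropped)[:5])
    query_set &= universe_set
    N, n = len(universe_set), len(query_set)

    trimmed = [(gs.name, frozenset(harmonize_symbol(g) for g in gs.genes) & universe_set)
               for gs in gene_sets]
    trimmed = [(name, members) for name, members in trimmed if members]

    if unique_assignment:
        owner: dict[str, str] = {}
        for name, members in sorted(trimmed, key=lambda t: (len(t[1]), t[0])):
            for g in members:
                owner.setdefault(g, name)
        trimmed = [
            (name, frozenset(g for g in members
                             if g not in query_set or owner[g] == name))
            for name, members in trimmed
        ]
        trimmed = [(name, members) for name, members in trimmed if members]

    records = []
    for name, members in trimmed:
        K = len(members)
        overlap = frozenset(members & query_set)
        k = len(overlap)
        # exact upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        records.append((name, k, K, overlap, min(p, 1.0)))
    records.sort(key=lambda r: (r[4], r[0]))
    fdrs = bh_fdr([r[4] for r in records])
    return [
        EnrichmentRecord(pathway=name, k=k, K=K, n=n, N=N,
                         p_value=p, fdr=fdr, overlap_genes=overlap)
        for (name, k, K, overlap, p), fdr in zip(records, fdrs)
    ]


def expand_gene_sets_with_interactors(gene_sets: Sequence[PathwayGeneSet],
                                      interactions: pd.DataFrame,
                                      ) -> list[PathwayGeneSet]:
    """Add first-degree interaction neighbors to each gene set (an
    include-interactors analysis mode over a user-supplied interaction table)."""
    neighbors: dict[str, set[str]] = {}
    for row in interactions.itertuples(index=False):
        a, b = harmonize_symbol(row.gene_a), harmonize_symbol(row.gene_b)
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    out = []
    for gs in gene_sets:
        extra: set[str] = set()
        for g in gs.genes:
            extra |= neighbors.get(harmonize_symbol(g), set())
        out.append(PathwayGeneSet(name=gs.name, description=gs.description,
                                  genes=frozenset(gs.genes) | extra))
    return out


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def build_network(query: ConsolidatedGeneList,
                  enriched: Sequence[EnrichmentRecord],
                  interactions: pd.DataFrame | None = None,
                  drugs: pd.DataFrame | None = None,
                  extra_genes: Iterable[str] = ()) -> nx.Graph:
    """Assemble the gene-gene / drug-target network.

    Nodes are the query genes, the enriched pathways' overlap genes, and any
    user-supplied extra genes (e.g. a most-altered-genes list from an external
    cohort). Gene-gene edges are filtered to the node-induced subgraph; drug
    nodes attach to their targets with FDA-approval and trial-count
    annotations. Unknown symbols in the tables are ignored with a logged count.
    """
    graph = nx.Graph()
    query_set = set(query.genes)
    nodes = set(query_set)
    for rec in enriched:
        nodes |= set(rec.overlap_genes)
    nodes |= {harmonize_symbol(g) for g in extra_genes}
    nodes.discard("")
    for gene in sorted(nodes):
        graph.add_node(gene, kind="gene", is_query=gene in query_set,
                       is_drug_target=False,
                       alteration_annotation=";".join(
                           sorted(query.provenance.get(gene, ()))))

    skipped = 0
    if interactions is not None:
        for row in interactions.itertuples(index=False):
            a, b = harmonize_symbol(row.gene_a), harmonize_symbol(row.gene_b)
            if a in nodes and b in nodes and a != b:
                graph.add_edge(a, b, edge_type="gene-gene",
                               interaction=getattr(row, "type", "interaction"))
            else:
                skipped += 1
    if drugs is not None:
        for row in drugs.itertuples(index=False):
            target = harmonize_symbol(row.target)
            if target not in nodes:
                skipped += 1
                continue
            drug_node = f"drug:{row.drug}"
            graph.add_node(drug_node, kind="drug", is_query=False,
                           is_drug_target=False, alteration_annotation="",
                           fda_approved=bool(row.fda_approved),
                           n_trials=int(row.n_trials))
            graph.add_edge(drug_node, target, edge_type="drug-target",
                           fda_approved=bool(row.fda_approved),
                           n_trials=int(row.n_trials))
            graph.nodes[target]["is_drug_target"] = True
    if skipped:
        logger.info("network assembly ignored %d table rows with unknown symbols",
                    skipped)
    return graph


def network_summary(graph: nx.Graph) -> dict:
    """Node/edge tallies plus the fraction of edges that are drug-target type."""
    n_drug_edges = sum(1 for *_, d in graph.edges(data=True)
                       if d.get("edge_type") == "drug-target")
    n_edges = graph.number_of_edges()
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_gene_nodes": sum(1 for _, d in graph.nodes(data=True)
                            if d.get("kind") == "gene"),
        "n_drug_nodes": sum(1 for _, d in graph.nodes(data=True)
                            if d.get("kind") == "drug"),
        "n_edges": n_edges,
        "n_drug_edges": n_drug_edges,
        "drug_edge_fraction": n_drug_edges / n_edges if n_edges else 0.0,
    }


def write_network(graph: nx.Graph, out_dir) -> None:
    """GraphML plus node/edge TSVs and a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, out_dir / "network.graphml")
    nodes = pd.DataFrame(
        [{"node": n, **d} for n, d in graph.nodes(data=True)]
    ).fillna("")
    nodes.to_csv(out_dir / "network_nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [{"source": a, "target": b, **d} for a, b, d in graph.edges(data=True)]
    )
    edges.to_csv(out_dir / "network_edges.tsv", sep="\t", index=False)
    write_json(out_dir / "network_summary.json", network_summary(graph))


def enrichment_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"pathway": r.pathway, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
         "p_value": r.p_value, "fdr": r.fdr,
         "overlap_genes": ",".join(sorted(r.overlap_genes))}
        for r in records
    ])


# ---------------------------------------------------------------------------
# Bundled demonstration gene sets
# ---------------------------------------------------------------------------

def example_gene_sets() -> list[PathwayGeneSet]:
    """Small synthetic stand-in pathway definitions for demos and tests.

    Built from published member lists of the TGF-beta signaling and HSF-1
    heat-shock pathways; they are fixtures for exercising the enrichment
    machinery end-to-end, not claims about any pathway database's true
    definitions.
    """
    return [
        PathwayGeneSet(
            name="TGF_BETA_SIGNALING",
            description="synthetic stand-in: TGF-beta signaling members",
            genes=frozenset({"SPHK1", "DDIT3", "RGS16", "LRRC15", "VDR",
                             "TGIF1", "GABARAPL1", "DUSP1", "CITED2", "PTGS2",
                             "HBEGF", "GADD45B", "RHOB", "PIM1", "HMOX1",
                             "DDIT4", "MIR21", "TIMP3", "EMP1"}),
        ),
        PathwayGeneSet(
            name="HSF1_ACTIVATION",
            description="synthetic stand-in: HSF-1 activation members",
            genes=frozenset({"DNAJB1", "HSPA1L", "HSPA1A", "DEDD2",
                             "RPA1", "RPA2", "BAG3", "PLK1", "SPHK1"}),
        ),
        PathwayGeneSet(
            name="HSF1_DEPENDENT_TRANSACTIVATION",
            description="synthetic stand-in: HSF-1-dependent transactivation members",
            genes=frozenset({"DNAJB1", "HSPA1L", "HSPA1A", "DEDD2", "HSPB8"}),
        ),
    ]
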