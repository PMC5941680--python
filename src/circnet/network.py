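"""Tripartite circRNA-miRNA-mRNA (ceRNA) network assembly.

Two stringency tiers are supported:

* **low** — circRNA-miRNA pairs predicted by both site predictors with a
  match score >= 150, joined to the miRNA-mRNA pairs shared by the two target
  databases, genes restricted to those differentially expressed at
  uncorrected p < 0.05;
* **high** — match score >= 180 and genes additionally at |log2FC| >= 2.

After the gene filter, miRNAs without a surviving gene are pruned, then
circRNAs without a surviving miRNA; statistics are recomputed after pruning,
so every gene node is reachable from a circRNA through a miRNA. circ-mir
edges are weighted by the number of predicted binding sites, mir-gene edges
have unit weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

LOW, HIGH = "low", "high"

#: Default thresholds per tier: (min match score, max DE p, min |log2FC|)
TIER_THRESHOLDS = {
    LOW: (150.0, 0.05, 0.0),
    HIGH: (180.0, 0.05, 2.0),
}


@dataclass
class DEGRecord:
    gene: str
    log2fc: float
    pvalue: float

    def __post_init__(self) -> None:
        self.gene = self.gene.strip().upper()
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"{self.gene}: p-value {self.pvalue} outside [0, 1]")


@dataclass
class InteractionEdge:
    source: str
    target: str
    layer: str  # "circ-mir" | "mir-gene"
    weight: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("edge weight must be >= 1")


@dataclass
class TripartiteNetwork:
    stringency: str
    circrnas: Set[str] = field(default_factory=set)
    mirnas: Set[str] = field(default_factory=set)
    genes: Set[str] = field(default_factory=set)
    edges: List[InteractionEdge] = field(default_factory=list)

    @property
    def stats(self) -> Dict[str, int]:
        return {
            "circRNAs": len(self.circrnas),
            "miRNAs": len(self.mirnas),
            "genes": len(self.genes),
            "edges": len(self.edges),
        }

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph(stringency=self.stringency)
        for n in sorted(self.circrnas):
            g.add_node(n, layer="circRNA")
        for n in sorted(self.mirnas):
            g.add_node(n, layer="miRNA")
        for n in sorted(self.genes):
            g.add_node(n, layer="gene")
        for e in self.edges:
            g.add_edge(e.source, e.target, layer=e.layer, weight=e.weight,
                       provenance=e.provenance)
        return g


def _norm_mirna(m: str) -> str:
    return m.strip().lower()


def _norm_gene(g: str) -> str:
    return g.strip().upper()


def read_target_db(path) -> Set[Tuple[str, str]]:
    """Read a miRNA-mRNA target TSV (mirna_id, gene_id[, source])."""
    pairs: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValueError(f"{path}:{ln}: expected >= 2 fields")
            if ln == 1 and f[0].lower() in ("mirna", "mirna_id"):
                continue
            pairs.add((_norm_mirna(f[0]), _norm_gene(f[1])))
    return pairs


def intersect_target_dbs(db1, db2) -> Set[Tuple[str, str]]:
    """Exact (miRNA, gene) pairs present in both databases, case-normalized."""
    a = db1 if isinstance(db1, set) else read_target_db(db1)
    b = db2 if isinstance(db2, set) else read_target_db(db2)
    a = {(_norm_mirna(m), _norm_gene(g)) for m, g in a}
    b = {(_norm_mirna(m), _norm_gene(g)) for m, g in b}
    return a & b


def read_de_table(path) -> List[DEGRecord]:
    """Read a differential-expression TSV (gene, log2FC, pvalue)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 fields")
            if ln == 1 and f[0].lower() in ("gene", "gene_id"):
                continue
            out.append(DEGRecord(f[0], float(f[1]), float(f[2])))
    return out


def build_network(
    pairs: Sequence,
    mirna_gene: Iterable[Tuple[str, str]],
    degs: Sequence[DEGRecord],
    stringency: str,
    score_threshold: Optional[float] = None,
    p_cutoff: Optional[float] = None,
    lfc_cutoff: Optional[float] = None,
) -> TripartiteNetwork:
    """Assemble one stringency tier of the ceRNA network.

    ``pairs`` are circRNA-miRNA predictions (objects with ``circ_id``,
    ``mirna_id``, ``n_sites``, ``best_score`` and ``predicted_by_both``, e.g.
    :class:`~circnet.targets.PairPrediction` or equivalent rows). Explicit
    threshold arguments override the tier defaults.
    """
    if stringency not in TIER_THRESHOLDS:
        raise ValueError(f"unknown stringency {stringency!r}; use 'low' or 'high'")
    d_score, d_p, d_lfc = TIER_THRESHOLDS[stringency]
    score_threshold = d_score if score_threshold is None else score_threshold
    p_cutoff = d_p if p_cutoff is None else p_cutoff
    lfc_cutoff = d_lfc if lfc_cutoff is None else lfc_cutoff

    de_pass = {
        d.gene
        for d in degs
        if d.pvalue < p_cutoff and abs(d.log2fc) >= lfc_cutoff
    }
    targets_by_mirna: Dict[str, Set[str]] = {}
    for m, g in mirna_gene:
        targets_by_mirna.setdefault(_norm_mirna(m), set()).add(_norm_gene(g))

    net = TripartiteNetwork(stringency=stringency)
    circ_mir: List[Tuple[str, str, float]] = []
    for p in pairs:
        if p.best_score < score_threshold or not p.predicted_by_both:
            continue
        circ_mir.append((p.circ_id, _norm_mirna(p.mirna_id), max(1, p.n_sites)))

    # gene filter, then prune miRNAs, then prune circRNAs
    mir_genes: Dict[str, Set[str]] = {}
    for _, mirna, _ in circ_mir:
        genes = targets_by_mirna.get(mirna, set()) & de_pass
        if genes:
            mir_genes[mirna] = genes
    kept_pairs = [(c, m, w) for c, m, w in circ_mir if m in mir_genes]

    for c, m, w in kept_pairs:
        net.circrnas.add(c)
        net.mirnas.add(m)
        net.edges.append(InteractionEdge(c, m, "circ-mir", w, "site_prediction"))
    for m in sorted(mir_genes):
        if m not in net.mirnas:
            continue
        for g in sorted(mir_genes[m]):
            net.genes.add(g)
            net.edges.append(InteractionEdge(m, g, "mir-gene", 1, "db_intersection"))
    return net


def network_from_edge_table(path=None, stringency: str = HIGH) -> TripartiteNetwork:
    """Build a network directly from a circ/mirna/sites/genes edge table.

    With no path, loads the bundled reference high-stringency edge table for
    posterior-cingulate astrocytes (circRNA, miRNA, predicted binding sites,
    differentially expressed target genes).
    """
    if path is None:
        ref = resources.files("circnet").joinpath("data/high_stringency_network.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    net = TripartiteNetwork(stringency=stringency)
    for row in df.itertuples(index=False):
        circ = str(row.circ_id)
        mirna = _norm_mirna(str(row.mirna_id))
        net.circrnas.add(circ)
        net.mirnas.add(mirna)
        net.edges.append(
            InteractionEdge(circ, mirna, "circ-mir", int(row.n_binding_sites),
                            "site_prediction")
        )
        for g in str(row.target_genes).split(";"):
            g = _norm_gene(g)
            if not g:
                continue
            net.genes.add(g)
            edge = InteractionEdge(mirna, g, "mir-gene", 1, "db_intersection")
            if not any(
                e.source == mirna and e.target == g for e in net.edges
            ):
                net.edges.append(edge)
    return net


def export_network(net: TripartiteNetwork, sif_path=None, graphml_path=None,
                   stats_path=None) -> None:
    """Write SIF ('binds'/'targets' relations), GraphML and stats JSON."""
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for e in net.edges:
                rel = "binds" if e.layer == "circ-mir" else "targets"
                fh.write(f"{e.source}\t{rel}\t{e.target}\n")
    if graphml_path is not None:
        nx.write_graphml(net.to_graph(), graphml_path)
    if stats_path is not None:
        with open(stats_path, "w") as fh:
            json.dump(net.stats, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_graphml(path) -> TripartiteNetwork:
    """Re-import a GraphML export (round-trips node and edge sets)."""
    g = nx.read_graphml(path)
    net = TripartiteNetwork(stringency=g.graph.get("stringency", "low"))
    for n, attrs in g.nodes(data=True):
        layer = attrs.get("layer")
        if layer == "circRNA":
            net.circrnas.add(n)
        elif layer == "miRNA":
            net.mirnas.add(n)
        elif layer == "gene":
            net.genes.add(n)
    for u, v, attrs in g.edges(data=True):
        net.edges.append(
            InteractionEdge(u, v, attrs.get("layer", ""),
                            attrs.get("weight", 1), attrs.get("provenance", ""))
        )
    return net
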