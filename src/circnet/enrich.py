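"""Pathway enrichment and circRNA differential expression.

Enrichment is a one-sided hypergeometric test per gene set (the classic
over-representation analysis): with a universe of N genes, K of which belong
to the pathway, and an input list of n genes containing k pathway members,

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

followed by Benjamini-Hochberg adjustment across pathways. The default
universe is the full gene list of the differential-expression table.

CircRNA-level differential expression between the two groups uses a
two-sided, equal-variance Student's t-test on per-sample junction read
counts (Welch available behind a flag); counts are used raw, appropriate for
depth-matched libraries, with an optional library-size normalization for
unmatched data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    pathway: str
    k: int  # input genes in pathway
    K: int  # pathway size (within universe)
    n: int  # input list size
    N: int  # universe size
    pvalue: float
    fdr: float

    @property
    def ratio_string(self) -> str:
        return f"{self.k}/{self.K}"


@dataclass
class CircDEResult:
    circ_id: str
    mean_a: float
    mean_b: float
    t_statistic: float
    pvalue: float
    log2fc: float


def parse_gmt(path) -> Dict[str, Tuple[str, List[str]]]:
    """Read a GMT file into {pathway: (description, member genes)}."""
    out: Dict[str, Tuple[str, List[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, desc, >=1 gene")
            out[f[0]] = (f[1], [g.strip().upper() for g in f[2:] if g.strip()])
    return out


def write_gmt(path, gene_sets: Mapping[str, Tuple[str, Sequence[str]]]) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in gene_sets.items():
            fh.write(name + "\t" + desc + "\t" + "\t".join(genes) + "\n")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k]."""
    if N <= 0:
        raise ValueError("universe size must be positive")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    input_genes: Iterable[str],
    gene_sets: Mapping[str, Tuple[str, Sequence[str]]],
    universe: Iterable[str],
    fdr_cutoff: float = 0.01,
    return_all: bool = False,
) -> List[EnrichmentResult]:
    """Over-representation analysis of an input gene list against gene sets.

    Pathways and the input list are intersected with the universe before
    counting. Results are BH-adjusted across all tested pathways, sorted by
    FDR ascending (pathway name breaking ties) and, unless ``return_all``,
    filtered to ``fdr < fdr_cutoff``.
    """
    uni = {g.strip().upper() for g in universe}
    if not uni:
        raise ValueError("empty gene universe")
    if not gene_sets:
        return []
    inp = {g.strip().upper() for g in input_genes} & uni
    N, n = len(uni), len(inp)

    names, pvals, counts = [], [], []
    for name in sorted(gene_sets):
        _, members = gene_sets[name]
        pathway = set(members) & uni
        K = len(pathway)
        if K == 0:
            continue
        k = len(pathway & inp)
        names.append(name)
        counts.append((k, K))
        pvals.append(hypergeom_pvalue(k, K, n, N))
    if not names:
        return []
    fdrs = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(name, k, K, n, N, p, fdr)
        for name, (k, K), p, fdr in zip(names, counts, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.pvalue, r.pathway))
    if not return_all:
        results = [r for r in results if r.fdr < fdr_cutoff]
    return results


def circ_de_test(
    candidates: Sequence,
    sample_groups: Mapping[str, str],
    min_per_group: int = 2,
    equal_var: bool = True,
    normalize: bool = False,
) -> Tuple[List[CircDEResult], List[Tuple[str, str]]]:
    """Per-candidate two-sample t-test between the two cohort groups.

    A candidate is tested only when it was detected (called with reads) in at
    least ``min_per_group`` samples of each group; skipped candidates are
    returned with a reason. The count vectors cover every cohort sample, with
    0 for samples where the candidate was not called. log2 fold change uses a
    pseudo-count of 1 on the group means, oriented first-group over second
    (groups ordered alphabetically, e.g. AD over ND).
    """
    groups = sorted(set(sample_groups.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    samples_a = sorted(s for s, g in sample_groups.items() if g == ga)
    samples_b = sorted(s for s, g in sample_groups.items() if g == gb)

    size_factor = {s: 1.0 for s in sample_groups}
    if normalize:
        totals = {s: 0.0 for s in sample_groups}
        for c in candidates:
            for s, r in c.per_sample_reads.items():
                if s in totals:
                    totals[s] += r
        ref = np.median([t for t in totals.values() if t > 0] or [1.0])
        size_factor = {s: (t / ref if t > 0 else 1.0) for s, t in totals.items()}

    results: List[CircDEResult] = []
    skipped: List[Tuple[str, str]] = []
    for c in candidates:
        det_a = sum(1 for s in samples_a if s in c.per_sample_reads)
        det_b = sum(1 for s in samples_b if s in c.per_sample_reads)
        if det_a < min_per_group or det_b < min_per_group:
            skipped.append(
                (c.id, f"detected in {det_a} {ga} / {det_b} {gb} samples; "
                       f"need >= {min_per_group} per group")
            )
            continue
        xa = np.array(
            [c.per_sample_reads.get(s, 0) / size_factor[s] for s in samples_a],
            dtype=float,
        )
        xb = np.array(
            [c.per_sample_reads.get(s, 0) / size_factor[s] for s in samples_b],
            dtype=float,
        )
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        if math.isnan(t):  # both groups constant and identical
            t, p = 0.0, 1.0
        results.append(
            CircDEResult(
                circ_id=c.id,
                mean_a=float(xa.mean()),
                mean_b=float(xb.mean()),
                t_statistic=float(t),
                pvalue=float(p),
                log2fc=float(np.log2((xa.mean() + 1.0) / (xb.mean() + 1.0))),
            )
        )
    return results, skipped


def write_enrichment_table(path, results: Sequence[EnrichmentResult]) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tratio\tpvalue\tfdr\n")
        for r in results:
            fh.write(f"{r.pathway}\t{r.ratio_string}\t{r.pvalue:.6g}\t{r.fdr:.6g}\n")


def write_circde_table(path, results: Sequence[CircDEResult]) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tmean_a\tmean_b\tt_statistic\tpvalue\tlog2fc\n")
        for r in results:
            fh.write(
                f"{r.circ_id}\t{r.mean_a:.4f}\t{r.mean_b:.4f}"
                f"\t{r.t_statistic:.4f}\t{r.pvalue:.6g}\t{r.log2fc:.4f}\n"
            )
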