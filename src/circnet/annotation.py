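"""Classify back-splice candidates against gene models.

A candidate is *exonic* when both back-splice boundaries fall inside exons of
a single transcript, *intronic* when it overlaps a gene body without meeting
the exonic rule, and *intergenic* otherwise. When several transcripts give
conflicting classes the most specific wins (exonic > intronic), and
``exons_spanned`` is taken from the transcript that maximizes it. A boundary
need not coincide with an annotated exon edge.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .callers import CircRNACandidate
from .models import Transcript


@dataclass
class AnnotatedCircRNA:
    candidate: CircRNACandidate
    region_class: str  # exonic | intronic | intergenic
    in_cds: bool
    exons_spanned: int
    host_genes: List[str]
    transcript: Optional[Transcript] = None  # best exonic transcript, if any

    @property
    def length_bp(self) -> int:
        return self.candidate.end - self.candidate.start

    @property
    def id(self) -> str:
        return self.candidate.id


def _transcript_index(transcripts: Sequence[Transcript]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in transcripts:
        trees[t.chrom][t.start : t.end] = t
    return trees


def annotate(
    candidates: Sequence[CircRNACandidate],
    transcripts: Sequence[Transcript],
) -> List[AnnotatedCircRNA]:
    """Assign a region class, CDS status and exon span to every candidate.

    Candidates on chromosomes absent from the gene models are classified
    intergenic with a warning rather than an error. CDS status is true when
    every exonic base overlapped by the circle lies inside the transcript's
    thick (CDS) span, i.e. the circle touches no untranslated region.
    """
    trees = _transcript_index(transcripts)
    known_chroms = set(trees)
    out: List[AnnotatedCircRNA] = []
    warned: set = set()

    for cand in candidates:
        if cand.chrom not in known_chroms:
            if cand.chrom not in warned:
                warnings.warn(
                    f"chromosome {cand.chrom!r} absent from gene models; "
                    "candidates there are classified intergenic"
                )
                warned.add(cand.chrom)
            out.append(AnnotatedCircRNA(cand, "intergenic", False, 0, []))
            continue

        hits = [iv.data for iv in trees[cand.chrom][cand.start : cand.end]]
        best: Optional[Transcript] = None
        best_span = 0
        touching: List[Transcript] = []
        for t in hits:
            touching.append(t)
            if t.contains_in_exon(cand.start) and t.contains_in_exon(
                cand.end, as_end=True
            ):
                span = sum(
                    1 for s, e in t.exons if max(s, cand.start) < min(e, cand.end)
                )
                if span > best_span:
                    best, best_span = t, span

        if best is not None:
            overlap = best.exon_overlap(cand.start, cand.end)
            in_cds = all(
                best.thick_start <= s and e <= best.thick_end for s, e in overlap
            ) and best.thick_start < best.thick_end
            hosts = sorted(
                {
                    t.gene
                    for t in touching
                    if t.contains_in_exon(cand.start)
                    and t.contains_in_exon(cand.end, as_end=True)
                }
            )
            out.append(
                AnnotatedCircRNA(cand, "exonic", in_cds, best_span, hosts, best)
            )
        elif touching:
            hosts = sorted({t.gene for t in touching})
            out.append(AnnotatedCircRNA(cand, "intronic", False, 0, hosts))
        else:
            out.append(AnnotatedCircRNA(cand, "intergenic", False, 0, []))
    return out


def context_summary(annotated: Sequence[AnnotatedCircRNA]) -> dict:
    """Genomic-context summary: class proportions, sizes, exon spans.

    Exon-span bins follow the usual reporting convention (single exon, 2-6,
    7-15, 16-100, >100 exons). Empty input yields an empty summary.
    """
    if not annotated:
        return {
            "n": 0,
            "region_counts": {},
            "region_proportions": {},
            "per_chrom": {},
            "size_quantiles": {},
            "exon_span_histogram": {},
            "single_exon_fraction_of_exonic": None,
            "cds_fraction_of_exonic": None,
        }

    n = len(annotated)
    region_counts = Counter(a.region_class for a in annotated)
    per_chrom = Counter(a.candidate.chrom for a in annotated)
    lengths = np.array([a.length_bp for a in annotated])
    qs = np.quantile(lengths, [0.0, 0.25, 0.5, 0.75, 1.0])

    exonic = [a for a in annotated if a.region_class == "exonic"]
    span_bins = {"1": 0, "2-6": 0, "7-15": 0, "16-100": 0, ">100": 0}
    for a in exonic:
        k = a.exons_spanned
        if k == 1:
            span_bins["1"] += 1
        elif k <= 6:
            span_bins["2-6"] += 1
        elif k <= 15:
            span_bins["7-15"] += 1
        elif k <= 100:
            span_bins["16-100"] += 1
        else:
            span_bins[">100"] += 1

    return {
        "n": n,
        "region_counts": dict(region_counts),
        "region_proportions": {k: v / n for k, v in region_counts.items()},
        "per_chrom": dict(per_chrom),
        "size_quantiles": {
            "min": float(qs[0]),
            "q25": float(qs[1]),
            "median": float(qs[2]),
            "q75": float(qs[3]),
            "max": float(qs[4]),
        },
        "exon_span_histogram": span_bins,
        "single_exon_fraction_of_exonic": (
            span_bins["1"] / len(exonic) if exonic else None
        ),
        "cds_fraction_of_exonic": (
            sum(1 for a in exonic if a.in_cds) / len(exonic) if exonic else None
        ),
    }


def write_annotation_table(path, annotated: Sequence[AnnotatedCircRNA]) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tregion_class\tin_cds\texons_spanned\thost_genes\tlength_bp\n")
        for a in annotated:
            fh.write(
                f"{a.id}\t{a.region_class}\t{int(a.in_cds)}\t{a.exons_spanned}"
                f"\t{','.join(a.host_genes)}\t{a.length_bp}\n"
            )
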