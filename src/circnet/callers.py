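"""Harmonize back-splice junction calls from four circRNA prediction tools.

The four tools emit tab-separated tables in different dialects; the columns
retained here are the ones every downstream stage needs (coordinates, strand,
junction read support). Layouts, one record per line, no header:

``ciri``
    circRNA_ID (``chrom:start|end``, 1-based), chrom, start (1-based,
    inclusive), end (inclusive), junction_reads, strand
``circexplorer``
    chrom, start (0-based), end, name, junction_reads, strand
``find_circ``
    chrom, start (0-based), end, name, junction_reads, strand, n_uniq
``knife``
    junction id ``chrom|start|end|strand`` (0-based), junction_reads,
    posterior probability

CIRI's 1-based inclusive starts are decremented on parse so every record is
0-based half-open internally; candidate identity is the exact
``(chrom, start, end)`` triple after normalization. Strand is recorded but is
not part of the identity because not all dialects report it reliably.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

TOOLS = ("ciri", "circexplorer", "find_circ", "knife")


@dataclass(frozen=True)
class CallerRecord:
    tool: str
    sample_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+", "-" or "."
    junction_reads: int

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}; expected one of {TOOLS}")
        if self.start < 0:
            raise ValueError(f"negative start after normalization: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start >= end: {self.start} >= {self.end}")
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be >= 0")


@dataclass
class CircRNACandidate:
    chrom: str
    start: int
    end: int
    strand: str
    per_sample_reads: Dict[str, int] = field(default_factory=dict)
    tools_by_sample: Dict[str, Set[str]] = field(default_factory=dict)
    group_labels: Dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def tools(self) -> Set[str]:
        out: Set[str] = set()
        for ts in self.tools_by_sample.values():
            out |= ts
        return out

    @property
    def n_samples(self) -> int:
        return len(self.per_sample_reads)

    def groups_present(self) -> Set[str]:
        return {
            self.group_labels[s] for s in self.per_sample_reads if s in self.group_labels
        }


def _parse_int(value: str, path, ln: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"{path}:{ln}: bad {what} field {value!r}") from None


def parse_caller_file(path, tool: str, sample_id: str) -> List[CallerRecord]:
    """Parse one per-sample caller output file into normalized records.

    Malformed lines raise ``ValueError`` carrying the file path and the
    1-based line number.
    """
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    records: List[CallerRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if tool == "ciri":
                    if len(f) < 6:
                        raise ValueError(f"{path}:{ln}: expected 6 fields, got {len(f)}")
                    chrom = f[1]
                    start = _parse_int(f[2], path, ln, "start") - 1  # 1-based -> 0-based
                    end = _parse_int(f[3], path, ln, "end")
                    reads = _parse_int(f[4], path, ln, "junction_reads")
                    strand = f[5]
                elif tool in ("circexplorer", "find_circ"):
                    need = 6 if tool == "circexplorer" else 7
                    if len(f) < need:
                        raise ValueError(
                            f"{path}:{ln}: expected {need} fields, got {len(f)}"
                        )
                    chrom = f[0]
                    start = _parse_int(f[1], path, ln, "start")
                    end = _parse_int(f[2], path, ln, "end")
                    reads = _parse_int(f[4], path, ln, "junction_reads")
                    strand = f[5]
                else:  # knife
                    if len(f) < 3:
                        raise ValueError(f"{path}:{ln}: expected 3 fields, got {len(f)}")
                    parts = f[0].split("|")
                    if len(parts) != 4:
                        raise ValueError(f"{path}:{ln}: bad junction id {f[0]!r}")
                    chrom = parts[0]
                    start = _parse_int(parts[1], path, ln, "start")
                    end = _parse_int(parts[2], path, ln, "end")
                    strand = parts[3]
                    reads = _parse_int(f[1], path, ln, "junction_reads")
                if strand not in ("+", "-", "."):
                    raise ValueError(f"{path}:{ln}: bad strand {strand!r}")
                records.append(
                    CallerRecord(tool, sample_id, chrom, start, end, strand, reads)
                )
            except ValueError as exc:
                if str(exc).startswith(str(path)):
                    raise
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return records


def write_caller_file(path, records: Iterable[CallerRecord], tool: str) -> None:
    """Serialize records back into a tool's dialect (inverse of the parser)."""
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}")
    with open(path, "w") as fh:
        for r in records:
            if tool == "ciri":
                start1 = r.start + 1
                fh.write(
                    f"{r.chrom}:{start1}|{r.end}\t{r.chrom}\t{start1}\t{r.end}"
                    f"\t{r.junction_reads}\t{r.strand}\n"
                )
            elif tool == "circexplorer":
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\tcircularRNA"
                    f"\t{r.junction_reads}\t{r.strand}\n"
                )
            elif tool == "find_circ":
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\tnorm_junction"
                    f"\t{r.junction_reads}\t{r.strand}\t{r.junction_reads}\n"
                )
            else:
                fh.write(
                    f"{r.chrom}|{r.start}|{r.end}|{r.strand}"
                    f"\t{r.junction_reads}\t0.99\n"
                )


def read_sample_sheet(path) -> Dict[str, str]:
    """Read the sample sheet TSV (sample_id, group). Header optional."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 fields")
            if ln == 1 and f[0].lower() in ("sample", "sample_id"):
                continue
            out[f[0]] = f[1]
    return out


def merge_candidates(
    records: Sequence[CallerRecord],
    min_reads: int = 2,
    sample_groups: Optional[Mapping[str, str]] = None,
) -> List[CircRNACandidate]:
    """Collapse normalized records into unique back-splice candidates.

    Records are grouped by exact (chrom, start, end). Within a candidate the
    per-sample read count is the maximum over the tools that report that
    sample (a conservative single number that avoids double counting); a
    sample is retained only when that maximum reaches ``min_reads``, and a
    candidate with no surviving sample is dropped. The result is sorted by
    coordinate, so the operation is order-independent in its input.
    """
    by_key: Dict[tuple, List[CallerRecord]] = defaultdict(list)
    for r in records:
        by_key[(r.chrom, r.start, r.end)].append(r)

    out: List[CircRNACandidate] = []
    for (chrom, start, end), recs in by_key.items():
        reads: Dict[str, int] = {}
        tools: Dict[str, Set[str]] = defaultdict(set)
        strands = [r.strand for r in recs if r.strand in "+-"]
        for r in recs:
            reads[r.sample_id] = max(reads.get(r.sample_id, 0), r.junction_reads)
            tools[r.sample_id].add(r.tool)
        kept = {s: n for s, n in reads.items() if n >= min_reads}
        if not kept:
            continue
        cand = CircRNACandidate(
            chrom=chrom,
            start=start,
            end=end,
            strand=max(set(strands), key=strands.count) if strands else ".",
            per_sample_reads=dict(sorted(kept.items())),
            tools_by_sample={s: set(tools[s]) for s in kept},
        )
        if sample_groups:
            cand.group_labels = {s: sample_groups[s] for s in kept if s in sample_groups}
        out.append(cand)
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out


def filter_recurrent(
    candidates: Sequence[CircRNACandidate],
    min_samples: int,
    min_reads_per_sample: int,
    cohort_size: Optional[int] = None,
) -> List[CircRNACandidate]:
    """Keep candidates seen in >= min_samples samples at >= min_reads each.

    With (min_samples=10, min_reads_per_sample=2) on a 20-sample cohort this
    selects the recurrent candidates used as network input (detection in at
    least half the samples).
    """
    if cohort_size is not None and min_samples > cohort_size:
        raise ValueError(
            f"min_samples={min_samples} exceeds cohort size {cohort_size}"
        )
    return [
        c
        for c in candidates
        if sum(1 for n in c.per_sample_reads.values() if n >= min_reads_per_sample)
        >= min_samples
    ]


def overlap_stats(candidates: Sequence[CircRNACandidate]) -> dict:
    """Per-tool counts, tool intersections, group occupancy and read histogram.

    A candidate counts toward a tool when any of its samples lists that tool.
    Histogram bins follow the read-support summary convention (<10, 10-20,
    >20 maximum per-sample reads).
    """
    per_tool = {t: 0 for t in TOOLS}
    pairwise = {}
    for i, a in enumerate(TOOLS):
        for b in TOOLS[i + 1 :]:
            pairwise[f"{a}&{b}"] = 0
    four_way = 0
    groups: Dict[str, int] = defaultdict(int)
    common = 0
    hist = {"lt10": 0, "10to20": 0, "gt20": 0}

    for c in candidates:
        tools = c.tools
        for t in tools:
            per_tool[t] += 1
        for i, a in enumerate(TOOLS):
            for b in TOOLS[i + 1 :]:
                if a in tools and b in tools:
                    pairwise[f"{a}&{b}"] += 1
        if len(tools) == 4:
            four_way += 1
        gp = c.groups_present()
        if len(gp) > 1:
            common += 1
        elif len(gp) == 1:
            groups[next(iter(gp))] += 1
        mx = max(c.per_sample_reads.values())
        if mx < 10:
            hist["lt10"] += 1
        elif mx <= 20:
            hist["10to20"] += 1
        else:
            hist["gt20"] += 1

    return {
        "n_candidates": len(candidates),
        "per_tool": per_tool,
        "pairwise": pairwise,
        "four_way": four_way,
        "unique_per_group": dict(groups),
        "common_between_groups": common,
        "read_histogram": hist,
    }


def write_candidate_table(path, candidates: Sequence[CircRNACandidate]) -> None:
    """Master candidate table: id, strand, samples, reads, tools, groups."""
    with open(path, "w") as fh:
        fh.write(
            "circ_id\tstrand\tn_samples\tper_sample_reads\ttools\tgroups\n"
        )
        for c in candidates:
            reads = ",".join(f"{s}:{n}" for s, n in sorted(c.per_sample_reads.items()))
            tools = ",".join(sorted(c.tools))
            groups = ",".join(sorted(c.groups_present()))
            fh.write(
                f"{c.id}\t{c.strand}\t{c.n_samples}\t{reads}\t{tools}\t{groups}\n"
            )
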