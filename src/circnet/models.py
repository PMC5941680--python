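"""Gene models in BED12 and the exon arithmetic built on them.

Coordinates follow the BED convention throughout: 0-based, half-open.
``thickStart``/``thickEnd`` delimit the CDS span; a transcript with
``thickStart == thickEnd`` is treated as non-coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


@dataclass
class Transcript:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Interval]  # sorted genomic (start, end), half-open
    thick_start: int
    thick_end: int
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            self.gene = self.name
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start >= end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.name}: exon ({s},{e}) outside transcript span")

    @property
    def introns(self) -> List[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exon_overlap(self, start: int, end: int) -> List[Interval]:
        """Intersections of [start, end) with the exon blocks, genomic order."""
        out = []
        for s, e in self.exons:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out.append((lo, hi))
        return out

    def contains_in_exon(self, pos: int, as_end: bool = False) -> bool:
        """Half-open containment of a boundary within some exon.

        A start boundary ``p`` is inside an exon when ``s <= p < e``; an end
        boundary (exclusive coordinate) when ``s < p <= e``.
        """
        for s, e in self.exons:
            if as_end:
                if s < pos <= e:
                    return True
            elif s <= pos < e:
                return True
        return False


def spliced_coordinate_map(exons: Iterable[Interval], strand: str) -> List[int]:
    """Genomic coordinate of every position of the spliced transcript sequence.

    Index i of the spliced (strand-oriented, 5'->3') sequence maps to
    ``map[i]`` on the forward genomic strand.
    """
    fwd: List[int] = []
    for s, e in sorted(exons):
        fwd.extend(range(s, e))
    if strand == "-":
        fwd.reverse()
    return fwd


def read_bed12(path) -> List[Transcript]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 BED fields, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{ln}: block count mismatch")
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            out.append(
                Transcript(
                    name=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    thick_start=thick_start,
                    thick_end=thick_end,
                )
            )
    return out


def write_bed12(path, transcripts: Iterable[Transcript]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            starts = ",".join(str(s - t.start) for s, e in t.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.chrom,
                        t.start,
                        t.end,
                        t.name,
                        0,
                        t.strand,
                        t.thick_start,
                        t.thick_end,
                        0,
                        len(t.exons),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )
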