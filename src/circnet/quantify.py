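"""Circular-to-linear abundance ratios.

For each back-splice candidate the circular abundance is the back-spliced
junction read count Nc, and the linear abundance is the larger of the linear
read counts sharing the same 5' or 3' splice site (Nl5, Nl3):

    ratio = Nc / max(Nl5, Nl3)

A circle with no linear reads at either splice site has no finite ratio and
is flagged ``CIRC_ONLY`` rather than reported as infinity. Ratio classes:

    circ_dominant_ge10  ratio >= 10 and linear count nonzero
    no_linear           max(Nl5, Nl3) == 0 with Nc > 0
    linear_higher       max(Nl5, Nl3) > Nc
    other               everything else

Cohort summaries average the counts across samples first and divide once
(mean-of-counts, not mean-of-ratios).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

CIRC_ONLY = "CIRC_ONLY"

RATIO_CLASSES = ("circ_dominant_ge10", "no_linear", "linear_higher", "other")


@dataclass(frozen=True)
class JunctionCounts:
    nc: float
    nl5: float
    nl3: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.nc < 0 or self.nl5 < 0 or self.nl3 < 0:
            raise ValueError("junction counts must be non-negative")

    @property
    def linear_max(self) -> float:
        return max(self.nl5, self.nl3)


@dataclass
class RatioResult:
    circ_id: str
    ratio: Optional[float]  # None <=> CIRC_ONLY
    linear_max: float
    ratio_class: str

    @property
    def circ_only(self) -> bool:
        return self.ratio is None


def _classify(nc: float, linear_max: float) -> str:
    if linear_max == 0:
        return "no_linear" if nc > 0 else "other"
    if nc / linear_max >= 10:
        return "circ_dominant_ge10"
    if linear_max > nc:
        return "linear_higher"
    return "other"


def circular_to_linear(counts: JunctionCounts, circ_id: str = "") -> RatioResult:
    """Apply the ratio formula and assign the ratio class for one candidate."""
    lm = counts.linear_max
    if lm == 0:
        return RatioResult(circ_id, None, 0.0, _classify(counts.nc, 0.0))
    return RatioResult(circ_id, counts.nc / lm, lm, _classify(counts.nc, lm))


def ratio_cohort_summary(
    per_sample: Mapping[str, Sequence[JunctionCounts]],
) -> Tuple[List[dict], Dict[str, float]]:
    """Candidate-level averaged ratios plus class proportions.

    ``per_sample`` maps candidate id -> per-sample JunctionCounts. Counts are
    averaged across samples before the single division, so a candidate gets
    one ratio computed from its mean Nc and mean per-sample linear maximum.
    Returns (per-candidate rows, class-proportion dict); proportions sum to 1
    over all candidates.
    """
    rows: List[dict] = []
    class_counts: Dict[str, int] = defaultdict(int)
    for circ_id in sorted(per_sample):
        counts = per_sample[circ_id]
        if not counts:
            continue
        n = len(counts)
        mean_nc = sum(c.nc for c in counts) / n
        mean_nl5 = sum(c.nl5 for c in counts) / n
        mean_nl3 = sum(c.nl3 for c in counts) / n
        mean_lm = sum(c.linear_max for c in counts) / n
        res = (
            RatioResult(circ_id, None, 0.0, _classify(mean_nc, 0.0))
            if mean_lm == 0
            else RatioResult(
                circ_id, mean_nc / mean_lm, mean_lm, _classify(mean_nc, mean_lm)
            )
        )
        class_counts[res.ratio_class] += 1
        rows.append(
            {
                "circ_id": circ_id,
                "mean_nc": mean_nc,
                "mean_nl5": mean_nl5,
                "mean_nl3": mean_nl3,
                "mean_linear_max": mean_lm,
                "ratio": res.ratio,
                "circ_only": res.circ_only,
                "ratio_class": res.ratio_class,
            }
        )
    total = len(rows)
    proportions = {
        k: (class_counts.get(k, 0) / total if total else 0.0) for k in RATIO_CLASSES
    }
    return rows, proportions


def read_linear_junction_tsv(path) -> Dict[Tuple[str, int], float]:
    """Read a per-sample linear junction TSV (chrom, position, reads)."""
    out: Dict[Tuple[str, int], float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 fields")
            if ln == 1 and f[0].lower() == "chrom":
                continue
            out[(f[0], int(f[1]))] = float(f[2])
    return out


def junction_counts_for_candidates(
    candidates,
    linear_by_sample: Mapping[str, Mapping[Tuple[str, int], float]],
) -> Dict[str, List[JunctionCounts]]:
    """Join candidate back-splice reads with linear counts at the splice sites.

    The 5' linear count is looked up at the candidate start coordinate and the
    3' count at the end coordinate; only samples in which the candidate was
    detected contribute. Missing splice-site rows count as 0 linear reads.
    """
    out: Dict[str, List[JunctionCounts]] = {}
    for cand in candidates:
        rows = []
        for sample, nc in sorted(cand.per_sample_reads.items()):
            lin = linear_by_sample.get(sample, {})
            nl5 = lin.get((cand.chrom, cand.start), 0.0)
            nl3 = lin.get((cand.chrom, cand.end), 0.0)
            rows.append(JunctionCounts(nc=nc, nl5=nl5, nl3=nl3, sample_id=sample))
        out[cand.id] = rows
    return out


def write_ratio_table(path, rows: Iterable[dict]) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tmean_nc\tmean_nl5\tmean_nl3\tratio\tratio_class\n")
        for r in rows:
            ratio = CIRC_ONLY if r["circ_only"] else f"{r['ratio']:.4f}"
            fh.write(
                f"{r['circ_id']}\t{r['mean_nc']:.4f}\t{r['mean_nl5']:.4f}"
                f"\t{r['mean_nl3']:.4f}\t{ratio}\t{r['ratio_class']}\n"
            )
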