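"""Synthetic cohort generator for the whole pipeline.

Emulates the inputs of a two-group (AD vs ND, 10 + 10 samples) astrocyte
circRNA study at desk scale: a small random genome with non-overlapping
multi-exon gene models, a set of true back-splice events spread over exonic,
intronic and intergenic space, four caller output files per sample in their
native dialects (including CIRI's 1-based starts), linear splice-junction
counts shaped into circle-dominant / no-linear / linear-higher classes,
miRNAs with sponge circRNAs carrying planted binding sites, a pair of
partially overlapping miRNA-mRNA target databases, a differential-expression
table and pathway gene sets.

Junction read counts are negative binomial (overdispersed, so the >= 2-read
support filter is exercised nontrivially); caller false positives are
Poisson per megabase and placed in intergenic space so truth-aware tests can
tell them apart. A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import callers as callers_mod
from .callers import CallerRecord, write_caller_file
from .models import Transcript, spliced_coordinate_map, write_bed12
from .sequences import revcomp_rna, rna_to_dna, write_fasta

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"


@dataclass(frozen=True)
class CallerProfile:
    """Detection behaviour of one caller: sensitivity per true event,
    false-positive calls per megabase per sample, and the fraction of the
    true junction reads the tool recovers."""

    sensitivity: float
    fp_per_mb: float
    read_capture: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if not 0.0 <= self.read_capture <= 1.0:
            raise ValueError("read_capture must be in [0, 1]")
        if self.fp_per_mb < 0:
            raise ValueError("fp_per_mb must be >= 0")


def default_caller_profiles() -> Dict[str, CallerProfile]:
    # Ordering of per-tool call-set sizes follows the usual benchmark
    # observation (KNIFE > find_circ > CIRI > CIRCexplorer).
    return {
        "ciri": CallerProfile(0.85, 2.0, 0.95),
        "circexplorer": CallerProfile(0.80, 1.0, 0.90),
        "find_circ": CallerProfile(0.90, 3.0, 0.90),
        "knife": CallerProfile(0.95, 4.0, 1.00),
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_samples_per_group: int = 10
    group_names: Tuple[str, str] = ("AD", "ND")
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 400_000}
    )
    n_genes: int = 30
    n_circ_true: int = 80
    exonic_fraction: float = 0.70
    intronic_fraction: float = 0.15
    caller_profiles: Dict[str, CallerProfile] = field(
        default_factory=default_caller_profiles
    )
    read_depth_mean: float = 8.0
    recurrent_depth_mean: float = 40.0
    nb_size: float = 2.0  # NB dispersion: var = mean + mean^2 / size
    fp_read_mean: float = 1.0
    # linear-junction classes
    circ_dominant_fraction: float = 0.10
    zero_linear_fraction: float = 0.45
    linear_mean: float = 30.0
    # miRNAs and planted sponge sites
    n_mirnas: int = 40
    mirna_length: int = 23
    n_sponge_circ: int = 6
    mirnas_per_sponge: int = 2
    seed_planted_sites: int = 12
    site_spacing: int = 6
    # target databases / DE / pathways
    n_universe_genes: int = 400
    targets_per_mirna: int = 12
    db_common_fraction: float = 0.4
    n_de_genes: int = 60
    de_log2fc: float = 3.0
    n_pathways: int = 20
    n_enriched_pathways: int = 3
    pathway_size: int = 30

    def __post_init__(self) -> None:
        for name in (
            "exonic_fraction",
            "intronic_fraction",
            "circ_dominant_fraction",
            "zero_linear_fraction",
            "db_common_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.exonic_fraction + self.intronic_fraction > 1.0:
            raise ValueError("exonic_fraction + intronic_fraction > 1")
        for name in (
            "n_samples_per_group",
            "n_genes",
            "n_circ_true",
            "n_mirnas",
            "n_universe_genes",
            "n_pathways",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.mirna_length < 8:
            raise ValueError("mirna_length must be >= 8 nt")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")

    @property
    def sample_ids(self) -> List[str]:
        a, b = self.group_names
        n = self.n_samples_per_group
        return [f"{a}_{i:02d}" for i in range(1, n + 1)] + [
            f"{b}_{i:02d}" for i in range(1, n + 1)
        ]

    @property
    def sample_groups(self) -> Dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids}


@dataclass
class TrueCircle:
    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    region_class: str  # exonic | intronic | intergenic
    ratio_class: str = "linear_higher"  # circ_dominant | zero_linear | linear_higher
    is_sponge: bool = False
    transcript_name: str = ""

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GroundTruth:
    config: SimConfig
    genome: Dict[str, List[str]]  # mutable per-base lists until rendered
    transcripts: List[Transcript]
    intergenic: Dict[str, List[Tuple[int, int]]]
    true_circles: List[TrueCircle]
    mirnas: List[Tuple[str, str]]  # (id, RNA sequence)
    planted_interactions: List[Tuple[str, str, int]]
    db_core: Set[Tuple[str, str]] = field(default_factory=set)
    true_de_genes: List[Tuple[str, float]] = field(default_factory=list)
    sample_reads: Optional[Dict[str, Dict[str, int]]] = None  # circ_id -> sample -> Nc

    def genome_str(self) -> Dict[str, str]:
        return {c: "".join(b) for c, b in self.genome.items()}

    def circle_by_id(self) -> Dict[str, TrueCircle]:
        return {c.id: c for c in self.true_circles}

    def transcript_by_name(self) -> Dict[str, Transcript]:
        return {t.name: t for t in self.transcripts}

    def ensure_expression(self) -> Dict[str, Dict[str, int]]:
        """Draw per-sample back-splice read counts once (idempotent).

        Counts are negative binomial; designated sponge circles use the
        higher recurrent depth so that, like the most recurrent circles in a
        real cohort, they survive the detection-in-half-the-samples filter.
        """
        if self.sample_reads is not None:
            return self.sample_reads
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 17])
        reads: Dict[str, Dict[str, int]] = {}
        for circ in self.true_circles:
            mean = cfg.recurrent_depth_mean if circ.is_sponge else cfg.read_depth_mean
            p = cfg.nb_size / (cfg.nb_size + mean)
            per_sample = rng.negative_binomial(cfg.nb_size, p, len(cfg.sample_ids))
            reads[circ.id] = {
                s: int(n) for s, n in zip(cfg.sample_ids, per_sample)
            }
        self.sample_reads = reads
        return reads


# ---------------------------------------------------------------------------
# Genome, gene models and true circles


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> List[Transcript]:
    """Non-overlapping multi-exon gene models tiled along the chromosomes.

    The first ``n_sponge_circ`` genes are sponge hosts: forced to the plus
    strand with larger exons so planted binding sites fit, and reserved for
    the sponge circles.
    """
    chroms = sorted(cfg.chrom_lengths)
    transcripts: List[Transcript] = []
    gi = 0
    per_chrom = {c: [] for c in chroms}
    # round-robin allocation of gene counts proportional to length
    total = sum(cfg.chrom_lengths.values())
    counts = {
        c: max(1, round(cfg.n_genes * cfg.chrom_lengths[c] / total)) for c in chroms
    }
    while sum(counts.values()) > cfg.n_genes:
        counts[max(counts, key=counts.get)] -= 1
    while sum(counts.values()) < cfg.n_genes:
        counts[min(counts, key=counts.get)] += 1

    for chrom in chroms:
        cursor = int(rng.integers(500, 2000))
        length = cfg.chrom_lengths[chrom]
        for _ in range(counts[chrom]):
            sponge_host = gi < cfg.n_sponge_circ
            n_exons = int(rng.integers(5, 8)) if sponge_host else int(rng.integers(3, 8))
            lo, hi = (260, 400) if sponge_host else (120, 400)
            exon_lens = rng.integers(lo, hi, n_exons)
            intron_lens = rng.integers(200, 800, n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + 500 > length:
                raise ValueError(
                    f"chromosome {chrom} ({length} bp) too short for "
                    f"{counts[chrom]} genes; increase chrom_lengths or "
                    "reduce n_genes"
                )
            exons = []
            pos = cursor
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            strand = "+" if sponge_host else ("+" if rng.random() < 0.5 else "-")
            start, end = exons[0][0], exons[-1][1]
            # CDS excludes roughly half of the terminal exons (the UTRs)
            thick_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
            thick_end = exons[-1][1] - (exons[-1][1] - exons[-1][0]) // 2
            name = f"GENE{gi:04d}"
            transcripts.append(
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
            per_chrom[chrom].append((start, end))
            cursor = end + int(rng.integers(1500, 4000))
            gi += 1
    return transcripts


def _intergenic_gaps(cfg: SimConfig, transcripts: Sequence[Transcript]):
    gaps: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in sorted(cfg.chrom_lengths):
        spans = sorted(
            (t.start, t.end) for t in transcripts if t.chrom == chrom
        )
        cursor = 100
        out = []
        for s, e in spans:
            if s - cursor > 600:
                out.append((cursor, s - 100))
            cursor = e + 100
        if cfg.chrom_lengths[chrom] - cursor > 600:
            out.append((cursor, cfg.chrom_lengths[chrom] - 100))
        gaps[chrom] = out
    return gaps


def _sample_true_circles(
    cfg: SimConfig,
    transcripts: Sequence[Transcript],
    gaps: Dict[str, List[Tuple[int, int]]],
    rng: np.random.Generator,
) -> List[TrueCircle]:
    n_exonic = round(cfg.exonic_fraction * cfg.n_circ_true)
    n_intronic = round(cfg.intronic_fraction * cfg.n_circ_true)
    n_intergenic = cfg.n_circ_true - n_exonic - n_intronic
    n_sponge = min(cfg.n_sponge_circ, n_exonic)

    # boundary coordinates are kept globally unique so each linear splice
    # site in the emitted junction table belongs to exactly one circle
    used_coords: Set[Tuple[str, int]] = set()
    circles: List[TrueCircle] = []

    def claim(chrom: str, a: int, b: int) -> bool:
        if (chrom, a) in used_coords or (chrom, b) in used_coords:
            return False
        used_coords.add((chrom, a))
        used_coords.add((chrom, b))
        return True

    sponge_hosts = list(transcripts[: cfg.n_sponge_circ])
    other_genes = [t for t in transcripts if t not in sponge_hosts]
    multi_exon = [t for t in other_genes if len(t.exons) >= 1]

    # sponge circles: span most of the host gene's exons for planting room
    for t in sponge_hosts[:n_sponge]:
        i, j = 0, len(t.exons) - 1
        claim(t.chrom, t.exons[i][0], t.exons[j][1])
        circles.append(
            TrueCircle(
                chrom=t.chrom,
                start=t.exons[i][0],
                end=t.exons[j][1],
                strand=t.strand,
                gene=t.gene,
                region_class="exonic",
                is_sponge=True,
                transcript_name=t.name,
            )
        )

    def draw_exonic() -> TrueCircle:
        for _ in range(2000):
            t = multi_exon[int(rng.integers(len(multi_exon)))]
            i = int(rng.integers(len(t.exons)))
            j = int(rng.integers(i, len(t.exons)))
            if not claim(t.chrom, t.exons[i][0], t.exons[j][1]):
                continue
            return TrueCircle(
                chrom=t.chrom,
                start=t.exons[i][0],
                end=t.exons[j][1],
                strand=t.strand,
                gene=t.gene,
                region_class="exonic",
                transcript_name=t.name,
            )
        raise RuntimeError("could not place a unique exonic circle")

    def draw_intronic() -> TrueCircle:
        introns = [
            (t, iv) for t in transcripts for iv in t.introns if iv[1] - iv[0] >= 120
        ]
        for _ in range(1000):
            t, (s, e) = introns[int(rng.integers(len(introns)))]
            a = int(rng.integers(s + 5, e - 60))
            b = int(rng.integers(a + 50, min(e - 2, a + 400)))
            if not claim(t.chrom, a, b):
                continue
            return TrueCircle(
                chrom=t.chrom,
                start=a,
                end=b,
                strand=t.strand,
                gene=t.gene,
                region_class="intronic",
                transcript_name=t.name,
            )
        raise RuntimeError("could not place a unique intronic circle")

    def draw_intergenic() -> TrueCircle:
        flat = [(c, s, e) for c in sorted(gaps) for s, e in gaps[c] if e - s >= 300]
        for _ in range(1000):
            chrom, s, e = flat[int(rng.integers(len(flat)))]
            a = int(rng.integers(s, e - 200))
            b = int(rng.integers(a + 100, min(e, a + 1200)))
            if not claim(chrom, a, b):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            return TrueCircle(chrom, a, b, strand, "", "intergenic")
        raise RuntimeError("could not place a unique intergenic circle")

    for _ in range(n_exonic - n_sponge):
        circles.append(draw_exonic())
    for _ in range(n_intronic):
        circles.append(draw_intronic())
    for _ in range(n_intergenic):
        circles.append(draw_intergenic())

    # ratio classes: sponges are circle-dominant by design; the remaining
    # dominant slots, then the no-linear class, then linear-higher
    n_dom = max(n_sponge, round(cfg.circ_dominant_fraction * len(circles)))
    n_zero = round(cfg.zero_linear_fraction * len(circles))
    order = [c for c in circles if c.is_sponge] + [
        c for c in circles if not c.is_sponge
    ]
    for k, c in enumerate(order):
        if k < n_dom:
            c.ratio_class = "circ_dominant"
        elif k < n_dom + n_zero:
            c.ratio_class = "zero_linear"
        else:
            c.ratio_class = "linear_higher"
    return circles


def generate_genome_and_models(cfg: SimConfig) -> GroundTruth:
    """Random genome + gene models + true circles, with sites planted.

    miRNA sequences are drawn here too, because sponge binding sites are
    written directly into the genome: each designated sponge circle carries
    ``seed_planted_sites`` exact reverse complements of each of its
    ``mirnas_per_sponge`` miRNAs, placed inside single exons through the
    spliced-coordinate map, so an exhaustive motif search on the extracted
    circRNA sequence recovers every planted site.
    """
    rng = np.random.default_rng([cfg.seed, 5])
    transcripts = _place_genes(cfg, rng)
    gaps = _intergenic_gaps(cfg, transcripts)
    genome = {
        chrom: list(
            "".join(rng.choice(list(DNA_BASES), size=cfg.chrom_lengths[chrom]))
        )
        for chrom in sorted(cfg.chrom_lengths)
    }
    circles = _sample_true_circles(cfg, transcripts, gaps, rng)

    mirnas = [
        (
            f"sim-miR-{i + 1:03d}",
            "".join(rng.choice(list(RNA_BASES), size=cfg.mirna_length)),
        )
        for i in range(cfg.n_mirnas)
    ]

    truth = GroundTruth(
        config=cfg,
        genome=genome,
        transcripts=transcripts,
        intergenic=gaps,
        true_circles=circles,
        mirnas=mirnas,
        planted_interactions=[],
    )
    _plant_sponge_sites(truth, rng)
    return truth


def _plant_sponge_sites(truth: GroundTruth, rng: np.random.Generator) -> None:
    cfg = truth.config
    by_name = truth.transcript_by_name()
    sponges = [c for c in truth.true_circles if c.is_sponge]
    for si, circ in enumerate(sponges):
        t = by_name[circ.transcript_name]
        blocks = t.exon_overlap(circ.start, circ.end)
        coord_map = spliced_coordinate_map(blocks, t.strand)
        # offsets of single-exon-contained windows, walked left to right
        slots: List[int] = []
        offset = 0
        step = cfg.mirna_length + cfg.site_spacing
        for s, e in blocks:
            pos = 0
            while pos + cfg.mirna_length <= e - s:
                slots.append(offset + pos)
                pos += step
            offset += e - s
        assigned = [
            truth.mirnas[(si * cfg.mirnas_per_sponge + k) % len(truth.mirnas)]
            for k in range(cfg.mirnas_per_sponge)
        ]
        need = cfg.seed_planted_sites * len(assigned)
        if len(slots) < need:
            raise ValueError(
                f"sponge circle {circ.id} has room for {len(slots)} sites, "
                f"needs {need}; enlarge sponge host exons or reduce "
                "seed_planted_sites"
            )
        chosen = sorted(
            int(i) for i in rng.choice(len(slots), size=need, replace=False)
        )
        chrom_seq = truth.genome[circ.chrom]
        for k, slot_idx in enumerate(chosen):
            mirna_id, mirna_seq = assigned[k % len(assigned)]
            motif_dna = rna_to_dna(revcomp_rna(mirna_seq))  # site on the RNA
            off = slots[slot_idx]
            for p, base in enumerate(motif_dna):
                gpos = coord_map[off + p]
                if t.strand == "-":
                    base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                chrom_seq[gpos] = base
        for mirna_id, _ in assigned:
            truth.planted_interactions.append(
                (circ.id, mirna_id, cfg.seed_planted_sites)
            )


# ---------------------------------------------------------------------------
# Caller outputs


def emit_caller_outputs(truth: GroundTruth, outdir) -> Dict[str, Dict[str, str]]:
    """Write four per-sample caller files; returns {tool: {sample: path}}.

    Each tool reports a sensitivity-thinned subset of the expressed true
    circles (junction reads binomially captured from the sample's true
    count, so different tools report slightly different support) plus
    Poisson false positives placed in intergenic space.
    """
    cfg = truth.config
    reads = truth.ensure_expression()
    rng = np.random.default_rng([cfg.seed, 23])
    total_mb = sum(cfg.chrom_lengths.values()) / 1e6
    flat_gaps = [
        (c, s, e) for c in sorted(truth.intergenic) for s, e in truth.intergenic[c]
    ]
    paths: Dict[str, Dict[str, str]] = {}
    for tool in callers_mod.TOOLS:
        profile = cfg.caller_profiles[tool]
        tool_dir = os.path.join(outdir, "callers", tool)
        os.makedirs(tool_dir, exist_ok=True)
        paths[tool] = {}
        for sample in cfg.sample_ids:
            records: List[CallerRecord] = []
            for circ in truth.true_circles:
                nc = reads[circ.id][sample]
                if nc <= 0 or rng.random() > profile.sensitivity:
                    continue
                obs = int(rng.binomial(nc, profile.read_capture))
                records.append(
                    CallerRecord(
                        tool, sample, circ.chrom, circ.start, circ.end,
                        circ.strand, max(1, obs),
                    )
                )
            n_fp = int(rng.poisson(profile.fp_per_mb * total_mb))
            for _ in range(n_fp):
                chrom, s, e = flat_gaps[int(rng.integers(len(flat_gaps)))]
                a = int(rng.integers(s, e - 150))
                b = int(rng.integers(a + 100, min(e, a + 1500)))
                records.append(
                    CallerRecord(
                        tool, sample, chrom, a, b,
                        "+" if rng.random() < 0.5 else "-",
                        1 + int(rng.poisson(cfg.fp_read_mean)),
                    )
                )
            records.sort(key=lambda r: (r.chrom, r.start, r.end))
            path = os.path.join(tool_dir, f"{sample}.tsv")
            write_caller_file(path, records, tool)
            paths[tool][sample] = path
    return paths


# ---------------------------------------------------------------------------
# Linear junction counts


def emit_linear_junction_counts(truth: GroundTruth, outdir) -> Dict[str, str]:
    """Per-sample TSVs of linear reads at each circle's two splice sites.

    Circle-dominant candidates get linear counts capped at Nc/12 per sample
    (with at least one nonzero sample) so the cohort-averaged ratio lands at
    >= 10 with a nonzero linear count; the zero-linear class gets all-zero
    rows; the rest draw overdispersed counts around ``linear_mean``. A few
    linear-only splice sites from circle-free genes are included as well.
    """
    cfg = truth.config
    reads = truth.ensure_expression()
    rng = np.random.default_rng([cfg.seed, 29])
    lin_dir = os.path.join(outdir, "linear")
    os.makedirs(lin_dir, exist_ok=True)

    circle_coords = {
        (c.chrom, pos) for c in truth.true_circles for pos in (c.start, c.end)
    }
    linear_only = [
        (t.chrom, boundary)
        for t in truth.transcripts
        for s, e in t.exons
        for boundary in (s, e)
        if (t.chrom, boundary) not in circle_coords
    ][:5]

    p_lin = cfg.nb_size / (cfg.nb_size + cfg.linear_mean)
    paths: Dict[str, str] = {}
    for sample in cfg.sample_ids:
        rows: List[Tuple[str, int, int]] = []
        for ci, circ in enumerate(truth.true_circles):
            nc = reads[circ.id][sample]
            if circ.ratio_class == "zero_linear":
                nl5 = nl3 = 0
            elif circ.ratio_class == "circ_dominant":
                cap = nc // 12
                nl5 = min(int(rng.poisson(1.0)), cap)
                nl3 = min(int(rng.poisson(1.0)), cap)
                if sample == cfg.sample_ids[0]:
                    nl5 = max(nl5, 1)  # linear count must not be identically 0
            else:
                nl5 = int(rng.negative_binomial(cfg.nb_size, p_lin))
                nl3 = int(rng.negative_binomial(cfg.nb_size, p_lin))
            rows.append((circ.chrom, circ.start, nl5))
            rows.append((circ.chrom, circ.end, nl3))
        for chrom, pos in linear_only:
            rows.append((chrom, pos, int(rng.negative_binomial(cfg.nb_size, p_lin))))
        rows.sort()
        path = os.path.join(lin_dir, f"{sample}.tsv")
        with open(path, "w") as fh:
            fh.write("chrom\tposition\tlinear_reads\n")
            for chrom, pos, n in rows:
                fh.write(f"{chrom}\t{pos}\t{n}\n")
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# miRNAs, target databases, DE table, pathways


def emit_mirna_and_targets(truth: GroundTruth, outdir) -> Dict[str, str]:
    """Write miRNA FASTA, two target DBs, the DE table and pathway GMT.

    The two target databases share a planted common core
    (``db_common_fraction`` of each miRNA's targets) — the intersection the
    network stage relies on. True DE genes are drawn preferentially from the
    core targets of the sponge miRNAs at +/- ``de_log2fc`` with small
    p-values; null genes get log2FC ~ N(0, 0.3) and p ~ Uniform(0, 1).
    Planted pathways are stacked with true DE genes; the rest are random.
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 31])
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "mirna_fasta": os.path.join(outdir, "mirnas.fa"),
        "targets_db1": os.path.join(outdir, "targets_mirtarbase_like.tsv"),
        "targets_db2": os.path.join(outdir, "targets_targetscan_like.tsv"),
        "de_table": os.path.join(outdir, "de_genes.tsv"),
        "gmt": os.path.join(outdir, "pathways.gmt"),
    }
    write_fasta(paths["mirna_fasta"], truth.mirnas)

    universe = [f"G{i:04d}" for i in range(cfg.n_universe_genes)]
    n_core = round(cfg.targets_per_mirna * cfg.db_common_fraction)
    n_uniq = cfg.targets_per_mirna - n_core
    db1: List[Tuple[str, str]] = []
    db2: List[Tuple[str, str]] = []
    core: Set[Tuple[str, str]] = set()
    for mirna_id, _ in truth.mirnas:
        picks = rng.choice(len(universe), size=n_core + 2 * n_uniq, replace=False)
        genes = [universe[int(i)] for i in picks]
        for g in genes[:n_core]:
            core.add((mirna_id, g))
            db1.append((mirna_id, g))
            db2.append((mirna_id, g))
        for g in genes[n_core : n_core + n_uniq]:
            db1.append((mirna_id, g))
        for g in genes[n_core + n_uniq :]:
            db2.append((mirna_id, g))
    truth.db_core = core
    with open(paths["targets_db1"], "w") as fh:
        fh.write("mirna_id\tgene_id\tsource\n")
        for m, g in sorted(db1):
            fh.write(f"{m}\t{g}\tdb1\n")
    with open(paths["targets_db2"], "w") as fh:
        fh.write("mirna_id\tgene_id\tsource\n")
        for m, g in sorted(db2):
            fh.write(f"{m}\t{g}\tdb2\n")

    sponge_mirnas = {m for _, m, _ in truth.planted_interactions}
    preferred = sorted({g for m, g in core if m in sponge_mirnas})
    pool = preferred + [g for g in universe if g not in set(preferred)]
    de_genes = pool[: cfg.n_de_genes]
    truth.true_de_genes = []
    de_rows = []
    for i, g in enumerate(de_genes):
        sign = 1.0 if i % 2 == 0 else -1.0
        lfc = sign * (cfg.de_log2fc + float(rng.normal(0, 0.25)))
        p = float(10 ** rng.uniform(-5, -2.5))
        truth.true_de_genes.append((g, lfc))
        de_rows.append((g, lfc, p))
    for g in universe:
        if g in set(de_genes):
            continue
        de_rows.append((g, float(rng.normal(0, 0.3)), float(rng.uniform())))
    de_rows.sort()
    with open(paths["de_table"], "w") as fh:
        fh.write("gene\tlog2fc\tpvalue\n")
        for g, lfc, p in de_rows:
            fh.write(f"{g}\t{lfc:.4f}\t{p:.6g}\n")

    # pathways: planted ones are ~2/3 true DE genes, the rest random draws
    gmt_rows = []
    de_set = list(de_genes)
    for i in range(cfg.n_pathways):
        name = f"PATHWAY_{i + 1:02d}"
        if i < cfg.n_enriched_pathways and de_set:
            n_hit = min(len(de_set), (2 * cfg.pathway_size) // 3)
            hits = [de_set[int(j)] for j in rng.choice(len(de_set), n_hit, replace=False)]
            fill = [
                universe[int(j)]
                for j in rng.choice(
                    len(universe), cfg.pathway_size - len(set(hits)), replace=False
                )
            ]
            members = sorted(set(hits) | set(fill))
        else:
            members = sorted(
                universe[int(j)]
                for j in rng.choice(len(universe), cfg.pathway_size, replace=False)
            )
        gmt_rows.append((name, f"synthetic pathway {i + 1}", members))
    with open(paths["gmt"], "w") as fh:
        for name, desc, members in gmt_rows:
            fh.write(name + "\t" + desc + "\t" + "\t".join(members) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Top-level orchestration


def simulate_all(cfg: SimConfig, outdir) -> Dict[str, object]:
    """Generate every pipeline input under ``outdir``; returns a path manifest."""
    os.makedirs(outdir, exist_ok=True)
    truth = generate_genome_and_models(cfg)
    truth.ensure_expression()

    genome_path = os.path.join(outdir, "genome.fa")
    write_fasta(genome_path, sorted(truth.genome_str().items()))
    bed_path = os.path.join(outdir, "genes.bed")
    write_bed12(bed_path, truth.transcripts)
    sheet_path = os.path.join(outdir, "samples.tsv")
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in cfg.sample_ids:
            fh.write(f"{s}\t{cfg.sample_groups[s]}\n")

    caller_paths = emit_caller_outputs(truth, outdir)
    linear_paths = emit_linear_junction_counts(truth, outdir)
    misc_paths = emit_mirna_and_targets(truth, outdir)

    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "true_circles": [
                    {
                        "id": c.id,
                        "strand": c.strand,
                        "gene": c.gene,
                        "region_class": c.region_class,
                        "ratio_class": c.ratio_class,
                        "is_sponge": c.is_sponge,
                    }
                    for c in truth.true_circles
                ],
                "planted_interactions": truth.planted_interactions,
                "true_de_genes": truth.true_de_genes,
                "db_core_size": len(truth.db_core),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return {
        "genome": genome_path,
        "gene_models": bed_path,
        "sample_sheet": sheet_path,
        "callers": caller_paths,
        "linear": linear_paths,
        "truth_json": truth_path,
        "truth": truth,
        **misc_paths,
    }
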