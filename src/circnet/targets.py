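"""miRNA binding-site prediction on circRNA sequences.

Two self-contained predictors are run on every circRNA-miRNA pair and a site
must satisfy both to count, mirroring the dual-algorithm intersection used in
ceRNA studies:

1. a complementarity *match score* from a Smith-Waterman local alignment of
   the miRNA (3'->5') against the circRNA (5'->3'), scored by Watson-Crick /
   G:U complementarity with affine gaps, with substitution scores doubled at
   miRNA positions 2-8 so seed pairing dominates; and
2. a *duplex free energy* from a nearest-neighbor stacking model of the
   implied RNA:RNA duplex.

Sites also carry a flag for a perfect Watson-Crick match to the miRNA seed
(positions 2-7 from the 5' end), the primary determinant of target
recognition. CircRNA sequences are extracted as the spliced exonic sequence
(or the genomic span for non-exonic circles) with a short junction-spanning
window appended so sites crossing the back-splice junction are detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .models import Transcript
from .sequences import dna_to_rna, revcomp_dna, revcomp_rna

# ---------------------------------------------------------------------------
# Scoring configuration

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

#: Nearest-neighbor stacking free energies (kcal/mol, 37 C) for consecutive
#: Watson-Crick pairs, keyed by the target-strand dinucleotide read 5'->3'.
WC_STACK = {
    "AA": -0.93, "AU": -1.10, "AC": -2.24, "AG": -2.08,
    "UA": -1.33, "UU": -0.93, "UC": -2.35, "UG": -2.11,
    "CA": -2.11, "CU": -2.08, "CC": -3.26, "CG": -2.36,
    "GA": -2.35, "GU": -2.24, "GC": -3.42, "GG": -3.26,
}

#: Flat stack value used when either pair of a step is a G:U wobble.
GU_STACK = -0.5

#: Free-energy penalty per internal non-paired alignment column.
MISMATCH_INTERRUPT = 0.5


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters of the complementarity aligner.

    Scores are on the conventional match-score scale where a strong site on a
    ~22-nt miRNA lands in the 140-190 range, so the usual 150/180 thresholds
    are directly applicable. Substitution scores are multiplied by
    ``seed_weight`` when the miRNA position (1-based from the 5' end) lies in
    ``weighted_span``.
    """

    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_weight: float = 2.0
    weighted_span: Tuple[int, int] = (2, 8)

    def position_weight(self, mirna_pos: int) -> float:
        lo, hi = self.weighted_span
        return self.seed_weight if lo <= mirna_pos <= hi else 1.0


DEFAULT_PARAMS = AlignmentParams()

SCORE_THRESHOLD_LOW = 150.0
SCORE_THRESHOLD_HIGH = 180.0
ENERGY_THRESHOLD = -20.0  # kcal/mol; duplex must be at least this favorable


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class MiRNA:
    id: str
    seq: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("T", "U")
        object.__setattr__(self, "seq", seq)
        if len(seq) < 8:
            raise ValueError(f"{self.id}: miRNA shorter than 8 nt")
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"{self.id}: non-ACGU characters in sequence")

    @property
    def seed(self) -> str:
        """Seed region, nucleotide positions 2-7 from the 5' end."""
        return self.seq[1:7]


@dataclass
class BindingSite:
    circ_id: str
    mirna_id: str
    target_start: int  # 0-based on the circRNA-local sequence
    target_end: int
    align_score: float
    duplex_energy: float
    seed_matched: bool

    def passes(self, score_threshold: float, energy_threshold: float) -> bool:
        return (
            self.align_score >= score_threshold
            and self.duplex_energy <= energy_threshold
        )


@dataclass
class PairPrediction:
    circ_id: str
    mirna_id: str
    sites: List[BindingSite] = field(default_factory=list)
    score_threshold: float = SCORE_THRESHOLD_LOW
    energy_threshold: float = ENERGY_THRESHOLD

    @property
    def n_sites(self) -> int:
        """Number of sites passing both the score and the energy criterion."""
        return sum(
            1 for s in self.sites if s.passes(self.score_threshold, self.energy_threshold)
        )

    @property
    def predicted_by_both(self) -> bool:
        return self.n_sites >= 1

    @property
    def best_score(self) -> float:
        return max((s.align_score for s in self.sites), default=0.0)

    @property
    def best_energy(self) -> float:
        return min((s.duplex_energy for s in self.sites), default=0.0)


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_circ_sequence(
    candidate,
    genome: Mapping[str, str],
    transcript: Optional[Transcript] = None,
    junction_window: int = 22,
) -> str:
    """Circularized RNA sequence of a candidate, junction window appended.

    Exonic candidates (``transcript`` given) yield the spliced sequence of the
    transcript's exons clipped to the back-splice interval; other candidates
    yield the full genomic span. Minus-strand candidates are
    reverse-complemented. Because the molecule is circular, the first
    ``junction_window`` nt (one less than the miRNA length, typically) are
    appended at the end so sites spanning the back-splice junction fall inside
    the linear scan.
    """
    chrom_seq = str(genome[candidate.chrom])
    if candidate.end > len(chrom_seq) or candidate.start < 0:
        raise ValueError(
            f"{candidate.id}: coordinates outside chromosome "
            f"(length {len(chrom_seq)})"
        )
    if transcript is not None:
        blocks = transcript.exon_overlap(candidate.start, candidate.end)
        dna = "".join(chrom_seq[s:e] for s, e in blocks)
    else:
        dna = chrom_seq[candidate.start : candidate.end]
    if candidate.strand == "-":
        dna = revcomp_dna(dna)
    rna = dna_to_rna(dna)
    if junction_window > 0 and rna:
        rna = rna + rna[: min(junction_window, len(rna))]
    return rna


# ---------------------------------------------------------------------------
# Seed scan


def seed_scan(sequence: str, mirna: MiRNA) -> List[int]:
    """Positions of exact Watson-Crick seed complements in the target.

    The scanned motif is the reverse complement of the miRNA seed (positions
    2-7); overlapping occurrences are all reported.
    """
    target = dna_to_rna(sequence)
    motif = revcomp_rna(mirna.seed)
    hits = []
    pos = target.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = target.find(motif, pos + 1)
    return hits


# ---------------------------------------------------------------------------
# Smith-Waterman complementarity alignment

_STOP, _DIAG, _FROM_E, _FROM_F = 0, 1, 2, 3


def _substitution_rows(mirna_rev: str, params: AlignmentParams) -> List[Dict[str, float]]:
    """Per-miRNA-position substitution score lookup for each target base."""
    n = len(mirna_rev)
    rows = []
    for i, m in enumerate(mirna_rev):
        pos = n - i  # 1-based position from the miRNA 5' end
        w = params.position_weight(pos)
        row = {}
        for t in "ACGUN":
            if (t, m) in WATSON_CRICK:
                row[t] = params.match * w
            elif (t, m) in WOBBLE:
                row[t] = params.wobble * w
            else:
                row[t] = params.mismatch * w
        rows.append(row)
    return rows


def _sw_matrices(target: str, mirna: MiRNA, params: AlignmentParams):
    """Affine-gap local alignment of the reversed miRNA against the target.

    Returns (H, ptrH, ptrE, ptrF): score and pointer matrices with the miRNA
    on rows (3'->5', i.e. reversed) and the target on columns (5'->3').
    """
    mirna_rev = mirna.seq[::-1]
    m, n = len(mirna_rev), len(target)
    sub = _substitution_rows(mirna_rev, params)
    go, ge = params.gap_open, params.gap_extend
    neg = float("-inf")

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    ptrH = [bytearray(n + 1) for _ in range(m + 1)]
    ptrE = [bytearray(n + 1) for _ in range(m + 1)]
    ptrF = [bytearray(n + 1) for _ in range(m + 1)]

    E_prev_row = None  # E only depends on the same row
    F_row_prev = [neg] * (n + 1)
    for i in range(1, m + 1):
        Hi, Hi1 = H[i], H[i - 1]
        pHi, pEi, pFi = ptrH[i], ptrE[i], ptrF[i]
        row_sub = sub[i - 1]
        E = neg
        F_row = [neg] * (n + 1)
        for j in range(1, n + 1):
            # E: gap in the miRNA (consumes target)
            e_open = Hi[j - 1] + go
            e_ext = E + ge
            if e_ext > e_open:
                E = e_ext
                pEi[j] = 1
            else:
                E = e_open
            # F: gap in the target (consumes miRNA)
            f_open = Hi1[j] + go
            f_ext = F_row_prev[j] + ge
            if f_ext > f_open:
                F = f_ext
                pFi[j] = 1
            else:
                F = f_open
            F_row[j] = F
            diag = Hi1[j - 1] + row_sub[target[j - 1]]
            best, ptr = 0.0, _STOP
            if diag > best:
                best, ptr = diag, _DIAG
            if E > best:
                best, ptr = E, _FROM_E
            if F > best:
                best, ptr = F, _FROM_F
            Hi[j] = best
            pHi[j] = ptr
        F_row_prev = F_row
    return H, ptrH, ptrE, ptrF


def _traceback(i: int, j: int, ptrH, ptrE, ptrF) -> Tuple[int, List[Tuple[int, int]]]:
    """Walk back from H[i][j]; returns (target_start, aligned diagonal cells).

    Diagonal cells are (mirna_rev index, target index) pairs, 5'->3' on the
    target after the final reversal.
    """
    pairs: List[Tuple[int, int]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            ptr = ptrH[i][j]
            if ptr == _STOP:
                break
            if ptr == _DIAG:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif ptr == _FROM_E:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ext = ptrE[i][j]
            j -= 1
            if ext == 0:
                state = "H"
        else:  # F
            ext = ptrF[i][j]
            i -= 1
            if ext == 0:
                state = "H"
    pairs.reverse()
    return j, pairs


def miranda_like_score(
    window: str,
    mirna: MiRNA,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> Tuple[float, Tuple[int, int]]:
    """Best local complementarity alignment score and its target span.

    The span is 0-based half-open on the target window; (0, 0) when no
    positive-scoring alignment exists.
    """
    target = dna_to_rna(window)
    if not target:
        return 0.0, (0, 0)
    H, ptrH, ptrE, ptrF = _sw_matrices(target, mirna, params)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, len(H)):
        Hi = H[i]
        for j in range(1, len(Hi)):
            if Hi[j] > best:
                best, bi, bj = Hi[j], i, j
    if best <= 0:
        return 0.0, (0, 0)
    tstart, _ = _traceback(bi, bj, ptrH, ptrE, ptrF)
    return best, (tstart, bj)


def _alignment_energy(
    target: str, mirna_rev: str, pairs: Sequence[Tuple[int, int]]
) -> float:
    """Nearest-neighbor free energy of the duplex implied by an alignment.

    Consecutive aligned columns where both positions base-pair contribute one
    stack term; each internal non-paired column adds a mismatch-interruption
    penalty. Positive totals (no stable duplex) are reported as 0.
    """
    if not pairs:
        return 0.0

    def paired(mi: int, tj: int) -> bool:
        duo = (target[tj], mirna_rev[mi])
        return duo in WATSON_CRICK or duo in WOBBLE

    energy = 0.0
    any_stack = False
    flags = [paired(mi, tj) for mi, tj in pairs]
    # internal mismatch interruptions: non-paired columns between paired ones
    first = next((k for k, f in enumerate(flags) if f), None)
    last = next((k for k in range(len(flags) - 1, -1, -1) if flags[k]), None)
    if first is None:
        return 0.0
    energy += MISMATCH_INTERRUPT * sum(
        1 for k in range(first, last + 1) if not flags[k]
    )
    for k in range(len(pairs) - 1):
        (mi1, tj1), (mi2, tj2) = pairs[k], pairs[k + 1]
        if not (flags[k] and flags[k + 1]):
            continue
        if mi2 != mi1 + 1 or tj2 != tj1 + 1:
            continue  # gapped step: no stack
        step = target[tj1] + target[tj2]
        duo1 = (target[tj1], mirna_rev[mi1])
        duo2 = (target[tj2], mirna_rev[mi2])
        if duo1 in WATSON_CRICK and duo2 in WATSON_CRICK:
            energy += WC_STACK[step]
        else:
            energy += GU_STACK
        any_stack = True
    if not any_stack:
        return 0.0
    return min(energy, 0.0)


def duplex_energy(
    site_sequence: str,
    mirna: MiRNA,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> float:
    """Free energy (kcal/mol) of the most complementary duplex on a site."""
    target = dna_to_rna(site_sequence)
    if not target:
        return 0.0
    H, ptrH, ptrE, ptrF = _sw_matrices(target, mirna, params)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, len(H)):
        Hi = H[i]
        for j in range(1, len(Hi)):
            if Hi[j] > best:
                best, bi, bj = Hi[j], i, j
    if best <= 0:
        return 0.0
    _, pairs = _traceback(bi, bj, ptrH, ptrE, ptrF)
    return _alignment_energy(target, mirna.seq[::-1], pairs)


# ---------------------------------------------------------------------------
# Site enumeration and pair prediction


def _enumerate_sites(
    target: str, mirna: MiRNA, params: AlignmentParams, score_floor: float
) -> List[Tuple[float, int, int, List[Tuple[int, int]]]]:
    """Non-overlapping candidate sites with score >= score_floor.

    Candidates are the per-target-column alignment maxima; overlap resolution
    is greedy by descending score with ties broken by leftmost position.
    Returns (score, start, end, aligned pairs) tuples sorted by position.
    """
    H, ptrH, ptrE, ptrF = _sw_matrices(target, mirna, params)
    m, n = len(H) - 1, len(target)
    col_best: List[Tuple[float, int]] = [(0.0, 0)] * (n + 1)
    for i in range(1, m + 1):
        Hi = H[i]
        for j in range(1, n + 1):
            if Hi[j] > col_best[j][0]:
                col_best[j] = (Hi[j], i)

    candidates = []
    for j in range(1, n + 1):
        score, i = col_best[j]
        if score >= score_floor:
            tstart, pairs = _traceback(i, j, ptrH, ptrE, ptrF)
            candidates.append((score, tstart, j, pairs))
    candidates.sort(key=lambda c: (-c[0], c[1]))

    chosen: List[Tuple[float, int, int, List[Tuple[int, int]]]] = []
    occupied: List[Tuple[int, int]] = []
    for score, s, e, pairs in candidates:
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        chosen.append((score, s, e, pairs))
        occupied.append((s, e))
    chosen.sort(key=lambda c: c[1])
    return chosen


def predict_pair(
    circ_id: str,
    sequence: str,
    mirna: MiRNA,
    score_threshold: float = SCORE_THRESHOLD_LOW,
    energy_threshold: float = ENERGY_THRESHOLD,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> PairPrediction:
    """Predict all binding sites of one miRNA on one circRNA sequence.

    Sites are non-overlapping local alignment maxima with
    ``align_score >= score_threshold``; a site additionally needs
    ``duplex_energy <= energy_threshold`` to count toward ``n_sites`` (the
    dual-predictor agreement requirement).
    """
    target = dna_to_rna(sequence)
    pred = PairPrediction(
        circ_id=circ_id,
        mirna_id=mirna.id,
        score_threshold=score_threshold,
        energy_threshold=energy_threshold,
    )
    if not target or score_threshold == float("inf"):
        return pred
    mirna_rev = mirna.seq[::-1]
    seed_motif = revcomp_rna(mirna.seed)
    for score, s, e, pairs in _enumerate_sites(target, mirna, params, score_threshold):
        energy = _alignment_energy(target, mirna_rev, pairs)
        site_seq = target[s:e]
        pred.sites.append(
            BindingSite(
                circ_id=circ_id,
                mirna_id=mirna.id,
                target_start=s,
                target_end=e,
                align_score=score,
                duplex_energy=energy,
                seed_matched=seed_motif in site_seq,
            )
        )
    return pred


def predict_all(
    sequences: Mapping[str, str],
    mirnas: Sequence[MiRNA],
    score_threshold: float = SCORE_THRESHOLD_LOW,
    energy_threshold: float = ENERGY_THRESHOLD,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> List[PairPrediction]:
    """Predict binding sites for every circRNA x miRNA combination."""
    out = []
    for circ_id in sorted(sequences):
        seq = sequences[circ_id]
        for mirna in mirnas:
            out.append(
                predict_pair(
                    circ_id, seq, mirna, score_threshold, energy_threshold, params
                )
            )
    return out


def read_mirna_fasta(path) -> List[MiRNA]:
    from .sequences import read_fasta

    return [MiRNA(name, seq) for name, seq in read_fasta(path).items()]


def write_interaction_table(path, predictions: Sequence[PairPrediction]) -> None:
    """Interaction TSV: one row per circRNA-miRNA pair with >= 1 site."""
    with open(path, "w") as fh:
        fh.write(
            "circ_id\tmirna_id\tn_sites\tbest_score\tbest_energy\tpredicted_by_both\n"
        )
        for p in predictions:
            if not p.sites:
                continue
            fh.write(
                f"{p.circ_id}\t{p.mirna_id}\t{p.n_sites}\t{p.best_score:.1f}"
                f"\t{p.best_energy:.2f}\t{int(p.predicted_by_both)}\n"
            )


def write_site_bed(path, predictions: Sequence[PairPrediction]) -> None:
    """Site-level BED on circRNA-local coordinates (score = align score)."""
    with open(path, "w") as fh:
        for p in predictions:
            for s in p.sites:
                fh.write(
                    f"{s.circ_id}\t{s.target_start}\t{s.target_end}"
                    f"\t{s.mirna_id}\t{s.align_score:.0f}\t+\n"
                )
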