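"""Synthetic cohort generator: determinism, structure and planted truth."""

from __future__ import annotations

import hashlib
import os

import pytest

from circnet.callers import parse_caller_file
from circnet.models import read_bed12
from circnet.sequences import read_fasta, revcomp_rna, rna_to_dna
from circnet.simulate import SimConfig, generate_genome_and_models, simulate_all
from circnet.targets import MiRNA, extract_circ_sequence, seed_scan

from conftest import small_sim_config


def _tree_hashes(root):
    out = {}
    for dirpath, _, files in os.walk(root):
        for f in sorted(files):
            p = os.path.join(dirpath, f)
            rel = os.path.relpath(p, root)
            out[rel] = hashlib.sha256(open(p, "rb").read()).hexdigest()
    return out


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SimConfig(exonic_fraction=1.4)
    with pytest.raises(ValueError):
        SimConfig(mirna_length=6)
    with pytest.raises(ValueError):
        SimConfig(chrom_lengths={})
    with pytest.raises(ValueError):
        SimConfig(n_genes=0)


def test_chromosome_too_short_raises_sizing_error():
    cfg = small_sim_config(chrom_lengths={"chr1": 8_000}, n_genes=8)
    with pytest.raises(ValueError, match="too short"):
        generate_genome_and_models(cfg)


def test_requested_counts_forced_by_config(tmp_path):
    cfg = small_sim_config(
        chrom_lengths={"chr1": 100_000}, n_genes=5, n_circ_true=6,
        n_sponge_circ=1,
    )
    manifest = simulate_all(cfg, tmp_path)
    genome = read_fasta(manifest["genome"])
    assert list(genome) == ["chr1"]
    assert len(genome["chr1"]) == 100_000
    assert len(read_bed12(manifest["gene_models"])) == 5
    assert len(manifest["truth"].true_circles) == 6


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    cfg = small_sim_config(seed=11)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_all(cfg, a)
    simulate_all(small_sim_config(seed=11), b)
    assert _tree_hashes(a) == _tree_hashes(b)


def test_different_seed_changes_outputs(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_all(small_sim_config(seed=11), a)
    simulate_all(small_sim_config(seed=12), b)
    assert _tree_hashes(a) != _tree_hashes(b)


def test_fully_exonic_config_places_every_circle_in_exons():
    cfg = small_sim_config(exonic_fraction=1.0, intronic_fraction=0.0)
    truth = generate_genome_and_models(cfg)
    by_name = truth.transcript_by_name()
    for circ in truth.true_circles:
        t = by_name[circ.transcript_name]
        # interval-containment oracle: both boundaries inside exons and all
        # exon-overlap blocks cover the span's exonic part
        assert t.contains_in_exon(circ.start)
        assert t.contains_in_exon(circ.end, as_end=True)


def test_perfect_sensitivity_and_no_fp_reproduces_truth(tmp_path):
    from circnet.simulate import CallerProfile

    profiles = {
        t: CallerProfile(1.0, 0.0, 1.0)
        for t in ("ciri", "circexplorer", "find_circ", "knife")
    }
    cfg = small_sim_config(caller_profiles=profiles)
    manifest = simulate_all(cfg, tmp_path)
    truth_set = {
        (c.chrom, c.start, c.end) for c in manifest["truth"].true_circles
    }
    for tool, per_sample in manifest["callers"].items():
        called = set()
        for sample, path in per_sample.items():
            called |= {
                (r.chrom, r.start, r.end)
                for r in parse_caller_file(path, tool, sample)
            }
        assert called == truth_set


def test_zero_sensitivity_tool_emits_only_false_positives(tmp_path):
    from circnet.simulate import CallerProfile, default_caller_profiles

    profiles = default_caller_profiles()
    profiles["ciri"] = CallerProfile(0.0, 5.0, 1.0)
    cfg = small_sim_config(caller_profiles=profiles)
    manifest = simulate_all(cfg, tmp_path)
    truth_set = {
        (c.chrom, c.start, c.end) for c in manifest["truth"].true_circles
    }
    for sample, path in manifest["callers"]["ciri"].items():
        for r in parse_caller_file(path, "ciri", sample):
            assert (r.chrom, r.start, r.end) not in truth_set


def test_ciri_raw_starts_are_one_based(tmp_path, small_cohort):
    """Raw CIRI start fields exceed the other dialects' by exactly 1."""
    ciri_raw = {}
    for sample, path in small_cohort["callers"]["ciri"].items():
        for line in open(path):
            f = line.split("\t")
            ciri_raw[(f[1], int(f[3]), sample)] = int(f[2])
    matched = 0
    for sample, path in small_cohort["callers"]["find_circ"].items():
        for line in open(path):
            f = line.split("\t")
            key = (f[0], int(f[2]), sample)
            if key in ciri_raw:
                assert ciri_raw[key] == int(f[1]) + 1
                matched += 1
    assert matched > 0


def test_planted_sites_recoverable_by_exhaustive_motif_search(small_cohort):
    truth = small_cohort["truth"]
    genome = read_fasta(small_cohort["genome"])
    mirna_seqs = dict(truth.mirnas)
    by_name = truth.transcript_by_name()
    circles = truth.circle_by_id()
    for circ_id, mirna_id, n_planted in truth.planted_interactions:
        circ = circles[circ_id]
        t = by_name[circ.transcript_name]
        seq = extract_circ_sequence(circ, genome, t, junction_window=0)
        motif = rna_to_dna(revcomp_rna(mirna_seqs[mirna_id])).replace("T", "U")
        count = sum(
            1 for i in range(len(seq) - len(motif) + 1)
            if seq[i : i + len(motif)] == motif
        )
        assert count == n_planted
        # and the seed scanner sees at least that many seed complements
        hits = seed_scan(seq, MiRNA(mirna_id, mirna_seqs[mirna_id]))
        assert len(hits) >= n_planted


def test_zero_linear_class_rows_are_all_zero(small_cohort):
    import circnet.quantify as quantify

    truth = small_cohort["truth"]
    zero_ids = [
        c for c in truth.true_circles if c.ratio_class == "zero_linear"
    ]
    assert zero_ids
    for sample, path in small_cohort["linear"].items():
        table = quantify.read_linear_junction_tsv(path)
        for c in zero_ids:
            assert table[(c.chrom, c.start)] == 0
            assert table[(c.chrom, c.end)] == 0


def test_circle_dominant_class_yields_ratio_at_least_ten(small_cohort):
    import circnet.quantify as quantify

    truth = small_cohort["truth"]
    reads = truth.ensure_expression()
    linear = {
        s: quantify.read_linear_junction_tsv(p)
        for s, p in small_cohort["linear"].items()
    }
    dominant = [c for c in truth.true_circles if c.ratio_class == "circ_dominant"]
    assert dominant
    for c in dominant:
        counts = [
            quantify.JunctionCounts(
                nc=reads[c.id][s],
                nl5=linear[s][(c.chrom, c.start)],
                nl3=linear[s][(c.chrom, c.end)],
                sample_id=s,
            )
            for s in truth.config.sample_ids
        ]
        rows, _ = quantify.ratio_cohort_summary({c.id: counts})
        (row,) = rows
        assert not row["circ_only"]
        assert row["ratio"] >= 10
        assert row["ratio_class"] == "circ_dominant_ge10"


def test_linear_only_loci_absent_from_caller_files(small_cohort):
    import circnet.quantify as quantify

    truth = small_cohort["truth"]
    circle_coords = set()
    for c in truth.true_circles:
        circle_coords.add((c.chrom, c.start))
        circle_coords.add((c.chrom, c.end))
    sample = truth.config.sample_ids[0]
    table = quantify.read_linear_junction_tsv(small_cohort["linear"][sample])
    extra = set(table) - circle_coords
    assert extra, "expected linear-only splice sites in the linear TSV"


def test_target_db_common_core_matches_configured_fraction(small_cohort):
    from circnet.network import intersect_target_dbs, read_target_db

    truth = small_cohort["truth"]
    inter = intersect_target_dbs(
        small_cohort["targets_db1"], small_cohort["targets_db2"]
    )
    core = {(m.lower(), g.upper()) for m, g in truth.db_core}
    assert inter == core
    cfg = truth.config
    per_mirna_core = round(cfg.targets_per_mirna * cfg.db_common_fraction)
    assert len(inter) == per_mirna_core * cfg.n_mirnas


def test_zero_common_core_empties_db_intersection(tmp_path):
    from circnet.network import intersect_target_dbs

    cfg = small_sim_config(db_common_fraction=0.0, targets_per_mirna=10)
    manifest = simulate_all(cfg, tmp_path)
    inter = intersect_target_dbs(manifest["targets_db1"], manifest["targets_db2"])
    assert inter == set()
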