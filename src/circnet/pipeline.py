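"""End-to-end orchestration: simulate -> integrate -> annotate -> quantify ->
predict -> network -> enrich -> de, with a checksummed output manifest.

Every stage reads and writes plain-text TSV/JSON contracts, so any stage can
be rerun standalone or swapped for genuine tool outputs (e.g. real caller
files) without code changes. With a fixed config and seed a rerun is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, List, Optional

import importlib

# the package re-exports a function named `enrich`, which shadows the
# submodule on attribute lookup; resolve the module explicitly
enrich_mod = importlib.import_module("circnet.enrich")

from . import annotation as annotation_mod
from . import callers as callers_mod
from . import network as network_mod
from . import quantify as quantify_mod
from . import simulate as simulate_mod
from . import targets as targets_mod
from .config import PipelineConfig

log = logging.getLogger("circnet")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path, what: str):
    if path is None or not os.path.exists(path):
        raise FileNotFoundError(f"missing {what}: {path!r}")
    return path


class Pipeline:
    """Stage runner bound to one output directory and config."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        os.makedirs(config.outdir, exist_ok=True)
        self.artifacts: Dict[str, str] = {}

    # -- helpers ---------------------------------------------------------

    def _out(self, name: str) -> str:
        return os.path.join(self.cfg.outdir, name)

    def _record(self, key: str, path) -> str:
        self.artifacts[key] = str(path)
        return str(path)

    def _timed(self, stage: str):
        class _T:
            def __enter__(s):
                s.t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                return s

            def __exit__(s, exc_type, exc, tb):
                dt = time.perf_counter() - s.t0
                if exc_type is None:
                    log.info("stage %s: done in %.2fs", stage, dt)
                else:
                    log.error("stage %s: FAILED after %.2fs", stage, dt)
                return False

        return _T()

    # -- stages ----------------------------------------------------------

    def simulate(self, sim_config: Optional[simulate_mod.SimConfig] = None):
        cfg = self.cfg
        with self._timed("simulate"):
            sim = sim_config or simulate_mod.SimConfig(seed=cfg.seed)
            manifest = simulate_mod.simulate_all(sim, self._out("sim"))
        cfg.genome = manifest["genome"]
        cfg.gene_models = manifest["gene_models"]
        cfg.sample_sheet = manifest["sample_sheet"]
        cfg.mirna_fasta = manifest["mirna_fasta"]
        cfg.targets_db1 = manifest["targets_db1"]
        cfg.targets_db2 = manifest["targets_db2"]
        cfg.de_table = manifest["de_table"]
        cfg.gmt = manifest["gmt"]
        for key in ("genome", "gene_models", "sample_sheet", "mirna_fasta",
                    "targets_db1", "targets_db2", "de_table", "gmt",
                    "truth_json"):
            self._record(f"sim/{key}", manifest[key] if key != "truth_json"
                         else manifest["truth_json"])
        self._caller_paths = manifest["callers"]
        self._linear_paths = manifest["linear"]
        return manifest

    def integrate(self, caller_paths=None):
        cfg = self.cfg
        with self._timed("integrate"):
            caller_paths = caller_paths or getattr(self, "_caller_paths", None)
            if caller_paths is None:
                raise FileNotFoundError(
                    "no caller outputs; run simulate first or pass caller_paths"
                )
            groups = callers_mod.read_sample_sheet(
                _require(cfg.sample_sheet, "sample sheet")
            )
            records: List[callers_mod.CallerRecord] = []
            for tool, per_sample in sorted(caller_paths.items()):
                for sample, path in sorted(per_sample.items()):
                    records.extend(callers_mod.parse_caller_file(path, tool, sample))
            self.candidates = callers_mod.merge_candidates(
                records, min_reads=cfg.min_reads, sample_groups=groups
            )
            self.recurrent = callers_mod.filter_recurrent(
                self.candidates,
                cfg.recurrence_min_samples,
                cfg.recurrence_min_reads,
                cohort_size=len(groups),
            )
            stats = callers_mod.overlap_stats(self.candidates)
            callers_mod.write_candidate_table(
                self._record("candidates", self._out("candidates.tsv")),
                self.candidates,
            )
            with open(self._record("overlap_stats",
                                   self._out("overlap_stats.json")), "w") as fh:
                json.dump(stats, fh, indent=2, sort_keys=True)
                fh.write("\n")
        return self.candidates

    def annotate(self):
        cfg = self.cfg
        with self._timed("annotate"):
            from .models import read_bed12

            transcripts = read_bed12(_require(cfg.gene_models, "gene models"))
            self.annotated = annotation_mod.annotate(self.candidates, transcripts)
            self.transcripts = transcripts
            annotation_mod.write_annotation_table(
                self._record("annotation", self._out("annotation.tsv")),
                self.annotated,
            )
            with open(self._record("context_summary",
                                   self._out("context_summary.json")), "w") as fh:
                json.dump(annotation_mod.context_summary(self.annotated), fh,
                          indent=2, sort_keys=True)
                fh.write("\n")
        return self.annotated

    def quantify(self, linear_paths=None):
        with self._timed("quantify"):
            linear_paths = linear_paths or getattr(self, "_linear_paths", None)
            if linear_paths is None:
                raise FileNotFoundError("no linear junction TSVs available")
            linear = {
                s: quantify_mod.read_linear_junction_tsv(p)
                for s, p in sorted(linear_paths.items())
            }
            per_sample = quantify_mod.junction_counts_for_candidates(
                self.candidates, linear
            )
            self.ratio_rows, self.ratio_proportions = (
                quantify_mod.ratio_cohort_summary(per_sample)
            )
            quantify_mod.write_ratio_table(
                self._record("ratios", self._out("ratios.tsv")), self.ratio_rows
            )
        return self.ratio_rows

    def predict(self):
        cfg = self.cfg
        with self._timed("predict"):
            import pyfaidx

            genome = pyfaidx.Fasta(_require(cfg.genome, "genome FASTA"))
            mirnas = targets_mod.read_mirna_fasta(
                _require(cfg.mirna_fasta, "miRNA FASTA")
            )
            annotated_by_id = {a.id: a for a in getattr(self, "annotated", [])}
            window = max((len(m.seq) for m in mirnas), default=22) - 1
            seqs = {}
            for cand in self.recurrent:
                ann = annotated_by_id.get(cand.id)
                transcript = ann.transcript if ann is not None else None
                seqs[cand.id] = targets_mod.extract_circ_sequence(
                    cand, genome, transcript, junction_window=window
                )
            self.circ_sequences = seqs
            self.predictions = targets_mod.predict_all(
                seqs,
                mirnas,
                score_threshold=cfg.score_low,
                energy_threshold=cfg.energy_threshold,
            )
            targets_mod.write_interaction_table(
                self._record("interactions", self._out("interactions.tsv")),
                self.predictions,
            )
            targets_mod.write_site_bed(
                self._record("sites_bed", self._out("sites.bed")),
                self.predictions,
            )
        return self.predictions

    def network(self):
        cfg = self.cfg
        with self._timed("network"):
            pairs_db = network_mod.intersect_target_dbs(
                _require(cfg.targets_db1, "target DB 1"),
                _require(cfg.targets_db2, "target DB 2"),
            )
            degs = network_mod.read_de_table(_require(cfg.de_table, "DE table"))
            self.networks = {}
            for tier, score in ((network_mod.LOW, cfg.score_low),
                                (network_mod.HIGH, cfg.score_high)):
                lfc = 0.0 if tier == network_mod.LOW else cfg.de_lfc_cutoff
                net = network_mod.build_network(
                    self.predictions, pairs_db, degs, tier,
                    score_threshold=score, p_cutoff=cfg.de_p_cutoff,
                    lfc_cutoff=lfc,
                )
                self.networks[tier] = net
                network_mod.export_network(
                    net,
                    sif_path=self._record(f"network_{tier}_sif",
                                          self._out(f"network_{tier}.sif")),
                    graphml_path=self._record(f"network_{tier}_graphml",
                                              self._out(f"network_{tier}.graphml")),
                    stats_path=self._record(f"network_{tier}_stats",
                                            self._out(f"network_{tier}_stats.json")),
                )
        return self.networks

    def enrich(self):
        cfg = self.cfg
        with self._timed("enrich"):
            gene_sets = enrich_mod.parse_gmt(_require(cfg.gmt, "GMT"))
            degs = network_mod.read_de_table(_require(cfg.de_table, "DE table"))
            universe = [d.gene for d in degs]
            input_genes = sorted(self.networks[network_mod.LOW].genes)
            self.enrichment = enrich_mod.enrich(
                input_genes, gene_sets, universe, fdr_cutoff=cfg.fdr_cutoff
            )
            enrich_mod.write_enrichment_table(
                self._record("enrichment", self._out("enrichment.tsv")),
                self.enrichment,
            )
        return self.enrichment

    def de(self):
        cfg = self.cfg
        with self._timed("de"):
            groups = callers_mod.read_sample_sheet(
                _require(cfg.sample_sheet, "sample sheet")
            )
            self.circ_de, self.circ_de_skipped = enrich_mod.circ_de_test(
                self.candidates, groups
            )
            enrich_mod.write_circde_table(
                self._record("circ_de", self._out("circ_de.tsv")), self.circ_de
            )
        return self.circ_de

    # -- run-all ---------------------------------------------------------

    def run_all(self, sim_config: Optional[simulate_mod.SimConfig] = None) -> str:
        """Run every stage and write the checksum manifest; returns its path."""
        self.simulate(sim_config)
        self.integrate()
        self.annotate()
        self.quantify()
        self.predict()
        self.network()
        self.enrich()
        self.de()
        manifest = {
            key: {"path": path, "sha256": _sha256(path)}
            for key, path in sorted(self.artifacts.items())
            if os.path.isfile(path)
        }
        path = self._out("manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
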