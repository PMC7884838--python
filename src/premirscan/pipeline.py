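"""End-to-end pipeline: simulate -> stats -> featurize -> bench -> scan ->
confirm -> ssr -> report, with a checksummed run manifest.

Every output file starts with a provenance header recording the tool version,
a hash of the effective configuration, and a UTC timestamp; the timestamp line
is excluded from checksums so identical config + seed reproduce identical
manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .classify import bench, reports_to_tsv, select_best, split_dataset, train_classifier
from .composition import (composition_table, load_quince_te_counts)
from .homology import HomologyConfig, matches_to_tsv, search
from .kmers import featurize_dataset
from .scan import (ScanConfig, loci_to_bed6, loci_to_gff3, merge_hits,
                   planted_recovery, scan)
from .seqio import assembly_stats, write_fasta
from .simulate import (SimulationConfig, crop_to_scan_windows, make_coding_set,
                       make_genome, make_hairpin_set, write_truth_bed)
from .ssr import SSRConfig, find_ssrs_in_records, loci_to_frame, ssr_summary

log = logging.getLogger("premirscan")

STAGES = ("simulate", "stats", "featurize", "bench", "scan", "confirm", "ssr", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "premirscan_run"
    seed: int = 0
    k: int = 4
    train_fraction: float = 0.7
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    ssr: SSRConfig = field(default_factory=SSRConfig)
    #: confirm at most this many candidate loci (highest probability first);
    #: the synthetic scan over-calls on i.i.d. background, and confirming
    #: every call is homology work that adds nothing to the demonstration
    confirm_top_n: int = 500
    log_level: str = "INFO"

    def to_json(self) -> str:
        # out_dir is excluded: where a run writes must not change what it
        # computes, so checksums and the config hash ignore it
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return json.dumps(d, indent=2, sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return (f"# premirscan v{__version__} config={config.config_hash()}\n"
            f"# generated={ts}\n")


def _checksum(path: Path) -> str:
    """sha256 of a file, skipping the volatile timestamp header line."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for line in fh:
            if line.startswith(b"# generated="):
                continue
            h.update(line)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(name)s %(levelname)s [%(message)s]")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.simulation.seed = config.seed
    artifacts: dict[str, str] = {}

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = _checksum(path)
        return path

    # simulate
    log.info("stage=simulate seed=%d", config.seed)
    positives = make_hairpin_set(config.simulation)
    negatives = make_coding_set(config.simulation)
    contigs, truth = make_genome(config.simulation)
    emit("hairpins.fasta", lambda p: write_fasta(positives, p))
    emit("coding.fasta", lambda p: write_fasta(negatives, p))
    emit("genome.fasta", lambda p: write_fasta(contigs, p))
    emit("truth.bed", lambda p: write_truth_bed(truth, p))
    emit("config.json", lambda p: p.write_text(config.to_json() + "\n"))

    # stats
    log.info("stage=stats contigs=%d", len(contigs))
    stats = assembly_stats(contigs)
    emit("assembly_stats.tsv", lambda p: p.write_text(_header(config) + stats.to_tsv()))

    # featurize
    log.info("stage=featurize k=%d", config.k)
    matrix = featurize_dataset(positives, negatives, k=config.k)
    emit("features.tsv", lambda p: matrix.to_tsv(p))

    # bench
    log.info("stage=bench algorithms=5")
    reports, models, rocs = bench(matrix, seed=config.seed,
                                  train_fraction=config.train_fraction)
    best = select_best(reports)
    emit("bench_metrics.tsv", lambda p: reports_to_tsv(reports, p))

    def write_roc(p):
        with open(p, "w") as fh:
            fh.write("algorithm\tfpr\ttpr\tauc\n")
            for alg, rc in rocs.items():
                for x, y in zip(rc.fpr, rc.tpr):
                    fh.write(f"{alg}\t{x:.6f}\t{y:.6f}\t{rc.auc:.6f}\n")

    emit("roc_points.tsv", write_roc)

    # scan with an SVM trained on window-sized crops, matching what it will see
    log.info("stage=scan threshold=%s", config.scan.probability_threshold)
    scan_fm = featurize_dataset(
        crop_to_scan_windows(positives, config.scan.window_length, config.seed),
        crop_to_scan_windows(negatives, config.scan.window_length, config.seed),
        k=config.k,
    )
    scan_train, _ = split_dataset(scan_fm, config.train_fraction, config.seed)
    scan_model = train_classifier(scan_train, "SVM", seed=config.seed)
    hits = scan(contigs, scan_model, config.scan)
    loci = merge_hits(hits, config.scan)
    emit("scan_hits.tsv", lambda p: hits.to_csv(p, sep="\t", index=False))
    emit("candidate_loci.tsv", lambda p: loci.to_csv(p, sep="\t", index=False))
    emit("candidate_loci.bed", lambda p: loci_to_bed6(loci, p))
    emit("candidate_loci.gff3", lambda p: loci_to_gff3(loci, p))
    recovery = (planted_recovery(loci, truth)
                if (truth["kind"] == "hairpin").any() and not loci.empty else 0.0)

    # confirm candidates against the positive reference set
    log.info("stage=confirm candidates=%d", len(loci))
    queries = []
    contig_by_id = {c.id: c for c in contigs}
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    confirm_loci = loci.sort_values("max_probability", ascending=False) \
                       .head(config.confirm_top_n)
    for r in confirm_loci.itertuples(index=False):
        seq = str(contig_by_id[r.contig_id].seq)[r.start:r.end]
        queries.append(SeqRecord(Seq(seq), id=r.locus_id, description=""))
    probs = {r.locus_id: float(r.max_probability) for r in loci.itertuples(index=False)}
    matches = search(queries, positives, config.homology) if queries else []
    emit("homology_matches.tsv", lambda p: matches_to_tsv(matches, p, probs))

    # ssr
    log.info("stage=ssr")
    ssr_loci = find_ssrs_in_records(contigs, config.ssr)
    summary = ssr_summary(ssr_loci, stats.total_length)
    emit("ssr_loci.tsv", lambda p: loci_to_frame(ssr_loci).to_csv(p, sep="\t", index=False))
    emit("ssr_summary.tsv", lambda p: p.write_text(_header(config) + summary.to_tsv()))

    # report: bundled TE composition arithmetic + run summary
    log.info("stage=report")
    te = composition_table(load_quince_te_counts())
    emit("te_composition.tsv", lambda p: te.to_csv(p, sep="\t", index=False))

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "best_algorithm": best,
        "n_candidate_loci": int(len(loci)),
        "n_homology_matches": len(matches),
        "n_ssr_loci": len(ssr_loci),
        "planted_hairpin_recovery": recovery,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
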