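"""End-to-end orchestration: scan -> regulon -> abundance -> clustering.

``run_pipeline`` consumes on-disk inputs (genome FASTA + GFF3 per MAG, a
MEME motif file, count TSVs, an expression series TSV, optionally an
operon table), runs every stage, and writes per-TF-per-MAG BED hit
files, regulon TSVs, an abundance table, cluster assignments and
Fig-style cluster summary TSVs, plus a JSON run manifest with the
config hash and seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as mio
from .abundance import MagStats, abundance_table, rpkm
from .cluster import ClusterConfig, gibbs_cluster, member_trajectories, prepare_series, summarize_clusters
from .motif import Background
from .scan import ScanConfig, predict_regulon

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Bad or incomplete pipeline configuration (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Paths and stage settings for one pipeline run.

    ``genomes`` maps mag_id -> {"fasta": path, "gff": path}.  The
    clustering stage pools predicted-regulon genes per TF across MAGs
    by default; set ``cluster_per_mag`` to partition within each MAG.
    """

    genomes: dict[str, dict[str, str]]
    motifs: str
    outdir: str
    dna_counts: str | None = None
    mrna_counts: str | None = None
    expression: str | None = None
    operons: str | None = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    cluster_per_mag: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.genomes:
            raise ConfigError("no genomes configured")
        for mag_id, paths in self.genomes.items():
            for key in ("fasta", "gff"):
                if key not in paths:
                    raise ConfigError(f"genome {mag_id}: missing {key} path")
                if not Path(paths[key]).exists():
                    raise ConfigError(f"genome {mag_id}: {key} file not found: {paths[key]}")
        if not Path(self.motifs).exists():
            raise ConfigError(f"motif file not found: {self.motifs}")
        for name in ("dna_counts", "mrna_counts", "expression", "operons"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p}")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict.

    Stages with missing optional inputs are skipped and noted in the
    manifest.  Determinism: identical config (including seed) produces
    byte-identical outputs.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "metaregulon",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "outputs": {},
        "stages": {},
    }

    annotations = {
        mag_id: mio.GenomeAnnotation.from_files(mag_id, p["fasta"], p["gff"])
        for mag_id, p in cfg.genomes.items()
    }
    operon_map = mio.read_operon_table(cfg.operons) if cfg.operons else None

    # background from the pooled promoters being scanned, then rebuild
    # the motif log-odds on that background
    from .scan import extract_promoters
    pooled = [p.seq for ann in annotations.values()
              for p in extract_promoters(ann, cfg.scan)]
    background = Background.from_sequences(pooled)
    pwms = mio.read_motif_meme(cfg.motifs)
    pwms = [mio.Pwm.from_probabilities(p.tf_name, p.probabilities(), background)
            for p in pwms]
    manifest["stages"]["background"] = {b: round(float(q), 4) for b, q in
                                        zip("ACGT", background.freqs)}

    # scan + retention per TF x MAG
    regulon_rows = []
    regulon_genes: dict[str, set[str]] = {}
    for pwm in pwms:
        for mag_id, ann in annotations.items():
            pred, hits = predict_regulon(pwm, ann, cfg.scan, operon_map)
            bed = outdir / f"hits_{pwm.tf_name}_{mag_id}.bed"
            mio.write_bed_hits(hits, bed)
            manifest["outputs"][bed.name] = str(bed)
            for g in sorted(pred.genes):
                regulon_rows.append({
                    "tf_name": pwm.tf_name, "mag_id": mag_id, "gene_id": g,
                    "retention_cutoff": pred.retention_cutoff,
                    "n_scanned_hits": pred.n_scanned_hits,
                })
            regulon_genes.setdefault(pwm.tf_name, set()).update(pred.genes)
    regulon_df = pd.DataFrame(
        regulon_rows,
        columns=["tf_name", "mag_id", "gene_id", "retention_cutoff", "n_scanned_hits"],
    )
    regulon_path = outdir / "regulons.tsv"
    regulon_df.to_csv(regulon_path, sep="\t", index=False)
    manifest["outputs"]["regulons.tsv"] = str(regulon_path)
    manifest["stages"]["scan"] = {"n_regulon_genes": int(len(regulon_df))}

    # abundance
    if cfg.dna_counts and cfg.mrna_counts:
        dna = mio.read_count_table(cfg.dna_counts)
        mrna = mio.read_count_table(cfg.mrna_counts)
        gene_to_mag = {g.gene_id: mag_id for mag_id, ann in annotations.items()
                       for g in ann.genes}
        mrna_by_mag = mrna.iloc[:, 0].groupby(
            mrna.index.map(gene_to_mag)).sum()
        stats = [
            MagStats(mag_id=mag_id,
                     genome_size_bp=ann.genome_size_bp,
                     dna_reads=int(dna.iloc[:, 0].get(mag_id, 0)),
                     mrna_reads=int(mrna_by_mag.get(mag_id, 0)))
            for mag_id, ann in annotations.items()
        ]
        ab = abundance_table(stats)
        ab_path = outdir / "abundance.tsv"
        ab.to_csv(ab_path, sep="\t")
        manifest["outputs"]["abundance.tsv"] = str(ab_path)

        lengths = pd.Series({g.gene_id: g.length for ann in annotations.values()
                             for g in ann.genes})
        rpkm_df = rpkm(mrna, lengths)
        rpkm_path = outdir / "rpkm.tsv"
        rpkm_df.to_csv(rpkm_path, sep="\t")
        manifest["outputs"]["rpkm.tsv"] = str(rpkm_path)
        manifest["stages"]["abundance"] = {"n_mags": len(stats)}
    else:
        manifest["stages"]["abundance"] = "skipped (no count tables)"

    # expression clustering of regulon genes
    if cfg.expression:
        series_raw = pd.read_csv(cfg.expression, sep="\t")
        all_regulon = set().union(*regulon_genes.values()) if regulon_genes else set()
        groups: dict[str, pd.DataFrame]
        if cfg.cluster_per_mag:
            gene_to_mag = {g.gene_id: mag_id for mag_id, ann in annotations.items()
                           for g in ann.genes}
            series_raw["_group"] = series_raw["gene_id"].map(gene_to_mag)
            groups = {k: v.drop(columns="_group")
                      for k, v in series_raw.groupby("_group")}
        else:
            groups = {"all": series_raw}
        assign_rows, summary_frames, traj_frames = [], [], []
        for group_name, sub in groups.items():
            sub = sub[sub["gene_id"].isin(all_regulon)] if all_regulon else sub
            if sub["gene_id"].nunique() < 2:
                logger.warning("clustering: group %s has <2 regulon genes; skipped", group_name)
                continue
            series = prepare_series(sub)
            ccfg = ClusterConfig(**{**asdict(cfg.cluster), "seed": cfg.seed})
            result = gibbs_cluster(series, ccfg)
            for g, c in sorted(result.assignment.items()):
                assign_rows.append({"group": group_name, "gene_id": g, "cluster": c})
            summary = summarize_clusters(result, series)
            summary.insert(0, "group", group_name)
            summary_frames.append(summary)
            traj = member_trajectories(result, series)
            traj.insert(0, "group", group_name)
            traj_frames.append(traj)
        if assign_rows:
            pd.DataFrame(assign_rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            pd.concat(summary_frames).to_csv(outdir / "cluster_summaries.tsv",
                                             sep="\t", index=False)
            pd.concat(traj_frames).to_csv(outdir / "cluster_trajectories.tsv",
                                          sep="\t", index=False)
            for name in ("clusters.tsv", "cluster_summaries.tsv", "cluster_trajectories.tsv"):
                manifest["outputs"][name] = str(outdir / name)
            manifest["stages"]["cluster"] = {"n_genes": len(assign_rows)}
    else:
        manifest["stages"]["cluster"] = "skipped (no expression table)"

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest.json"] = str(manifest_path)
    return manifest
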