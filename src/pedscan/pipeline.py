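"""End-to-end orchestration: simulate or load -> IBD -> transfer ->
selection scan -> LD/clusters -> QTL overlap.

Every stage consumes and produces plain TSV/BED/CSV files in the output
directory, so each one can be re-run independently.  A run manifest
records the seed, a hash of the resolved configuration and the status of
every stage; reruns with the same configuration are byte-identical for
all deterministic stages.  The global seed fans out to per-stage seeds
derived by hashing the stage name, so adding a stage never perturbs the
randomness of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import PEDIGREE_PANELS, study_pedigree
from .ibd import DetectorParams, all_pairs_ibd, ibd_summary, segments_to_frame
from .io import (
    GenotypeMatrix,
    MarkerMap,
    read_features_bed,
    read_genotypes,
    read_pedigree,
    write_features_bed,
    write_segments_bed,
)
from .ld import call_clusters, clusters_to_frame, fit_decay, mean_r2, pairwise_r2
from .overlap import candidate_genes, intersect_qtl_ibd, qtl_in_ibd_tally, selection_annotate
from .scan import sliding_scan
from .simulate import SimConfig, derive_seed, simulate_pedigree, synthetic_features, true_ibd_segments
from .transfer import aggregate_transfer

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)        # SimConfig fields
    genotypes: str | None = None                   # used when simulate=False
    marker_map: str | None = None
    pedigree: str | None = None
    qtl_bed: str | None = None
    genes_bed: str | None = None
    detector: dict = field(default_factory=dict)   # DetectorParams fields
    scan: dict = field(default_factory=lambda: {"window": 15, "step": 1,
                                                "convention": "main_text"})
    ld: dict = field(default_factory=lambda: {"max_distance_bp": 10_000_000})
    clusters: dict = field(default_factory=dict)   # gap_mb; default = fitted decay

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genotypes", "marker_map", "pedigree"):
                if getattr(self, name) is None:
                    raise ValueError(
                        f"simulate=false requires the '{name}' input path"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    On stage failure the manifest marks the failing stage, partial
    outputs are retained, and the exception propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pedscan_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    current_stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        current_stage = "inputs"
        if config.simulate:
            sim_fields = dict(config.sim)
            sim_fields.setdefault("selection_targets", [])
            sim_fields["selection_targets"] = [tuple(t) for t in sim_fields["selection_targets"]]
            sim_fields["rng_seed"] = derive_seed(config.seed, "simulate")
            sim_config = SimConfig(**sim_fields)
            ped = study_pedigree()
            result = simulate_pedigree(ped, sim_config)
            gm, mm = result.genotypes, result.marker_map
            sim_config.to_yaml(outdir / "sim_config.yaml")
            mm.write_tsv(outdir / "marker_map.tsv")
            gm.write_tsv(outdir / "genotypes.tsv")
            ped.write_csv(outdir / "pedigree.csv")
            truth = []
            for final in ("Tapidor", "Ningyou7"):
                for anc in PEDIGREE_PANELS[final]:
                    if anc != final:
                        truth.extend(true_ibd_segments(result, anc, final))
            write_segments_bed(truth, outdir / "truth_segments.bed")
            qtls, genes = synthetic_features(result)
            write_features_bed(qtls, outdir / "qtl.synthetic.bed")
            write_features_bed(genes, outdir / "genes.synthetic.bed")
        else:
            mm = MarkerMap.read_tsv(config.marker_map)
            gm, qc = read_genotypes(config.genotypes, mm)
            ped = read_pedigree(config.pedigree)
            qtls = read_features_bed(config.qtl_bed, "QTL") if config.qtl_bed else []
            genes = read_features_bed(config.genes_bed, "gene") if config.genes_bed else []
        panels = {
            label: [s for s in members if s in gm.sample_ids]
            for label, members in PEDIGREE_PANELS.items()
        }
        panels = {k: v for k, v in panels.items() if len(v) >= 3}
        if not panels:
            panels = {"all": list(gm.sample_ids)}
        manifest["stages"]["inputs"] = "ok"

        # ----------------------------------------------------------- ibd
        current_stage = "ibd"
        params = DetectorParams(**config.detector)
        pairs = []
        for members in panels.values():
            pairs.extend(combinations(members, 2))
        segments = all_pairs_ibd(gm, pairs, params)
        write_segments_bed(segments, outdir / "ibd.bed")
        summary = ibd_summary(segments)
        summary.to_csv(outdir / "ibd_summary.tsv", sep="\t", index=False)
        manifest["stages"]["ibd"] = "ok"

        # ------------------------------------------------------- transfer
        current_stage = "transfer"
        finals = [label for label in panels if label in gm.sample_ids]
        rows = []
        per_pair = summary[summary["sample_a"] != "(all)"]
        for _, r in per_pair.iterrows():
            a, b = r["sample_a"], r["sample_b"]
            for anc, desc in ((a, b), (b, a)):
                if desc in finals:
                    rows.append(
                        {"pedigree": desc, "ancestor": anc, "descendant": desc,
                         "n_ibd": r["count_total"], "total_size_mb": r["length_total_mb"]}
                    )
        if rows:
            table = aggregate_transfer(pd.DataFrame(rows), ped)
            table.to_csv(outdir / "transfer_table.tsv", sep="\t", index=False)
        manifest["stages"]["transfer"] = "ok"

        # ----------------------------------------------------------- scan
        current_stage = "scan"
        scan_cfg = dict(config.scan)
        convention = scan_cfg.pop("convention", "main_text")
        scans = {}
        for label, members in panels.items():
            scan_df = sliding_scan(gm, members, **scan_cfg)
            scan_df.to_csv(outdir / f"scan_{label}.tsv", sep="\t", index=False)
            scans[label] = scan_df
        manifest["stages"]["scan"] = "ok"

        # ------------------------------------------------------------- ld
        current_stage = "ld"
        all_lines = sorted({s for members in panels.values() for s in members})
        ld_pairs = pairwise_r2(gm, all_lines, **config.ld)
        fit = fit_decay(ld_pairs)
        ld_report = {
            "mean_r2": mean_r2(ld_pairs),
            "n_pairs": int(len(ld_pairs)),
            "beta_per_bp": fit.beta,
            "decay_distance_mb": fit.decay_distance_mb,
            "rss": fit.rss,
        }
        (outdir / "ld_fit.json").write_text(json.dumps(ld_report, indent=2, sort_keys=True))
        manifest["stages"]["ld"] = "ok"

        # ------------------------------------------------------- overlap
        current_stage = "overlap"
        annotated = None
        if qtls:
            overlaps = intersect_qtl_ibd(qtls, segments)
            tally = qtl_in_ibd_tally(qtls, overlaps)
            tally.to_csv(outdir / "qtl_in_ibd.tsv", sep="\t", index=False)
            gene_table = candidate_genes(overlaps, genes, ped)
            scan_any = next(iter(scans.values()))
            annotated = selection_annotate(gene_table, scan_any, convention)
            annotated.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
        manifest["stages"]["overlap"] = "ok"

        # ------------------------------------------------------ clusters
        current_stage = "clusters"
        if genes:
            gap_mb = config.clusters.get("gap_mb") or (
                fit.decay_distance_mb if fit.decay_distance_mb not in (0, float("inf"))
                else 0.7
            )
            labels = {}
            if annotated is not None:
                for _, r in annotated.iterrows():
                    if r["pedigree_label"]:
                        labels.setdefault(r["gene_id"], set()).add(r["pedigree_label"])
            clusters = call_clusters(genes, gap_mb, labels)
            clusters_to_frame(clusters).to_csv(
                outdir / "clusters.tsv", sep="\t", index=False
            )
        manifest["stages"]["clusters"] = "ok"
    except Exception:
        manifest["stages"][current_stage] = "failed"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
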