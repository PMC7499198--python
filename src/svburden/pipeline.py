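"""End-to-end orchestration: read -> filter -> classify -> merge ->
carrier matrix -> per-stratum association -> meta -> rare/recurrent ->
overlap -> gene-set tally, with plain-text artifacts at every stage.

All outputs are TSV/BED/JSON with a provenance header (producing command,
config hash, seed) and no timestamps, so identical configs give identical
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .classify import classify_all, merge_loci, build_carrier_matrix
from .genome import GenomeIndex, load_annotation
from .model import (SVBurdenModel, rare_recurrent_filter, read_gmt)
from .sv_io import filter_calls, read_manifest, read_sv_vcf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ConfigError", "DataError"]


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    annotation: str
    vcfs: list[str]
    manifest: str
    out_dir: str
    gene_sets: str | None = None
    annotation_dialect: str = "gtf"
    min_len: int = 50
    require_pass: bool = True
    merge_window: int = 50
    reciprocal_overlap: float = 0.8
    alpha: float = 0.05
    risk_only: bool = True
    yates: bool = False
    bonferroni_family: str = "per_class"
    min_case_occurrence: int = 2
    max_control_freq: float = 0.005
    case_only: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)      # output location does not affect results
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        for p in [self.annotation, self.manifest, *self.vcfs]:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.gene_sets and not Path(self.gene_sets).exists():
            raise ConfigError(f"gene set file does not exist: {self.gene_sets}")


def _provenance(cfg: RunConfig, stage: str) -> str:
    return f"# svburden {stage} config={cfg.digest()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg, stage))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a run report dict.

    Writes (under ``cfg.out_dir``): assignments.tsv, clusters.bed,
    association_<stratum>.tsv per stratum, meta.tsv, rare_recurrent.tsv,
    overlap.json, geneset_tally.tsv and report.json.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_annotation"
    try:
        with open(cfg.annotation) as fh:
            genes = load_annotation(fh, dialect=cfg.annotation_dialect)
        index = GenomeIndex(genes)

        stage = "read_vcfs"
        raw = []
        for v in sorted(cfg.vcfs):
            raw.extend(read_sv_vcf(v))
        manifest = read_manifest(cfg.manifest)

        stage = "filter"
        kept = filter_calls(raw, min_len=cfg.min_len,
                            require_pass=cfg.require_pass)
        logger.info("filter: %d of %d records kept", len(kept), len(raw))

        stage = "classify"
        assignments = classify_all(kept, index)
        adf = pd.DataFrame(
            [(a.sv.sample_id, a.sv.id, a.sv.sv_type, a.sv.chrom, a.sv.start,
              a.sv.end, a.sv.length, a.gene_id, a.region_class, a.distance)
             for a in assignments],
            columns=["sample_id", "sv_id", "sv_type", "chrom", "start",
                     "end", "length", "gene_id", "region_class", "distance"])
        adf = adf.sort_values(list(adf.columns), ignore_index=True)
        _write_tsv(adf, out / "assignments.tsv", cfg, "annotate")
        class_counts = adf["region_class"].value_counts().to_dict()

        stage = "merge"
        clusters = merge_loci(assignments, window=cfg.merge_window,
                              reciprocal_overlap=cfg.reciprocal_overlap)
        with open(out / "clusters.bed", "w") as fh:
            fh.write(_provenance(cfg, "merge"))
            for c in clusters:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t"
                         f"{c.occurrence}\t{c.sv_type}\n")

        stage = "associate"
        matrix = build_carrier_matrix(assignments, manifest, strict=False)
        model = SVBurdenModel(
            matrix, manifest, alpha=cfg.alpha, yates=cfg.yates,
            risk_only=cfg.risk_only, bonferroni_family=cfg.bonferroni_family)
        results = model.fit()
        for s in results.strata:
            df = results.frame(s).copy()
            df["key"] = df["key"].map(lambda k: "|".join(map(str, k)))
            _write_tsv(df, out / f"association_{s}.tsv", cfg, "associate")

        stage = "meta"
        if results.meta is not None:
            mdf = results.meta.copy()
            mdf["key"] = mdf["key"].map(lambda k: "|".join(map(str, k)))
            _write_tsv(mdf, out / "meta.tsv", cfg, "meta")
        else:
            _write_tsv(pd.DataFrame(
                columns=["key", "strata", "k", "meta_stat", "meta_p"]),
                out / "meta.tsv", cfg, "meta")

        stage = "rare_recurrent"
        rare = rare_recurrent_filter(
            clusters, manifest, min_case_occurrence=cfg.min_case_occurrence,
            max_control_freq=cfg.max_control_freq, case_only=cfg.case_only)
        rdf = pd.DataFrame(
            [(c.cluster_id, c.chrom, c.start, c.end, c.sv_type, c.occurrence,
              ";".join(f"{g}:{rc}" for g, rc in c.gene_classes))
             for c in rare],
            columns=["cluster_id", "chrom", "start", "end", "sv_type",
                     "occurrence", "gene_classes"])
        _write_tsv(rdf, out / "rare_recurrent.tsv", cfg, "recur")

        stage = "overlap"
        if len(results.strata) >= 2:
            overlap = results.overlap()
        else:
            overlap = {}
        with open(out / "overlap.json", "w") as fh:
            json.dump({"_provenance": {"config": cfg.digest(),
                                       "seed": cfg.seed},
                       "overlap": overlap}, fh, indent=1, sort_keys=True)

        stage = "geneset"
        if cfg.gene_sets:
            tally = results.geneset_tally(read_gmt(cfg.gene_sets))
        else:
            tally = pd.DataFrame(columns=["gene_set", "gene_id", "stratum",
                                          "region_class", "sv_type",
                                          "odds_ratio", "chi2_p", "tier"])
        _write_tsv(tally, out / "geneset_tally.tsv", cfg, "geneset")

        stage = "report"
        report = {
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "n_input_records": len(raw),
            "n_pass_filter": len(kept),
            "n_assignments": len(adf),
            "class_counts": class_counts,
            "class_proportions": {
                k: v / len(adf) for k, v in class_counts.items()} if len(adf) else {},
            "n_clusters": len(clusters),
            "n_rare_recurrent": len(rdf),
            "strata": {
                s: {"tested": len(results.frame(s)),
                    "significant": int(results.frame(s)["significant"].sum())}
                for s in results.strata},
            "n_meta_keys": 0 if results.meta is None else len(results.meta),
            "artifacts": sorted(p.name for p in out.iterdir()
                                if p.name != "report.json"),
            "summary": results.summary(),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        return report
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc
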