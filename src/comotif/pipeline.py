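"""End-to-end pipeline: curation -> scanning -> screens -> reports."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import curation, screen
from .curation import CurationReport, Experiment, Peak
from .motifs import PWM, load_motifs
from .screen import ScanContext, ScreenThresholds, SpecificCall

logger = logging.getLogger(__name__)

STAGES = ("curation", "scan", "screen")


@dataclass
class PipelineConfig:
    genome: str
    peaks_dir: str
    metadata: str
    motifs: str
    canonical_map: str
    out_dir: str
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    jaspar_pseudocount: float = 0.25
    scan_pseudocount: float = 0.1
    scale: float = 1000.0
    bg_floor: float = 0.01
    n_null: int = 999
    seed: int = 0
    excluded_tfs: tuple[str, ...] = tuple(sorted(curation.DEFAULT_EXCLUDED_TFS))
    classes: tuple[str, ...] = (screen.PROXIMAL, screen.DISTAL)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = ScreenThresholds(**raw.pop("thresholds", {}))
        if "excluded_tfs" in raw:
            raw["excluded_tfs"] = tuple(raw["excluded_tfs"])
        if "classes" in raw:
            raw["classes"] = tuple(raw["classes"])
        return cls(thresholds=thresholds, **raw)

    def validate_paths(self) -> None:
        for name in ("genome", "peaks_dir", "metadata", "motifs",
                     "canonical_map"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: CurationReport
    experiments: list[Experiment]
    calls: list[SpecificCall]
    paths: dict[str, Path]


def _load_compendium(config: PipelineConfig):
    experiments = curation.load_experiments(Path(config.metadata).read_text())
    canon = curation.load_canonical_map(Path(config.canonical_map).read_text())
    pwms = load_motifs(config.motifs, pseudocount=config.jaspar_pseudocount)
    pwms_by_id = {p.motif_id: p for p in pwms}
    for tf, ids in canon.items():
        missing = [m for m in ids if m not in pwms_by_id]
        if missing:
            raise ValueError(
                f"canonical map references unknown motif(s) for {tf!r}: "
                f"{', '.join(missing)}"
            )
    peaks: list[Peak] = []
    peaks_dir = Path(config.peaks_dir)
    for exp in experiments:
        bed = peaks_dir / f"{exp.exp_id}.bed"
        if not bed.exists():
            raise FileNotFoundError(f"peak file missing: {bed}")
        peaks.extend(curation.load_peaks(bed.read_text(), exp.exp_id))
    return experiments, canon, pwms, pwms_by_id, peaks


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] = STAGES,
) -> PipelineResult:
    """Execute curation -> scanning -> screening, writing stage artifacts.

    ``stages`` may stop the run early (e.g. ``("curation",)`` writes only the
    curation report and HOT BED). Outputs for identical inputs and seed are
    byte-identical.
    """
    t0 = time.time()
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    experiments, canon, pwms, pwms_by_id, peaks = _load_compendium(config)
    report = CurationReport(rows=[])
    report.add("loaded", len(experiments), len(peaks), 0)

    retained, exp_rows = curation.filter_experiments(
        experiments, canon, excluded_tfs=config.excluded_tfs
    )
    retained_ids = {e.exp_id for e in retained}
    for stage_name, n_exps, _removed in exp_rows:
        kept_peaks = [p for p in peaks if p.exp_id in retained_ids]
        report.add(stage_name, n_exps, len(kept_peaks),
                   report.rows[-1][2] - len(kept_peaks))
    peaks = [p for p in peaks if p.exp_id in retained_ids]

    hot = curation.find_hot_regions(
        peaks, n_experiments=len(retained),
        hot_fraction=config.thresholds.hot_fraction,
    )
    cold, n_removed = curation.remove_hot_peaks(peaks, hot)
    report.add("hot_peaks", len(retained), len(cold), n_removed)
    logger.info("curation done in %.1fs: %d experiments, %d COLD peaks",
                time.time() - t0, len(retained), len(cold))

    paths["curation_report"] = out_dir / "curation_report.tsv"
    report.write_tsv(paths["curation_report"])
    paths["hot_regions"] = out_dir / "hot_regions.bed"
    curation.write_bed(hot, paths["hot_regions"])
    _write_manifest(config, out_dir)
    paths["manifest"] = out_dir / "run_manifest.json"
    if "scan" not in stages:
        return PipelineResult(report, retained, [], paths)

    cold = curation.extract_sequences(cold, config.genome)
    peaks_by_exp: dict[str, list[Peak]] = {e.exp_id: [] for e in retained}
    for p in cold:
        peaks_by_exp[p.exp_id].append(p)

    ctx = ScanContext(
        pseudocount=config.scan_pseudocount,
        scale=config.scale,
        presence_p=config.thresholds.presence_p,
        bg_floor=config.bg_floor,
    )
    partitions: dict[str, screen.PeakPartition] = {}
    presence_by_exp: dict[str, pd.DataFrame] = {}
    canon_by_exp: dict[str, list[str]] = {}
    t1 = time.time()
    for exp in retained:
        presence = screen.experiment_presence(peaks_by_exp[exp.exp_id], pwms, ctx)
        presence_by_exp[exp.exp_id] = presence
        canon_by_exp[exp.exp_id] = list(canon[exp.tf_name])
        partitions[exp.exp_id] = screen.partition_peaks(
            exp, peaks_by_exp[exp.exp_id], canon, pwms_by_id, ctx,
            presence=presence,
        )
    records = screen.abundance_table(partitions, presence_by_exp, canon_by_exp)
    records = [r for r in records if r.cls in config.classes]
    logger.info("scanning done in %.1fs: %d abundance records",
                time.time() - t1, len(records))

    flags = screen.enrichment_flags(records, pct=config.thresholds.pct)
    paths["records"] = out_dir / "abundance_records.tsv"
    screen.records_frame(records, flags).to_csv(
        paths["records"], sep="\t", index=False, float_format="%.6g"
    )
    if "screen" not in stages:
        return PipelineResult(report, retained, [], paths)

    retained_pairs = screen.ubiquity_filter(
        flags, n_exps=len(retained), thresholds=config.thresholds
    )
    calls = screen.cell_type_specific_screen(
        flags, records, retained, config.thresholds, retained_pairs
    )
    calls += screen.tf_specific_screen(
        flags, records, retained, config.thresholds, retained_pairs
    )
    calls = screen.remove_similar(
        calls, canon, pwms_by_id, retained,
        thresholds=config.thresholds, seed=config.seed, n_null=config.n_null,
    )
    report_paths = screen.write_reports(calls, records, flags, out_dir)
    paths.update({name: p for name, p in report_paths.items()})
    logger.info("pipeline done in %.1fs: %d specific calls",
                time.time() - t0, len(calls))
    return PipelineResult(report, retained, calls, paths)


def _write_manifest(config: PipelineConfig, out_dir: Path) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
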