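"""End-to-end orchestration: qc -> structure -> roh -> inbreeding ->
islands -> report, with deterministic TSV artifacts.

Every artifact starts with provenance comment lines (tool version, config
hash, seed) and stores full precision; rounding happens only in the
display tables. Rerunning with an identical config reproduces byte-
identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import GenotypePanel, QCConfig, apply_qc, read_panel, write_panel
from .inbreeding import (
    correlate_estimators,
    inbreeding_table,
    summarise_inbreeding,
)
from .popstruct import flag_cluster_outliers, ibs_similarity, pca_from_similarity
from .roh_detection import (
    DEFAULT_L_AUT,
    ROHParams,
    classify_and_summarise,
    detect_roh,
    mean_heterozygosity,
    segments_to_bed,
    segments_to_frame,
)
from .roh_islands import (
    annotate_island_ld,
    call_islands,
    islands_to_frame,
    roh_frequency,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class IslandConfig:
    threshold: float = 0.20
    min_island_snps: int = 5
    max_join_gap_bp: int = 500_000


@dataclass
class RunConfig:
    input_prefix: str = ""
    input_format: str = "bed"
    output_dir: str = "rohscan_run"
    seed: int = 0
    n_pcs: int = 2
    outlier_n_sd: float = 3.0
    drop_outliers: bool = True
    l_aut: float = DEFAULT_L_AUT
    qc: QCConfig = field(default_factory=QCConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    islands: IslandConfig = field(default_factory=IslandConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("qc", QCConfig), ("roh", ROHParams), ("islands", IslandConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_artifact(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# rohscan {__version__}\n"
        f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_artifact(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(cfg: RunConfig, panel: GenotypePanel | None = None) -> dict[str, Path]:
    """Run every stage and return the artifact paths.

    ``panel`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``cfg.input_prefix``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if panel is None:
        panel = stage("read")(lambda: read_panel(cfg.input_prefix, cfg.input_format))

    # qc ----------------------------------------------------------------
    def _qc():
        filtered, report = apply_qc(panel, cfg.qc)
        _write_artifact(report.to_frame(), out / "qc_report.tsv", cfg)
        return filtered

    panel_qc = stage("qc")(_qc)
    artifacts["qc_report"] = out / "qc_report.tsv"

    # population structure ----------------------------------------------
    def _structure():
        sim = ibs_similarity(panel_qc)
        pcs = pca_from_similarity(sim, max(cfg.n_pcs, 2))
        labels = panel_qc.samples.set_index("sample_id")["population"]
        flagged = flag_cluster_outliers(pcs, labels, cfg.outlier_n_sd)
        sim_df = sim.to_frame().reset_index(names="sample_id")
        _write_artifact(sim_df, out / "ibs_similarity.tsv", cfg)
        pc_df = pcs.to_frame()
        pc_df.insert(1, "population", labels.loc[pc_df["sample_id"]].to_numpy())
        pc_df["outlier"] = pc_df["sample_id"].isin(flagged)
        ve = pd.DataFrame(
            {
                "component": [f"PC{i+1}" for i in range(len(pcs.variance_explained))],
                "variance_explained": pcs.variance_explained,
            }
        )
        _write_artifact(pc_df, out / "pca_coordinates.tsv", cfg)
        _write_artifact(ve, out / "pca_variance.tsv", cfg)
        if cfg.drop_outliers and flagged:
            keep = ~panel_qc.samples["sample_id"].isin(flagged).to_numpy()
            return panel_qc.subset(sample_mask=keep)
        return panel_qc

    panel_final = stage("popstruct")(_structure)
    artifacts["ibs_similarity"] = out / "ibs_similarity.tsv"
    artifacts["pca_coordinates"] = out / "pca_coordinates.tsv"
    artifacts["pca_variance"] = out / "pca_variance.tsv"

    pops = panel_final.samples["population"]
    pop_sizes = pops.value_counts().to_dict()
    pop_of = panel_final.samples.set_index("sample_id")["population"].to_dict()

    # roh ----------------------------------------------------------------
    def _roh():
        segments = []
        for pop in sorted(pop_sizes):
            mask = (pops == pop).to_numpy()
            sub = panel_final.subset(sample_mask=mask)
            params = cfg.roh.resolved(sub.n_samples, sub.n_snps, mean_heterozygosity(sub))
            segments.extend(detect_roh(sub, params))
        seg_df = segments_to_frame(segments, pop_of)
        _write_artifact(seg_df, out / "roh_segments.tsv", cfg)
        bed = segments_to_bed(segments)
        bed_path = out / "roh_segments.bed"
        with open(bed_path, "w") as fh:
            bed.to_csv(fh, sep="\t", index=False, header=False)
        summary = classify_and_summarise(segments, pop_of, pop_sizes, cfg.l_aut)
        _write_artifact(summary, out / "roh_class_summary.tsv", cfg)
        return segments

    segments = stage("roh")(_roh)
    artifacts["roh_segments"] = out / "roh_segments.tsv"
    artifacts["roh_class_summary"] = out / "roh_class_summary.tsv"

    # inbreeding ----------------------------------------------------------
    def _inbreeding():
        records = inbreeding_table(panel_final, segments, cfg.l_aut)
        _write_artifact(records, out / "inbreeding.tsv", cfg)
        _write_artifact(correlate_estimators(records), out / "inbreeding_correlations.tsv", cfg)
        _write_artifact(summarise_inbreeding(records), out / "inbreeding_summary.tsv", cfg)
        return records

    stage("inbreeding")(_inbreeding)
    artifacts["inbreeding"] = out / "inbreeding.tsv"
    artifacts["inbreeding_correlations"] = out / "inbreeding_correlations.tsv"
    artifacts["inbreeding_summary"] = out / "inbreeding_summary.tsv"

    # islands -------------------------------------------------------------
    def _islands():
        tracks, islands = [], []
        for pop in sorted(pop_sizes):
            pop_segs = [s for s in segments if pop_of[s.sample_id] == pop]
            track = roh_frequency(pop_segs, panel_final.markers, pop_sizes[pop])
            track.insert(0, "population", pop)
            tracks.append(track)
            pop_islands = call_islands(
                track,
                cfg.islands.threshold,
                cfg.islands.min_island_snps,
                cfg.islands.max_join_gap_bp,
                population=pop,
            )
            mask = (pops == pop).to_numpy()
            annotate_island_ld(pop_islands, panel_final.subset(sample_mask=mask))
            islands.extend(pop_islands)
        _write_artifact(pd.concat(tracks, ignore_index=True), out / "roh_frequency.tsv", cfg)
        _write_artifact(islands_to_frame(islands), out / "roh_islands.tsv", cfg)
        return islands

    stage("islands")(_islands)
    artifacts["roh_frequency"] = out / "roh_frequency.tsv"
    artifacts["roh_islands"] = out / "roh_islands.tsv"

    # report --------------------------------------------------------------
    render_tables(out, cfg)
    artifacts["table1"] = out / "table_roh_classes.tsv"
    artifacts["table2"] = out / "table_inbreeding_means.tsv"
    artifacts["table3"] = out / "table_inbreeding_correlations.tsv"
    artifacts["manhattan_track"] = out / "manhattan_track.tsv"
    return artifacts


def render_tables(run_dir: str | Path, cfg: RunConfig | None = None) -> dict[str, Path]:
    """Render display tables (2-dp rounding) from the full-precision
    artifacts of a run directory. Raises naming the missing artifact."""
    run_dir = Path(run_dir)
    cfg = cfg or RunConfig(output_dir=str(run_dir))
    needed = {
        "roh_class_summary": run_dir / "roh_class_summary.tsv",
        "inbreeding_summary": run_dir / "inbreeding_summary.tsv",
        "inbreeding_correlations": run_dir / "inbreeding_correlations.tsv",
        "roh_frequency": run_dir / "roh_frequency.tsv",
    }
    for name, path in needed.items():
        if not path.exists():
            raise PipelineError(f"stage 'report' failed: missing artifact {name} ({path})")

    summary = read_artifact(needed["roh_class_summary"])
    t1 = summary.copy()
    for c in ("percentage", "mean_length_mb", "sd_length_mb", "genome_coverage_pct"):
        t1[c] = t1[c].round(2)
    _write_artifact(t1, run_dir / "table_roh_classes.tsv", cfg)

    inb = read_artifact(needed["inbreeding_summary"])
    t2 = inb.assign(
        mean=inb["mean"].round(3), sd=inb["sd"].round(3), se=inb["se"].round(3)
    )[["population", "coefficient", "mean", "sd", "se", "n"]]
    _write_artifact(t2, run_dir / "table_inbreeding_means.tsv", cfg)

    corr = read_artifact(needed["inbreeding_correlations"])
    t3 = corr.assign(pearson_r=corr["pearson_r"].round(2))
    _write_artifact(t3, run_dir / "table_inbreeding_correlations.tsv", cfg)

    track = read_artifact(needed["roh_frequency"])
    manh = track[["population", "chromosome", "position_bp", "fraction"]].copy()
    manh["percent"] = (100.0 * manh.pop("fraction")).round(3)
    _write_artifact(manh, run_dir / "manhattan_track.tsv", cfg)

    return {
        "table1": run_dir / "table_roh_classes.tsv",
        "table2": run_dir / "table_inbreeding_means.tsv",
        "table3": run_dir / "table_inbreeding_correlations.tsv",
        "manhattan_track": run_dir / "manhattan_track.tsv",
    }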