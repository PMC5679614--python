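"""Pipeline orchestration: simulate -> fit -> summarize -> stats -> report.

A run is driven by a :class:`PipelineConfig` (YAML-serializable, CLI flags
take precedence over file values, which take precedence over built-in
defaults).  Each stage records a signature (hash of its inputs and the
config fields it depends on) in the run manifest; re-running with
unchanged inputs skips completed stages, and changing e.g. the fit mode
re-runs fitting and everything downstream while leaving simulation
untouched.  A subject with missing or broken files is reported and
skipped; the remaining subjects proceed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .fitting import (
    FieldGradientMap,
    FitOptions,
    MultiEchoImage,
    NavigatorSeries,
    estimate_field,
    fit_volume,
    navigator_correct,
)
from .roi import ROILabelMap, SkullScaling, summarize_subject
from .signal_model import AcquisitionParams
from .stats import BatteryConfig, MS_GROUPS, ancova_compare, bh_fdr, run_correlation_battery
from .synthetic import FIXTURE_REGIONS, CohortSpec, derive_seed, make_end_to_end_fixture

__all__ = ["PipelineConfig", "RunManifest", "ConfigError", "run_all", "report", "STAGES"]

STAGES = ("simulate", "fit", "summarize", "stats", "report")


class ConfigError(ValueError):
    """Malformed pipeline configuration; raised before any stage runs."""


@dataclass
class PipelineConfig:
    input_dir: str = "study"
    output_dir: str = "out"
    seed: int = 1
    simulate: bool = True
    snr: float = 100.0
    mode: str = "zeta"
    delta_omega: float = 70.0
    macro_mode: str = "model"
    alpha: float = 0.05
    regions: tuple = FIXTURE_REGIONS
    ancova_regions: tuple = ("hippocampus", "amygdala")
    resume: bool = True
    # override of the generator's group sizes (HC/RRMS/SPMS/PPMS); None
    # keeps the standard cohort composition
    cohort_sizes: dict | None = None

    def validate(self) -> None:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode not in ("zeta", "zeta+domega"):
            problems.append(f"mode must be 'zeta' or 'zeta+domega', got {self.mode!r}")
        if self.macro_mode not in ("model", "predivide"):
            problems.append(f"macro_mode must be 'model' or 'predivide', got {self.macro_mode!r}")
        if self.snr is not None and self.snr <= 0:
            problems.append(f"snr must be > 0, got {self.snr}")
        if not self.simulate and not Path(self.input_dir).exists():
            problems.append(f"input_dir does not exist: {self.input_dir}")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["regions"] = list(d["regions"])
        d["ancova_regions"] = list(d["ancova_regions"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path, **overrides):
        try:
            d = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config file {path}: {e}") from e
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        d.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**d)
        cfg.regions = tuple(cfg.regions)
        cfg.ancova_regions = tuple(cfg.ancova_regions)
        return cfg

    def fit_options(self, noise_sigma=None) -> FitOptions:
        return FitOptions(
            mode=self.mode,
            delta_omega_fixed=self.delta_omega,
            macro_mode=self.macro_mode,
            noise_sigma=noise_sigma,
        )


@dataclass
class RunManifest:
    version: str = "0.1.0"
    config_hash: str = ""
    stages: dict = dc_field(default_factory=dict)
    outputs: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "config_hash": self.config_hash,
             "stages": self.stages, "outputs": self.outputs,
             "warnings": self.warnings}, indent=1, default=str))

    @classmethod
    def load(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(version=d["version"], config_hash=d["config_hash"],
                   stages=d["stages"], outputs=d["outputs"], warnings=d["warnings"])


def _sha(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _stage_done(manifest: RunManifest, prev: RunManifest | None, stage: str,
                signature: str, outputs: list[Path], resume: bool) -> bool:
    if (
        resume
        and prev is not None
        and prev.stages.get(stage, {}).get("signature") == signature
        and all(Path(p).exists() for p in outputs)
    ):
        manifest.stages[stage] = dict(prev.stages[stage], status="skipped")
        return True
    return False


def _finish_stage(manifest: RunManifest, stage: str, signature: str,
                  outputs: list[Path], t0: float) -> None:
    manifest.stages[stage] = dict(
        signature=signature, status="completed", seconds=round(time.time() - t0, 3)
    )
    for p in outputs:
        manifest.outputs[str(p)] = _sha(p)


def run_all(config: PipelineConfig, log=print) -> RunManifest:
    """Execute every stage in order, honoring resume semantics.

    Returns the run manifest (also written to ``<output_dir>/manifest.json``).
    """
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_obj(asdict(config)))
    manifest_path = outdir / "manifest.json"
    prev = RunManifest.load(manifest_path) if manifest_path.exists() else None

    # ---- simulate -------------------------------------------------------
    if config.simulate:
        sig = _hash_obj(dict(seed=config.seed, snr=config.snr, regions=config.regions,
                             sizes=config.cohort_sizes))
        cohort_path = indir / "cohort.tsv"
        t0 = time.time()
        if not _stage_done(manifest, prev, "simulate", sig, [cohort_path], config.resume):
            log("[simulate] generating synthetic study")
            spec_kwargs = dict(seed=derive_seed(config.seed, 0), regions=config.regions)
            if config.cohort_sizes is not None:
                spec_kwargs["n_per_group"] = dict(config.cohort_sizes)
            make_end_to_end_fixture(
                config.seed, indir,
                cohort_spec=CohortSpec(**spec_kwargs),
                snr=config.snr,
            )
            _finish_stage(manifest, "simulate", sig, [cohort_path], t0)
    if not (indir / "cohort.tsv").exists():
        raise FileNotFoundError(f"no cohort table at {indir / 'cohort.tsv'}")
    cohort = io.read_tsv(indir / "cohort.tsv")

    # ---- fit + summarize ------------------------------------------------
    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    summary_path = outdir / "region_summaries.tsv"
    input_sigs = {}
    for sid in cohort.subject_id:
        stem = indir / "subjects" / sid
        mag = stem.with_name(sid + "_mag.nii")
        input_sigs[sid] = _sha(mag) if mag.exists() else "missing"
    fit_sig = _hash_obj(dict(mode=config.mode, delta_omega=config.delta_omega,
                             macro_mode=config.macro_mode, inputs=input_sigs))
    t0 = time.time()
    if not _stage_done(manifest, prev, "fit", fit_sig, [summary_path], config.resume):
        log("[fit] voxelwise fitting + [summarize] region aggregation")
        summaries = []
        for sid in cohort.subject_id:
            try:
                row = _fit_one_subject(config, indir, maps_dir, sid, cohort)
            except FileNotFoundError as e:
                msg = f"subject {sid} incomplete, skipped: {e}"
                manifest.warnings.append(msg)
                log("[fit] WARNING " + msg)
                continue
            summaries.append(row)
        if not summaries:
            raise RuntimeError("no subject could be processed")
        io.write_tsv(pd.concat(summaries, ignore_index=True), summary_path)
        _finish_stage(manifest, "fit", fit_sig, [summary_path], t0)
        manifest.stages["summarize"] = manifest.stages["fit"]
    else:
        manifest.stages["summarize"] = dict(manifest.stages["fit"])

    # ---- stats ----------------------------------------------------------
    stats_path = outdir / "stat_results.tsv"
    stats_sig = _hash_obj(dict(alpha=config.alpha, fit=fit_sig,
                               ancova=config.ancova_regions))
    t0 = time.time()
    if not _stage_done(manifest, prev, "stats", stats_sig, [stats_path], config.resume):
        log("[stats] group comparisons and correlation battery")
        summaries = io.read_tsv(summary_path)
        stats_df = compute_stats(summaries, cohort, config)
        io.write_tsv(stats_df, stats_path)
        _finish_stage(manifest, "stats", stats_sig, [stats_path], t0)

    # ---- report ---------------------------------------------------------
    t0 = time.time()
    report_paths = [outdir / "report_R2t.tsv", outdir / "report_NV.tsv",
                    outdir / "report.txt"]
    rep_sig = _hash_obj(dict(stats=stats_sig, alpha=config.alpha))
    if not _stage_done(manifest, prev, "report", rep_sig, report_paths, config.resume):
        log("[report] formatted tables")
        stats_df = io.read_tsv(stats_path)
        report(stats_df, config, outdir)
        _finish_stage(manifest, "report", rep_sig, report_paths, t0)

    manifest.save(manifest_path)
    return manifest


def _fit_one_subject(config, indir, maps_dir, sid, cohort) -> pd.DataFrame:
    stem = indir / "subjects" / sid
    for suffix in ("_mag.nii", "_phase.nii", ".json", "_labels.nii", "_labels.tsv"):
        if not stem.with_name(sid + suffix).exists():
            raise FileNotFoundError(stem.with_name(sid + suffix))
    data, affine, echo_times = io.load_multiecho(stem)
    acq = AcquisitionParams(
        te_first=echo_times[0],
        te_spacing=echo_times[1] - echo_times[0] if len(echo_times) > 1 else 0.004,
        n_echoes=len(echo_times),
    )
    labels_arr, _ = io.load_nifti(stem.with_name(sid + "_labels.nii"))
    labelmap = ROILabelMap(
        labels=np.asarray(labels_arr, dtype=np.int32),
        label_table=io.read_tsv(stem.with_name(sid + "_labels.tsv")),
    )
    from .synthetic import WM_LABEL  # mask matches the generator convention
    mask = (labelmap.labels > 0) & (labelmap.labels != WM_LABEL)
    image = MultiEchoImage(data=data, acq=acq, affine=affine, brain_mask=mask)

    nav_path = stem.with_name(sid + "_nav.tsv")
    if nav_path.exists():
        nav = NavigatorSeries(io.read_tsv(nav_path).phase_rad.to_numpy())
        image = navigator_correct(image, nav)
    field = estimate_field(image)
    noise_sigma = None
    if config.snr:
        noise_sigma = 100.0 / config.snr  # generator's gm_s0 convention
    qmaps = fit_volume(image, field, config.fit_options(noise_sigma=noise_sigma))

    io.save_nifti(qmaps.r2t_star_map.astype(np.float32), affine,
                  maps_dir / f"{sid}_r2tstar.nii")
    io.save_nifti(qmaps.quality_mask.astype(np.uint8), affine,
                  maps_dir / f"{sid}_quality.nii")
    srow = cohort[cohort.subject_id == sid].iloc[0]
    scaling = SkullScaling(float(srow.scaling_factor))
    return summarize_subject(
        qmaps.r2t_star_map, labelmap, scaling, acq.voxel_volume, sid,
        quality_mask=qmaps.quality_mask, region_set=config.regions,
    )


def fit_study(config: PipelineConfig, log=print) -> Path:
    """Fit + summarize only (no simulation, statistics or report).

    Reads an existing study directory and writes per-subject maps plus the
    concatenated region-summary TSV; missing subjects are skipped with a
    warning.  Returns the summary path.
    """
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    maps_dir = outdir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    cohort = io.read_tsv(indir / "cohort.tsv")
    summaries = []
    for sid in cohort.subject_id:
        try:
            summaries.append(_fit_one_subject(config, indir, maps_dir, sid, cohort))
        except FileNotFoundError as e:
            log(f"[fit] WARNING subject {sid} incomplete, skipped: {e}")
    if not summaries:
        raise RuntimeError("no subject could be processed")
    summary_path = outdir / "region_summaries.tsv"
    io.write_tsv(pd.concat(summaries, ignore_index=True), summary_path)
    return summary_path


def summarize_maps(config: PipelineConfig, log=print) -> Path:
    """Recompute region summaries from previously fitted maps on disk."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    maps_dir = outdir / "maps"
    cohort = io.read_tsv(indir / "cohort.tsv")
    rows = []
    for sid in cohort.subject_id:
        map_path = maps_dir / f"{sid}_r2tstar.nii"
        stem = indir / "subjects" / sid
        if not map_path.exists():
            log(f"[summarize] WARNING no fitted map for {sid}, skipped")
            continue
        r2t, _ = io.load_nifti(map_path)
        quality, _ = io.load_nifti(maps_dir / f"{sid}_quality.nii")
        labelmap = ROILabelMap(
            labels=np.asarray(io.load_nifti(stem.with_name(sid + "_labels.nii"))[0],
                              dtype=np.int32),
            label_table=io.read_tsv(stem.with_name(sid + "_labels.tsv")),
        )
        srow = cohort[cohort.subject_id == sid].iloc[0]
        rows.append(summarize_subject(
            np.asarray(r2t, dtype=float), labelmap,
            SkullScaling(float(srow.scaling_factor)),
            AcquisitionParams().voxel_volume, sid,
            quality_mask=np.asarray(quality, dtype=bool),
            region_set=config.regions,
        ))
    if not rows:
        raise RuntimeError("no fitted maps found")
    summary_path = outdir / "region_summaries.tsv"
    io.write_tsv(pd.concat(rows, ignore_index=True), summary_path)
    return summary_path


def compute_stats(summaries: pd.DataFrame, cohort: pd.DataFrame,
                  config: PipelineConfig) -> pd.DataFrame:
    """Correlation battery plus ANCOVA group contrasts, FDR per family."""
    battery = run_correlation_battery(
        summaries, cohort, BatteryConfig(alpha=config.alpha)
    )
    merged = summaries.merge(cohort, on="subject_id")
    anc_rows = []
    for measure, col in (("R2t*", "median_r2t_star"), ("NV", "normalized_volume")):
        for region in config.ancova_regions:
            for hemi in ("left", "right"):
                cell = merged[(merged.region_name == region) & (merged.hemisphere == hemi)]
                cell = cell[cell[col].notna()]
                if cell.empty or cell.group.nunique() < 2:
                    continue
                try:
                    res = ancova_compare(cell[col], cell.group, cell.age, cell.gender)
                except ValueError:
                    continue
                for _, c in res.contrasts.iterrows():
                    anc_rows.append(
                        dict(
                            region_name=region, hemisphere=hemi, measure=measure,
                            test_name=f"ancova:{c.contrast}", method="ancova",
                            estimate=c.estimate, statistic=c.statistic, df=c.df,
                            p_raw=c.p_raw, n=res.n,
                            covariates="age,gender",
                        )
                    )
    anc = pd.DataFrame(anc_rows)
    if not anc.empty:
        anc["p_fdr"] = np.nan
        # hemispheres are separate FDR families
        for (_, _), idx in anc.groupby(["measure", "hemisphere"]).groups.items():
            sub = anc.loc[idx]
            anc.loc[sub.index, "p_fdr"] = bh_fdr(sub["p_raw"].to_numpy())
        anc["significant"] = anc["p_fdr"] < config.alpha
        anc["analysis_id"] = (anc["measure"] + ":ancova:" + anc["region_name"] + ":"
                              + anc["hemisphere"] + ":" + anc["test_name"])
    return pd.concat([battery, anc], ignore_index=True)


def report(stats_df: pd.DataFrame, config: PipelineConfig, outdir) -> list[Path]:
    """Per-measure region x test grids of (r, adjusted p); significance is
    adjusted-p < alpha.  Emits machine-readable TSVs plus a text rendering."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    lines = [f"Association report (FDR families per measure/method; alpha={config.alpha})"]
    for measure, fname in (("R2t*", "report_R2t.tsv"), ("NV", "report_NV.tsv")):
        sub = stats_df[
            (stats_df.get("measure") == measure)
            & (stats_df.get("method") != "ancova")
        ] if not stats_df.empty else pd.DataFrame()
        path = outdir / fname
        if sub.empty:
            io.write_tsv(pd.DataFrame(columns=["region", "hemisphere"]), path)
            paths.append(path)
            continue
        grid = sub.pivot_table(
            index=["region_name", "hemisphere"], columns="test_name",
            values=["estimate", "p_fdr"], aggfunc="first",
        )
        flat = pd.DataFrame(index=grid.index)
        for test in sorted(sub.test_name.unique()):
            for stat, suffix in (("estimate", "_r"), ("p_fdr", "_p_fdr")):
                col = (stat, test)
                flat[f"{test}{suffix}"] = grid[col] if col in grid.columns else np.nan
        flat = flat.reset_index().rename(
            columns={"region_name": "region"})
        io.write_tsv(flat, path)
        paths.append(path)
        lines.append(f"\n== {measure} ==")
        for _, row in sub.sort_values(["region_name", "hemisphere", "test_name"]).iterrows():
            mark = " *" if bool(row.get("significant")) else ""
            lines.append(
                f"  {row.region_name:<18s} {row.hemisphere:<5s} {row.test_name:<10s} "
                f"r={row.estimate:+.3f} p_fdr={row.p_fdr:.4f} n={int(row.n)}{mark}"
            )
    text_path = outdir / "report.txt"
    text_path.write_text("\n".join(lines) + "\n")
    paths.append(text_path)
    return paths
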