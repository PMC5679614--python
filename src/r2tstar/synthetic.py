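"""Synthetic phantoms and cohorts with known ground truth.

Every stage of the pipeline is testable without any scanner data:

* :func:`make_phantom` builds a piecewise-constant digital phantom (CSF
  slab, white-matter filler, labeled gray-matter regions per hemisphere),
  synthesizes the complex multi-echo signal from the forward decay model
  with a smooth B0 field, per-excitation navigator phase drift, and
  complex Gaussian noise, and returns the ground-truth maps alongside.
* :func:`make_cohort` draws a cohort (healthy controls and three MS
  subtypes) with designed group effects on regional R2t* and volume and
  clinical scores constructed to hit target partial correlations given
  the covariate model.
* :func:`make_end_to_end_fixture` writes a complete miniature study to
  disk in the same NIfTI/TSV formats the real-data path consumes.

R2t* truths are anchored to physiology: about 1 s^-1 in CSF and 15-20
s^-1 in brain tissue.  All generators are pure functions of their spec
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .fitting import MultiEchoImage, NavigatorSeries, QMaps
from .roi import ROILabelMap
from .signal_model import AcquisitionParams, fs_lookup

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "PhantomOutput",
    "make_phantom",
    "make_cohort",
    "make_end_to_end_fixture",
    "FIXTURE_REGIONS",
]

#: Reduced region set used by the miniature fixture (a 16x16x8 grid cannot
#: hold all eleven limbic regions per hemisphere at useful sizes).
FIXTURE_REGIONS = ("hippocampus", "amygdala", "parahippocampal", "insula")

CSF_LABEL = 1
WM_LABEL = 2


def derive_seed(seed: int, index: int) -> int:
    """Stable per-subject sub-seed below 2**31."""
    return int(np.random.default_rng([seed, index]).integers(2**31))


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, tissue truths, field/drift/noise model and seed.

    ``region_r2t`` / ``region_n_voxels`` key on (region_name, hemisphere);
    unspecified regions use ``gm_r2t`` and half the block capacity.  Noise
    is complex Gaussian on the channel-combined voxel signal with
    sigma = gm_s0 / snr (magnitude therefore Rician); ``snr=None`` means
    noiseless.  B0 is a linear field in mm coordinates.
    """

    seed: int
    shape: tuple = (16, 16, 8)
    acq: AcquisitionParams = dc_field(default_factory=AcquisitionParams)
    regions: tuple = FIXTURE_REGIONS
    region_r2t: dict = dc_field(default_factory=dict)
    region_n_voxels: dict = dc_field(default_factory=dict)
    csf_r2t: float = 1.0
    wm_r2t: float = 19.0
    gm_r2t: float = 17.0
    csf_s0: float = 120.0
    wm_s0: float = 90.0
    gm_s0: float = 100.0
    csf_zeta: float = 0.0
    wm_zeta: float = 0.01
    gm_zeta: float = 0.015
    delta_omega: float = 70.0
    b0_offset_hz: float = 0.0
    b0_gradient_hz_per_mm: tuple = (0.0, 0.0, 0.0)
    nav_amplitude_rad: float = 0.0
    nav_frequency_hz: float = 1.0
    snr: float | None = None
    mask_wm: bool = False

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0 or None")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class PhantomOutput:
    image: MultiEchoImage
    navigator: NavigatorSeries
    truth: QMaps
    labels: ROILabelMap
    noise_sigma: float


def block_capacity(shape: tuple) -> int:
    """Voxel capacity of one gray-matter region block for a given grid."""
    nx, ny, nz = shape
    return 5 * 3 * max(nz - 2, 1)


def build_label_map(shape, regions, region_n_voxels) -> ROILabelMap:
    """Geometric label volume: CSF slab (y rows 0-1), per-hemisphere GM
    region blocks, WM everywhere else.

    Each region occupies the first ``n`` voxels (fixed raster order) of a
    5 x 3 x (nz-2) block; left-hemisphere blocks sit at low x, right at
    high x.  Left labels are 100+i, right labels 200+i.
    """
    nx, ny, nz = shape
    if ny < 2 + 3 * len(regions) or nx < 13:
        raise ValueError(f"grid {shape} too small for {len(regions)} region bands")
    labels = np.full(shape, WM_LABEL, dtype=np.int32)
    labels[:, :2, :] = CSF_LABEL
    rows = [
        dict(label_id=CSF_LABEL, region_name="csf", hemisphere="none"),
        dict(label_id=WM_LABEL, region_name="wm", hemisphere="none"),
    ]
    cap = block_capacity(shape)
    for i, region in enumerate(regions):
        y0 = 2 + 3 * i
        for hemi, label_id, x0 in (("left", 100 + i, 1), ("right", 200 + i, nx - 6)):
            n = int(region_n_voxels.get((region, hemi), cap // 2))
            n = int(np.clip(n, 1, cap))
            block = np.argwhere(np.ones((5, 3, nz - 2), dtype=bool))
            chosen = block[:n]
            for dx, dy, dzi in chosen:
                labels[x0 + dx, y0 + dy, 1 + dzi] = label_id
            rows.append(dict(label_id=label_id, region_name=region, hemisphere=hemi))
    return ROILabelMap(labels=labels, label_table=pd.DataFrame(rows))


def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Synthesize a multi-echo phantom and its ground truth.

    Complex voxel signal = magnitude forward model x exp(i 2 pi b0 TE)
    x exp(i phi_nav(row)) + complex Gaussian noise; deterministic for a
    fixed seed, and exactly equal to the forward model at snr=None.
    """
    rng = np.random.default_rng(spec.seed)
    labelmap = build_label_map(spec.shape, spec.regions, spec.region_n_voxels)
    labels = labelmap.labels
    nx, ny, nz = spec.shape
    te = spec.acq.echo_times
    dz = spec.acq.voxel_size[2]

    r2t = np.full(spec.shape, spec.wm_r2t)
    s0 = np.full(spec.shape, spec.wm_s0)
    zeta = np.full(spec.shape, spec.wm_zeta)
    r2t[labels == CSF_LABEL] = spec.csf_r2t
    s0[labels == CSF_LABEL] = spec.csf_s0
    zeta[labels == CSF_LABEL] = spec.csf_zeta
    for _, row in labelmap.label_table.iterrows():
        if row.label_id in (CSF_LABEL, WM_LABEL):
            continue
        sel = labels == row.label_id
        r2t[sel] = spec.region_r2t.get((row.region_name, row.hemisphere), spec.gm_r2t)
        s0[sel] = spec.gm_s0
        zeta[sel] = spec.gm_zeta

    # linear B0 field in mm coordinates (voxel index * voxel size)
    vx, vy, vz = spec.acq.voxel_size
    gx, gy, gz = spec.b0_gradient_hz_per_mm
    X, Y, Z = np.meshgrid(
        np.arange(nx) * vx, np.arange(ny) * vy, np.arange(nz) * vz, indexing="ij"
    )
    b0 = spec.b0_offset_hz + gx * X + gy * Y + gz * Z
    g_through = np.gradient(b0, vz, axis=2) if nz > 1 else np.zeros(spec.shape)

    phi = fs_lookup(spec.delta_omega * te)  # (ne,)
    decay = np.exp(
        -r2t[..., None] * te - zeta[..., None] * phi
    )
    sinc = np.abs(np.sinc(g_through[..., None] * dz * te))
    mag = s0[..., None] * decay * sinc
    signal = mag.astype(complex) * np.exp(1j * 2 * np.pi * b0[..., None] * te)

    nav_phase = spec.nav_amplitude_rad * np.sin(
        2 * np.pi * spec.nav_frequency_hz * np.arange(ny) * spec.acq.tr
    )
    signal *= np.exp(1j * nav_phase)[None, :, None, None]

    sigma = 0.0
    if spec.snr is not None:
        sigma = spec.gm_s0 / spec.snr
        noise = rng.normal(0, sigma, signal.shape) + 1j * rng.normal(0, sigma, signal.shape)
        signal = signal + noise

    if spec.mask_wm:
        mask = labels > 0
    else:
        mask = (labels != WM_LABEL) & (labels > 0)
    image = MultiEchoImage(data=signal, acq=spec.acq, brain_mask=mask)
    truth = QMaps(
        s0_map=s0,
        r2t_star_map=r2t,
        zeta_map=zeta,
        delta_omega_map=np.full(spec.shape, spec.delta_omega),
        residual_rms_map=np.zeros(spec.shape),
        converged_mask=mask.copy(),
        quality_mask=mask.copy(),
    )
    nav = NavigatorSeries(phase_per_excitation=nav_phase)
    return PhantomOutput(image=image, navigator=nav, truth=truth, labels=labelmap,
                         noise_sigma=sigma)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Cohort composition, designed effects, and score-generation model.

    Group sizes default to 31 healthy controls and 80 MS patients (32
    relapsing-remitting, 32 secondary-progressive, 16 primary-progressive).
    ``group_effects_r2t`` / ``group_effects_vol`` map group -> {(region,
    hemisphere): additive effect} relative to the HC mean (s^-1 for R2t*,
    mm^3 for volume).  ``correlation_targets`` are tuples (score_column,
    region, hemisphere, measure, target partial rho): each named score is
    built as rho * z + sqrt(1 - rho^2) * noise where z is the standardized
    residual of the regional truth on the covariates, so its partial
    correlation with the region equals rho in expectation.  Skewed clinical
    scores (EDSS, timed tests) are strictly monotone transforms of their
    latent, exercising the Spearman path.
    """

    seed: int
    n_per_group: dict = dc_field(
        default_factory=lambda: {"HC": 31, "RRMS": 32, "SPMS": 32, "PPMS": 16}
    )
    regions: tuple = FIXTURE_REGIONS
    age_mean: float = 49.5
    age_sd: float = 14.0
    age_range: tuple = (23.0, 85.0)
    p_female: float = 0.65
    p_right_handed: float = 73.0 / 80.0
    p_treated: float = 60.0 / 80.0
    hc_r2t_mean: dict = dc_field(
        default_factory=lambda: {
            "hippocampus": 16.5, "amygdala": 17.0,
            "parahippocampal": 17.5, "insula": 18.0,
        }
    )
    r2t_subject_sd: float = 1.2
    r2t_age_slope: float = -0.02
    hc_vol_mean_mm3: float = 72.0
    vol_subject_sd: float = 7.0
    vol_age_slope: float = -0.15
    group_effects_r2t: dict = dc_field(
        default_factory=lambda: {
            "RRMS": {("hippocampus", "right"): -0.6},
            "SPMS": {
                ("hippocampus", "left"): -1.0, ("hippocampus", "right"): -1.2,
                ("amygdala", "right"): -1.0, ("amygdala", "left"): -0.5,
            },
            "PPMS": {("hippocampus", "right"): -0.8},
        }
    )
    group_effects_vol: dict = dc_field(
        default_factory=lambda: {
            "SPMS": {
                ("hippocampus", "left"): -14.0, ("hippocampus", "right"): -14.0,
                ("amygdala", "left"): -10.0, ("amygdala", "right"): -10.0,
            },
            "PPMS": {("hippocampus", "left"): -10.0, ("hippocampus", "right"): -10.0},
        }
    )
    correlation_targets: tuple = (
        ("SDMT_z", "hippocampus", "left", "R2t*", 0.4),
        ("PASAT2_z", "amygdala", "left", "R2t*", 0.36),
        ("EDSS", "amygdala", "right", "R2t*", -0.30),
    )
    lesion_load_median_ml: float = 6.0
    lesion_load_log_sd: float = 0.8
    scaling_mean: float = 1.0
    scaling_sd: float = 0.04
    voxel_volume_mm3: float = 2.0

    def __post_init__(self) -> None:
        for *_, rho in self.correlation_targets:
            if not -1 < rho < 1:
                raise ValueError("target correlations must lie in (-1, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    while True:
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort and its per-subject regional ground truth.

    Returns ``(cohort, truth)``: one row per subject with demographics,
    covariates and clinical scores; and a tidy truth table (subject_id,
    region_name, hemisphere, median_r2t_star, n_voxels, volume_mm3,
    normalized_volume) whose value columns are drop-in compatible with the
    region-summary output, so the statistics path can be exercised on
    truths directly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group, n in spec.n_per_group.items():
        for _ in range(n):
            sid += 1
            age = float(_truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, 1)[0])
            is_ms = group != "HC"
            rows.append(
                dict(
                    subject_id=f"S{sid:03d}",
                    group=group,
                    age=age,
                    gender="F" if rng.random() < spec.p_female else "M",
                    handedness="right" if rng.random() < spec.p_right_handed else "left",
                    lesion_load=(
                        float(np.exp(rng.normal(np.log(spec.lesion_load_median_ml),
                                                spec.lesion_load_log_sd)))
                        if is_ms else np.nan
                    ),
                    treatment=int(rng.random() < spec.p_treated) if is_ms else 0,
                    scaling_factor=float(rng.normal(spec.scaling_mean, spec.scaling_sd)),
                )
            )
    cohort = pd.DataFrame(rows)
    n_sub = len(cohort)

    truth_rows = []
    for _, s in cohort.iterrows():
        for region in spec.regions:
            base_r2t = spec.hc_r2t_mean.get(region, 17.0)
            for hemi in ("left", "right"):
                eff = spec.group_effects_r2t.get(s.group, {}).get((region, hemi), 0.0)
                r2t = (
                    base_r2t + eff
                    + spec.r2t_age_slope * (s.age - spec.age_mean)
                    + rng.normal(0, spec.r2t_subject_sd)
                )
                veff = spec.group_effects_vol.get(s.group, {}).get((region, hemi), 0.0)
                vol = (
                    spec.hc_vol_mean_mm3 + veff
                    + spec.vol_age_slope * (s.age - spec.age_mean)
                    + rng.normal(0, spec.vol_subject_sd)
                )
                n_vox = int(np.clip(round(vol / spec.voxel_volume_mm3), 5, 10**6))
                truth_rows.append(
                    dict(
                        subject_id=s.subject_id, region_name=region, hemisphere=hemi,
                        median_r2t_star=float(r2t), n_voxels=n_vox,
                        volume_mm3=n_vox * spec.voxel_volume_mm3,
                        normalized_volume=n_vox * spec.voxel_volume_mm3 * s.scaling_factor,
                    )
                )
    truth = pd.DataFrame(truth_rows)

    cohort = _attach_scores(spec, rng, cohort, truth)
    return cohort, truth


_MEASURE_COL = {"R2t*": "median_r2t_star", "NV": "normalized_volume"}


def _attach_scores(spec, rng, cohort, truth):
    """Build clinical scores with designed partial correlations (MS only)."""
    ms = cohort[cohort.group != "HC"]
    ms_idx = ms.index
    cov = np.column_stack([
        np.ones(len(ms)),
        ms.age.to_numpy(float),
        (ms.gender == "M").to_numpy(float),
        ms.lesion_load.to_numpy(float),
        ms.treatment.to_numpy(float),
    ])

    def region_z(region, hemi, measure):
        col = _MEASURE_COL[measure]
        t = truth[(truth.region_name == region) & (truth.hemisphere == hemi)]
        v = t.set_index("subject_id").loc[ms.subject_id, col].to_numpy(float)
        beta, *_ = np.linalg.lstsq(cov, v, rcond=None)
        resid = v - cov @ beta
        sd = resid.std()
        return resid / sd if sd > 0 else resid

    targets = {t[0]: t[1:] for t in spec.correlation_targets}
    score_cols = ["PASAT3_z", "PASAT2_z", "SDMT_z", "EDSS", "T25FW",
                  "9HPT_dom", "9HPT_nondom"]
    latents = {}
    for col in score_cols:
        eps = rng.normal(0, 1, len(ms))
        if col in targets:
            region, hemi, measure, rho = targets[col]
            z = region_z(region, hemi, measure)
            latents[col] = rho * z + np.sqrt(1 - rho**2) * eps
        else:
            latents[col] = eps

    age_c = (ms.age.to_numpy(float) - spec.age_mean) / spec.age_sd
    for col in ("PASAT3_z", "PASAT2_z", "SDMT_z"):
        cohort.loc[ms_idx, col] = latents[col] - 0.25 * age_c
    # strictly monotone, skewed transforms for the Spearman-path scores
    cohort.loc[ms_idx, "EDSS"] = np.clip(3.0 + 1.6 * latents["EDSS"] + 0.3 * age_c, 0.0, 10.0)
    cohort.loc[ms_idx, "T25FW"] = 5.5 * np.exp(0.35 * latents["T25FW"] + 0.1 * age_c)
    cohort.loc[ms_idx, "9HPT_dom"] = 20.0 * np.exp(0.25 * latents["9HPT_dom"])
    cohort.loc[ms_idx, "9HPT_nondom"] = 22.0 * np.exp(0.25 * latents["9HPT_nondom"])

    hc_idx = cohort.index.difference(ms_idx)
    for col in ("PASAT3_z", "PASAT2_z", "SDMT_z"):
        cohort.loc[hc_idx, col] = rng.normal(0.3, 1.0, len(hc_idx))
    # raw cognitive scores: monotone rescalings of the z-scores
    cohort["PASAT3"] = np.round(45 + 8 * cohort["PASAT3_z"], 0)
    cohort["PASAT2"] = np.round(35 + 8 * cohort["PASAT2_z"], 0)
    cohort["SDMT"] = np.round(55 + 10 * cohort["SDMT_z"], 0)
    return cohort


# ---------------------------------------------------------------------------
# End-to-end fixture
# ---------------------------------------------------------------------------

def make_end_to_end_fixture(
    seed: int,
    outdir,
    cohort_spec: CohortSpec | None = None,
    snr: float = 100.0,
    b0_gradient_hz_per_mm: tuple = (0.0, 0.0, 1.0),
    nav_amplitude_rad: float = 0.3,
    shape: tuple = (16, 16, 8),
) -> dict:
    """Write a complete miniature study consumable by the pipeline.

    Per subject: a multi-echo magnitude/phase NIfTI pair with echo-time
    sidecar, a navigator trace TSV, and a label volume; plus one cohort TSV
    (including per-subject skull scaling factors) and the ground-truth
    region table.  Regional truths (R2t* and voxel counts) come from
    :func:`make_cohort`, so designed group effects and score correlations
    propagate into the images.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort_spec is None:
        cohort_spec = CohortSpec(seed=derive_seed(seed, 0))
    cohort, truth = make_cohort(cohort_spec)

    cap = block_capacity(shape)
    subj_dir = outdir / "subjects"
    subj_dir.mkdir(exist_ok=True)
    manifest = {"cohort": outdir / "cohort.tsv", "truth": outdir / "truth_regions.tsv",
                "subjects": {}}
    for i, (_, s) in enumerate(cohort.iterrows()):
        t = truth[truth.subject_id == s.subject_id]
        region_r2t = {
            (r.region_name, r.hemisphere): r.median_r2t_star for _, r in t.iterrows()
        }
        region_n = {
            (r.region_name, r.hemisphere): int(np.clip(r.n_voxels, 1, cap))
            for _, r in t.iterrows()
        }
        ps = PhantomSpec(
            seed=derive_seed(seed, i + 1),
            shape=shape,
            regions=cohort_spec.regions,
            region_r2t=region_r2t,
            region_n_voxels=region_n,
            b0_gradient_hz_per_mm=b0_gradient_hz_per_mm,
            nav_amplitude_rad=nav_amplitude_rad,
            snr=snr,
        )
        out = make_phantom(ps)
        stem = subj_dir / s.subject_id
        io.save_multiecho(
            np.abs(out.image.data), np.angle(out.image.data),
            out.image.affine, out.image.acq.echo_times, stem,
        )
        io.save_nifti(out.labels.labels, out.image.affine,
                      stem.with_name(s.subject_id + "_labels.nii"))
        io.write_tsv(out.labels.label_table,
                     stem.with_name(s.subject_id + "_labels.tsv"))
        io.write_tsv(
            pd.DataFrame({"excitation": np.arange(len(out.navigator.phase_per_excitation)),
                          "phase_rad": out.navigator.phase_per_excitation}),
            stem.with_name(s.subject_id + "_nav.tsv"),
        )
        manifest["subjects"][s.subject_id] = {
            "stem": stem, "noise_sigma": out.noise_sigma,
        }
    # truth n_voxels was clipped to block capacity when realized in images
    truth = truth.copy()
    truth["n_voxels"] = truth["n_voxels"].clip(upper=cap)
    truth["volume_mm3"] = truth["n_voxels"] * cohort_spec.voxel_volume_mm3
    truth["normalized_volume"] = truth["volume_mm3"] * truth.subject_id.map(
        cohort.set_index("subject_id").scaling_factor
    )
    io.write_tsv(cohort, manifest["cohort"])
    io.write_tsv(truth, manifest["truth"])
    return manifest
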