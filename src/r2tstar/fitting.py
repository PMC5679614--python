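"""Voxelwise estimation of S0, R2t* and BOLD parameters from multi-echo data.

The pipeline here is: (1) remove per-excitation global phase fluctuations
using the navigator trace, (2) estimate the B0 field and its through-slab
gradient from the echo phase evolution, (3) fit the magnitude decay model
voxel by voxel with bounded nonlinear least squares, treating the
macroscopic-field sinc term either as part of the model or as a
pre-correction of the data.

Fitting is magnitude-domain.  Rician noise bias at low SNR is handled by a
quality mask (last-echo SNR floor and residual ceiling) rather than a
Rician likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .signal_model import (
    AcquisitionParams,
    BoldParams,
    MacroFieldParams,
    TissueParams,
    f_macro,
    fs_lookup,
)

__all__ = [
    "MultiEchoImage",
    "NavigatorSeries",
    "FieldGradientMap",
    "QMaps",
    "FitOptions",
    "FitDiagnostics",
    "navigator_correct",
    "estimate_field",
    "init_loglinear",
    "fit_voxel",
    "fit_volume",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MultiEchoImage:
    """4D multi-echo volume (x, y, z, echo), complex-valued or magnitude-only.

    ``data`` complex implies phase is available (navigator correction and
    field estimation need it); a magnitude-only volume may be passed as a
    real array.  ``affine`` maps voxel indices to world mm.
    """

    data: np.ndarray
    acq: AcquisitionParams
    affine: np.ndarray = None  # type: ignore[assignment]
    brain_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, echo)")
        if self.data.shape[-1] != self.acq.n_echoes:
            raise ValueError(
                f"echo axis length {self.data.shape[-1]} != acq.n_echoes {self.acq.n_echoes}"
            )
        if self.affine is None:
            self.affine = np.diag(list(self.acq.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial shape")

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data) if self.is_complex else np.asarray(self.data)

    @property
    def phase(self) -> np.ndarray:
        if not self.is_complex:
            raise ValueError("phase unavailable for magnitude-only data")
        return np.angle(self.data)


@dataclass
class NavigatorSeries:
    """Per-excitation global phase trace (radians), zeroth-order model.

    Excitations index the phase-encode rows of the image (axis 1): all
    voxels of row j share the phase ``phase_per_excitation[j]``.
    """

    phase_per_excitation: np.ndarray
    excitation_axis: int = 1

    def __post_init__(self) -> None:
        self.phase_per_excitation = np.asarray(self.phase_per_excitation, dtype=float)
        if not np.all(np.isfinite(self.phase_per_excitation)):
            raise ValueError("navigator phases must be finite")


@dataclass
class FieldGradientMap:
    """Per-voxel B0 offset (Hz) and through-slab gradient (Hz/mm)."""

    b0_map: np.ndarray
    g_through: np.ndarray

    def __post_init__(self) -> None:
        self.b0_map = np.asarray(self.b0_map, dtype=float)
        self.g_through = np.asarray(self.g_through, dtype=float)
        if self.b0_map.shape != self.g_through.shape:
            raise ValueError("b0_map and g_through shapes must match")


@dataclass
class QMaps:
    """Quantitative maps produced by the voxelwise fit."""

    s0_map: np.ndarray
    r2t_star_map: np.ndarray
    zeta_map: np.ndarray
    delta_omega_map: np.ndarray
    residual_rms_map: np.ndarray
    converged_mask: np.ndarray
    quality_mask: np.ndarray


# zeta's lower bound is negative on purpose: clamping at the physical floor
# of zero rectifies noise excursions along the near-collinear zeta-R2t*
# direction and biases R2t* low (cf. negative variance-component estimates)
_DEFAULT_BOUNDS = {
    "s0": (0.0, np.inf),
    "r2t_star": (0.0, 100.0),
    "zeta": (-0.2, 0.2),
    "delta_omega": (10.0, 300.0),
}


@dataclass
class FitOptions:
    """Switches for the voxelwise fit.

    mode 'zeta' fits (S0, R2t*, zeta) with delta_omega fixed (default:
    10 magnitude points constrain a 4-parameter model poorly); mode
    'zeta+domega' additionally frees delta_omega.  macro_mode 'model'
    multiplies the sinc term into the model; 'predivide' divides it out of
    the data before fitting.
    """

    mode: str = "zeta"
    delta_omega_fixed: float = 70.0
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    max_iterations: int = 200
    tolerance: float = 1e-10
    init_strategy: str = "loglinear"
    macro_mode: str = "model"
    f_macro_floor: float = 0.3
    snr_floor: float = 3.0
    noise_sigma: float | None = None
    residual_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("zeta", "zeta+domega"):
            raise ValueError("mode must be 'zeta' or 'zeta+domega'")
        if self.macro_mode not in ("model", "predivide"):
            raise ValueError("macro_mode must be 'model' or 'predivide'")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for {name} has lower > upper")


@dataclass
class FitDiagnostics:
    residual_rms: float
    n_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# Pre-corrections
# ---------------------------------------------------------------------------

def navigator_correct(image: MultiEchoImage, nav: NavigatorSeries) -> MultiEchoImage:
    """Remove per-excitation global phase: row j is multiplied by exp(-i phi_j).

    Exact when the physiological fluctuation really is a global
    (zeroth-order) phase per excitation; any spatially-varying component is
    left untouched.  Idempotent for a zero navigator.
    """
    if not image.is_complex:
        raise ValueError("navigator correction requires complex data (phase needed)")
    nrows = image.data.shape[nav.excitation_axis]
    if len(nav.phase_per_excitation) != nrows:
        raise ValueError(
            f"navigator covers {len(nav.phase_per_excitation)} excitations, "
            f"image has {nrows} rows"
        )
    shape = [1, 1, 1, 1]
    shape[nav.excitation_axis] = nrows
    corr = np.exp(-1j * nav.phase_per_excitation).reshape(shape)
    return replace(image, data=image.data * corr)


def estimate_field(image: MultiEchoImage) -> FieldGradientMap:
    """B0 map from the per-voxel slope of temporally-unwrapped phase vs TE.

    phase(TE) = 2*pi*b0*TE + phi0, unwrapped along the echo axis, slope by
    least squares; valid for |b0| < 1/(2*dTE).  The through-slab gradient is
    the central finite difference of b0 along z divided by the voxel z size
    (one-sided at the edges).
    """
    if image.acq.n_echoes < 2:
        raise ValueError("field estimation needs >= 2 echoes")
    te = image.acq.echo_times
    phase = np.unwrap(image.phase, axis=-1)
    # slope of phase on TE, vectorized: cov(te, phase)/var(te)
    te_c = te - te.mean()
    slope = np.tensordot(phase, te_c, axes=([-1], [0])) / np.dot(te_c, te_c)
    b0 = slope / (2.0 * np.pi)
    dz = image.acq.voxel_size[2]
    g_through = np.gradient(b0, dz, axis=2)
    return FieldGradientMap(b0_map=b0, g_through=g_through)


# ---------------------------------------------------------------------------
# Voxel fit
# ---------------------------------------------------------------------------

def init_loglinear(signal: np.ndarray, te: np.ndarray) -> TissueParams:
    """Mono-exponential initialization: OLS of ln(S) on TE.

    Returns s0 = exp(intercept) and r2t_star = max(0, -slope).  With a BOLD
    term present the slope estimate is biased high by the extra decay; the
    nonlinear fit removes this.
    """
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(signal <= 0):
        raise ValueError("init_loglinear requires strictly positive signal")
    slope, intercept = np.polyfit(te, np.log(signal), 1)
    return TissueParams(s0=float(np.exp(intercept)), r2t_star=float(max(0.0, -slope)))


def _model_and_jac(params, te, phi, fmac, mode, domega_fixed):
    """Evaluate the magnitude model and its Jacobian w.r.t. free params."""
    if mode == "zeta":
        s0, r2t, zeta = params
        m = s0 * np.exp(-r2t * te - zeta * phi) * fmac
        jac = np.column_stack([
            np.exp(-r2t * te - zeta * phi) * fmac,
            -te * m,
            -phi * m,
        ])
    else:
        s0, r2t, zeta, domega = params
        x = domega * te
        fsv = fs_lookup(x)
        m = s0 * np.exp(-r2t * te - zeta * fsv) * fmac
        eps = max(1e-6 * domega, 1e-4)
        dfs = (fs_lookup((domega + eps) * te) - fs_lookup(np.maximum(domega - eps, 0) * te)) / (2 * eps)
        jac = np.column_stack([
            np.exp(-r2t * te - zeta * fsv) * fmac,
            -te * m,
            -fsv * m,
            -zeta * dfs * m,
        ])
    return m, jac


def fit_voxel(
    signal: np.ndarray,
    te: np.ndarray,
    macro: MacroFieldParams,
    opts: FitOptions,
) -> tuple[TissueParams, BoldParams, FitDiagnostics]:
    """Bounded nonlinear least squares of the decay model to one voxel.

    Non-convergence returns the initialization with ``converged=False``
    rather than raising.  NaNs in the signal are the caller's problem
    (fit_volume flags such voxels out of the quality mask).
    """
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(te, dtype=float)
    if signal.shape != te.shape:
        raise ValueError("signal and te must have matching lengths")
    n_free = 3 if opts.mode == "zeta" else 4
    if len(signal) < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} echoes for {n_free} parameters")

    fmac = np.asarray(f_macro(te, macro), dtype=float)
    data = signal
    if opts.macro_mode == "predivide":
        safe = np.maximum(fmac, 1e-6)
        data = signal / safe
        fmac = np.ones_like(te)

    # initialization: log-linear (s0, r2t*), small zeta, configured domega
    pos = data > 0
    if pos.sum() >= 2:
        init = init_loglinear(data[pos], te[pos])
    else:
        init = TissueParams(s0=float(np.abs(data).max(initial=0.0)), r2t_star=20.0)
    b = opts.bounds
    x0 = [
        np.clip(init.s0, max(b["s0"][0], 1e-12), None),
        np.clip(init.r2t_star, *b["r2t_star"]),
        np.clip(0.01, *b["zeta"]),
    ]
    lo = [b["s0"][0], b["r2t_star"][0], b["zeta"][0]]
    hi = [b["s0"][1], b["r2t_star"][1], b["zeta"][1]]
    if opts.mode == "zeta+domega":
        x0.append(np.clip(opts.delta_omega_fixed, *b["delta_omega"]))
        lo.append(b["delta_omega"][0])
        hi.append(b["delta_omega"][1])

    phi = np.asarray(fs_lookup(opts.delta_omega_fixed * te), dtype=float)

    def resid(p):
        m, _ = _model_and_jac(p, te, phi, fmac, opts.mode, opts.delta_omega_fixed)
        return m - data

    def jac(p):
        _, j = _model_and_jac(p, te, phi, fmac, opts.mode, opts.delta_omega_fixed)
        return j

    try:
        res = least_squares(
            resid,
            np.asarray(x0, dtype=float),
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-14,
            ftol=opts.tolerance,
            gtol=1e-14,
            max_nfev=opts.max_iterations,
        )
        converged = bool(res.status > 0)
        p = res.x if converged else np.asarray(x0, dtype=float)
        rms = float(np.sqrt(np.mean(resid(p) ** 2)))
        nit = int(res.nfev)
    except Exception:
        converged = False
        p = np.asarray(x0, dtype=float)
        rms = float(np.sqrt(np.mean(resid(p) ** 2)))
        nit = 0

    tissue = TissueParams(s0=float(p[0]), r2t_star=float(p[1]))
    domega = float(p[3]) if opts.mode == "zeta+domega" else opts.delta_omega_fixed
    bold = BoldParams(zeta=float(p[2]), delta_omega=domega)
    return tissue, bold, FitDiagnostics(residual_rms=rms, n_iterations=nit, converged=converged)


def fit_volume(
    image: MultiEchoImage,
    field: FieldGradientMap | None,
    opts: FitOptions,
) -> QMaps:
    """Apply :func:`fit_voxel` to every voxel inside the brain mask.

    The result is independent of traversal order by construction (each voxel
    is fit in isolation).  The quality mask drops voxels whose sinc
    attenuation at the last echo falls below ``opts.f_macro_floor``, whose
    last-echo SNR is below ``opts.snr_floor`` (when a noise sigma is known),
    whose residual RMS exceeds ``residual_factor * noise_sigma``, or that
    contain NaNs.
    """
    shape = image.data.shape[:3]
    if field is not None and field.b0_map.shape != shape:
        raise ValueError("field map shape must match image spatial shape")
    te = image.acq.echo_times
    mag = image.magnitude
    dz = image.acq.voxel_size[2]

    s0 = np.zeros(shape)
    r2t = np.zeros(shape)
    zeta = np.zeros(shape)
    domega = np.zeros(shape)
    rms = np.zeros(shape)
    converged = np.zeros(shape, dtype=bool)
    quality = np.zeros(shape, dtype=bool)

    idx = np.argwhere(image.brain_mask)
    for i, j, k in idx:
        sig = mag[i, j, k, :]
        if not np.all(np.isfinite(sig)):
            continue
        g = float(field.g_through[i, j, k]) if field is not None else 0.0
        macro = MacroFieldParams(g_through=g, slab_thickness=dz)
        tissue, bold, diag = fit_voxel(sig, te, macro, opts)
        s0[i, j, k] = tissue.s0
        r2t[i, j, k] = tissue.r2t_star
        zeta[i, j, k] = bold.zeta
        domega[i, j, k] = bold.delta_omega
        rms[i, j, k] = diag.residual_rms
        converged[i, j, k] = diag.converged

        ok = diag.converged
        ok &= f_macro(float(te[-1]), macro) >= opts.f_macro_floor
        if opts.noise_sigma is not None and opts.noise_sigma > 0:
            expected_last = tissue.s0 * np.exp(-tissue.r2t_star * te[-1])
            ok &= expected_last / opts.noise_sigma >= opts.snr_floor
            ok &= diag.residual_rms <= opts.residual_factor * opts.noise_sigma
        quality[i, j, k] = ok

    return QMaps(
        s0_map=s0,
        r2t_star_map=r2t,
        zeta_map=zeta,
        delta_omega_map=domega,
        residual_rms_map=rms,
        converged_mask=converged,
        quality_mask=quality,
    )
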