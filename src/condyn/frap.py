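"""FRAP recovery quantification.

Turns time-lapse movies plus ROI definitions into corrected, normalized
recovery curves and fitted dynamic parameters: half-times, mobile fractions
and, for diffusion-dominated recovery in a circular bleach spot, a diffusion
coefficient via the uniform-disk (Soumpasis) relation.

The processing chain is

    extract_roi_trace -> correct_acquisition_bleach -> normalize_recovery
        -> fit_single_exponential / fit_biexponential / choose_model
        -> diffusion_coefficient / summarize_replicates
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapMovie",
    "RoiSpec",
    "RecoveryCurve",
    "FrapFit",
    "FrapSummary",
    "DESIGN_RADIUS_UM",
    "SOUMPASIS_GAMMA",
    "roi_mask",
    "extract_roi_trace",
    "correct_acquisition_bleach",
    "normalize_recovery",
    "process_movie",
    "fit_single_exponential",
    "fit_biexponential",
    "choose_model",
    "diffusion_coefficient",
    "summarize_replicates",
]

# Root x* of e^-x (I0(x) + I1(x)) = 1/2 maps the uniform-disk recovery
# half-time onto the diffusion coefficient: D = r^2 / (2 x* t_half).
_SOUMPASIS_XHALF = 2.2356581526482238
SOUMPASIS_GAMMA = 1.0 / (2.0 * _SOUMPASIS_XHALF)  # ~0.2236

#: Default bleach-ROI radius per experimental design, in micrometres.
#: full-FRAP covers a whole ~3 um condensate; inner-FRAP a 1 um circle
#: inside it; nucleoplasmic-FRAP a 6 um circle; fiber-FRAP a 0.5 um circle.
DESIGN_RADIUS_UM = {
    "full": 1.5,
    "inner": 0.5,
    "nucleoplasmic": 3.0,
    "fiber": 0.25,
}

#: Fit model conventionally used per design (fiber recovery is bi-exponential,
#: everything else single-exponential).
DESIGN_MODEL = {
    "full": "single",
    "inner": "single",
    "nucleoplasmic": "single",
    "fiber": "biexp",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FrapMovie:
    """A time-ordered stack of 2D intensity frames with acquisition metadata.

    Parameters
    ----------
    frames : (n_frames, h, w) array
    pixel_size : micrometres per pixel
    frame_interval : seconds between acquisitions
    n_pre, n_bleach : frame counts of the pre-bleach and bleach phases;
        post-bleach frames are everything after them.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    n_pre: int
    n_bleach: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, h, w) stack")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.n_pre < 0 or self.n_bleach < 0:
            raise ValueError("n_pre and n_bleach must be non-negative")
        if self.n_pre + self.n_bleach > len(self.frames):
            raise ValueError("n_pre + n_bleach exceeds the frame count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_post(self) -> int:
        return self.n_frames - self.n_pre - self.n_bleach

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RoiSpec:
    """Region-of-interest specification.

    ``kind`` is one of ``circle`` (center + radius), ``polyline-band``
    (points + width, a band of given width around a polyline) or
    ``freehand-mask`` (explicit boolean mask).  ``center`` is in pixel
    coordinates (x, y); ``radius`` and ``width`` are physical (um).

    ``coast_width`` (um), when set on a circle, restricts the mask to an
    annular band of that width at the ROI boundary — the "coast" of the
    bleached region adjacent to unbleached surroundings.
    """

    kind: Literal["circle", "polyline-band", "freehand-mask"] = "circle"
    center: tuple[float, float] | None = None
    radius: float | None = None
    width: float | None = None
    points: np.ndarray | None = None
    mask: np.ndarray | None = None
    design: str | None = None
    coast_width: float | None = None

    @classmethod
    def for_design(cls, design: str, center: tuple[float, float]) -> "RoiSpec":
        """Circle ROI with the default radius of a named FRAP design."""
        if design not in DESIGN_RADIUS_UM:
            raise ValueError(f"unknown design {design!r}; expected one of "
                             f"{sorted(DESIGN_RADIUS_UM)}")
        return cls(kind="circle", center=center,
                   radius=DESIGN_RADIUS_UM[design], design=design)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "design": self.design,
             "coast_width": self.coast_width}
        if self.center is not None:
            d["center"] = [float(c) for c in self.center]
        if self.radius is not None:
            d["radius"] = float(self.radius)
        if self.width is not None:
            d["width"] = float(self.width)
        if self.points is not None:
            d["points"] = np.asarray(self.points, float).tolist()
        if self.mask is not None:
            d["mask"] = np.asarray(self.mask, bool).astype(int).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        out = cls(kind=d.get("kind", "circle"),
                  center=tuple(d["center"]) if d.get("center") else None,
                  radius=d.get("radius"), width=d.get("width"),
                  design=d.get("design"), coast_width=d.get("coast_width"))
        if d.get("points") is not None:
            out.points = np.asarray(d["points"], float)
        if d.get("mask") is not None:
            out.mask = np.asarray(d["mask"], bool)
        return out


def roi_mask(roi: RoiSpec, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean pixel membership of an ROI on a frame of given shape.

    Membership is by pixel-center-in-region test. ``pixel_size`` is um/px.
    """
    h, w = shape
    if roi.kind == "circle":
        if roi.center is None or roi.radius is None:
            raise ValueError("circle ROI requires center and radius")
        if roi.radius <= 0:
            raise ValueError("circle radius must be positive")
        cx, cy = roi.center
        r_px = roi.radius / pixel_size
        if cx - r_px < -0.5 or cy - r_px < -0.5 or \
                cx + r_px > w - 0.5 or cy + r_px > h - 0.5:
            raise ValueError("circle ROI extends outside the frame")
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(xx - cx, yy - cy)
        m = d <= r_px
        if roi.coast_width is not None:
            m &= d > r_px - roi.coast_width / pixel_size
    elif roi.kind == "polyline-band":
        if roi.points is None or roi.width is None:
            raise ValueError("polyline-band ROI requires points and width")
        pts = np.asarray(roi.points, float)
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.full(shape, np.inf)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            vx, vy = x1 - x0, y1 - y0
            denom = vx * vx + vy * vy
            if denom == 0:
                t = np.zeros(shape)
            else:
                t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / denom, 0, 1)
            d = np.minimum(d, np.hypot(xx - (x0 + t * vx), yy - (y0 + t * vy)))
        m = d <= (roi.width / 2.0) / pixel_size
    elif roi.kind == "freehand-mask":
        if roi.mask is None:
            raise ValueError("freehand-mask ROI requires a mask")
        m = np.asarray(roi.mask, bool)
        if m.shape != shape:
            raise ValueError("freehand mask shape does not match frame")
    else:
        raise ValueError(f"unknown ROI kind {roi.kind!r}")
    if not m.any():
        raise ValueError("ROI contains no pixels")
    return m


@dataclass
class RecoveryCurve:
    """Normalized recovery: post-bleach times (s, zero at the first
    post-bleach frame) paired with normalized intensities, plus pre/post
    bookkeeping (pre-bleach mean and first post-bleach raw values)."""

    times: np.ndarray
    values: np.ndarray
    n_pre: int = 0
    pre_mean: float = 1.0
    post0: float = 0.0
    corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class FrapFit:
    """A fitted recovery model and its derived quantities.

    ``amplitudes``/``rates``/``half_times`` are per-component tuples,
    fast-to-slow for the bi-exponential model.  ``mobile_fraction`` is the
    fitted plateau (sum of amplitudes), reported raw and flagged via
    ``mobile_in_range`` when outside [0, 1.05].
    """

    model: Literal["single", "biexp"]
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    half_times: tuple[float, ...]
    mobile_fraction: float
    residual_sse: float
    n_points: int
    fit_ok: bool
    aicc: float = np.nan
    diffusion_coeff: float | None = None
    mobile_in_range: bool = True
    notes: str = ""
    aicc_scores: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "amplitudes": list(self.amplitudes),
            "rates_per_s": list(self.rates),
            "half_times_s": list(self.half_times),
            "mobile_fraction": self.mobile_fraction,
            "residual_sse": self.residual_sse,
            "n_points": self.n_points,
            "fit_ok": self.fit_ok,
            "aicc": None if np.isnan(self.aicc) else self.aicc,
            "diffusion_coeff_um2_per_s": self.diffusion_coeff,
            "mobile_in_range": self.mobile_in_range,
            "notes": self.notes,
        }


@dataclass
class FrapSummary:
    """Across-replicate summary of one condition: mean and sample SD of
    per-component half-times and of the mobile fraction.  SDs are ``None``
    with fewer than two successful fits."""

    n_fits: int
    n_failed: int
    model: str
    mean_half_times: tuple[float, ...]
    sd_half_times: tuple[float, ...] | None
    mean_mobile: float
    sd_mobile: float | None
    fits: list[FrapFit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Trace extraction, correction, normalization
# ---------------------------------------------------------------------------

def extract_roi_trace(movie: FrapMovie, roi: RoiSpec) -> np.ndarray:
    """Per-frame mean intensity over the ROI pixels."""
    m = roi_mask(roi, movie.shape, movie.pixel_size)
    return movie.frames[:, m].mean(axis=1)


def correct_acquisition_bleach(target: np.ndarray, reference: np.ndarray,
                               n_pre: int) -> np.ndarray:
    """Remove general acquisition photobleaching from a target trace.

    Divides the target by the reference trace (an unbleached region of the
    same nucleus) normalized to its own pre-bleach mean:

        corrected(t) = target(t) / (reference(t) / mean(reference[:n_pre]))

    A constant reference is the identity map; a shared multiplicative decay
    cancels exactly.
    """
    target = np.asarray(target, float)
    reference = np.asarray(reference, float)
    if target.shape != reference.shape:
        raise ValueError("target and reference traces differ in length")
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    if np.any(reference <= 0):
        raise ValueError("reference trace contains non-positive values")
    _warn_if_recovering(reference, n_pre)
    return target * (reference[:n_pre].mean() / reference)


def _warn_if_recovering(reference: np.ndarray, n_pre: int) -> None:
    # A reference placed on (or too near) the bleached region recovers over
    # time; a genuine acquisition-bleach reference can only decay.  Flag a
    # post-phase upward trend that exceeds 3 standard errors.
    post = reference[n_pre:]
    if len(post) < 10:
        return
    t = np.arange(len(post), dtype=float)
    slope, intercept = np.polyfit(t, post, 1)
    resid = post - (slope * t + intercept)
    se = np.sqrt(resid.var(ddof=2) * 12.0 / (len(post) * (len(post) ** 2 - 1)))
    if se > 0 and slope > 3 * se:
        warnings.warn("reference trace increases over time (recovery "
                      "signature?) — check reference ROI placement",
                      stacklevel=3)


def normalize_recovery(corrected: np.ndarray, n_pre: int, n_bleach: int,
                       frame_interval: float) -> RecoveryCurve:
    """Full-scale normalization of a corrected trace.

    f(t) = (F(t) - F0) / (F_pre - F0) with F_pre the pre-bleach mean and F0
    the first post-bleach value, so the pre-bleach mean maps to 1 and the
    first post-bleach value to 0 exactly.  Bleach-phase frames are dropped
    and time zero is the first post-bleach acquisition.
    """
    corrected = np.asarray(corrected, float)
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    n0 = n_pre + n_bleach
    if len(corrected) <= n0:
        raise ValueError("trace has no post-bleach frames")
    f_pre = corrected[:n_pre].mean()
    f0 = corrected[n0]
    if abs(f_pre - f0) <= 1e-12 * max(abs(f_pre), 1.0):
        raise ValueError("no bleach detected: pre-bleach mean equals the "
                         "first post-bleach value")
    post = corrected[n0:]
    values = (post - f0) / (f_pre - f0)
    times = np.arange(len(post)) * frame_interval
    return RecoveryCurve(times=times, values=values, n_pre=n_pre,
                         pre_mean=float(f_pre), post0=float(f0),
                         corrected=True)


def process_movie(movie: FrapMovie, roi: RoiSpec,
                  reference_roi: RoiSpec | None = None) -> RecoveryCurve:
    """Extract, optionally bleach-correct, and normalize one ROI trace."""
    trace = extract_roi_trace(movie, roi)
    if reference_roi is not None:
        ref = extract_roi_trace(movie, reference_roi)
        trace = correct_acquisition_bleach(trace, ref, movie.n_pre)
    return normalize_recovery(trace, movie.n_pre, movie.n_bleach,
                              movie.frame_interval)


# ---------------------------------------------------------------------------
# Exponential fitting
# ---------------------------------------------------------------------------

_LN2 = float(np.log(2.0))
_K_BOUNDS = (1e-4, 1e3)
_A_MAX = 1.5


def _single_model(t, a, k):
    return a * (1.0 - np.exp(-k * t))


def _biexp_model(t, a1, k1, a2, k2):
    return a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def _aicc(sse: float, n: int, n_params: int) -> float:
    sse = max(float(sse), 1e-300)
    aic = n * np.log(sse / n) + 2 * n_params
    corr_den = n - n_params - 1
    return aic + (2 * n_params * (n_params + 1) / corr_den if corr_den > 0
                  else np.inf)


def _init_single(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # A <- mean of the last decile; k <- ln2 / time-to-half-plateau
    n10 = max(1, len(y) // 10)
    a0 = float(np.clip(y[-n10:].mean(), 1e-3, _A_MAX))
    above = np.nonzero(y >= a0 / 2)[0]
    t_half0 = t[above[0]] if len(above) and t[above[0]] > 0 else \
        max(t[len(t) // 2], t[1] if len(t) > 1 else 1.0)
    k0 = float(np.clip(_LN2 / t_half0, *_K_BOUNDS))
    return a0, k0


def _failed_fit(model: str, n: int, note: str) -> FrapFit:
    ncomp = 1 if model == "single" else 2
    return FrapFit(model=model, amplitudes=(np.nan,) * ncomp,
                   rates=(np.nan,) * ncomp, half_times=(np.nan,) * ncomp,
                   mobile_fraction=np.nan, residual_sse=np.nan, n_points=n,
                   fit_ok=False, notes=note)


def fit_single_exponential(curve: RecoveryCurve) -> FrapFit:
    """Least-squares fit of f(t) = A (1 - e^{-kt}).

    Mobile fraction is the plateau A; the half-time is ln2 / k.  Returns
    ``fit_ok=False`` (never raises) on non-convergence or a vanishing
    recovery amplitude.
    """
    t, y = curve.times, curve.values
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach points")
    a0, k0 = _init_single(t, y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_single_model, t, y, p0=[a0, k0],
                                bounds=([0.0, _K_BOUNDS[0]],
                                        [_A_MAX, _K_BOUNDS[1]]),
                                maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return _failed_fit("single", len(t), f"non-convergence: {exc}")
    a, k = float(popt[0]), float(popt[1])
    if a < 1e-3:
        return _failed_fit("single", len(t),
                           "no recovery amplitude; rate unidentifiable")
    sse = float(np.sum((_single_model(t, a, k) - y) ** 2))
    return FrapFit(model="single", amplitudes=(a,), rates=(k,),
                   half_times=(_LN2 / k,), mobile_fraction=a,
                   residual_sse=sse, n_points=len(t), fit_ok=True,
                   aicc=_aicc(sse, len(t), 2),
                   mobile_in_range=0.0 <= a <= 1.05)


def fit_biexponential(curve: RecoveryCurve,
                      fixed_fast_rate: float | None = None) -> FrapFit:
    """Least-squares fit of f(t) = A1 (1-e^{-k1 t}) + A2 (1-e^{-k2 t}).

    Components are ordered fast-to-slow (k1 > k2); the mobile fraction is
    A1 + A2.  If the two rate constants collapse (k1/k2 < 3) the components
    are unresolved: a warning is issued and the single-exponential fit is
    returned instead.

    ``fixed_fast_rate`` optionally pins k1 (e.g. to an independently
    measured free-diffusion rate) and fits only A1, A2, k2.
    """
    t, y = curve.times, curve.values
    if len(t) < 20:
        raise ValueError("need at least 20 post-bleach points")
    single = fit_single_exponential(curve)
    if not single.fit_ok:
        return _failed_fit("biexp", len(t),
                           f"single-exponential seed failed: {single.notes}")
    a_s, k_s = single.amplitudes[0], single.rates[0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fixed_fast_rate is None:
                p0 = [a_s / 2, np.clip(5 * k_s, *_K_BOUNDS),
                      a_s / 2, np.clip(k_s / 5, *_K_BOUNDS)]
                popt, _ = curve_fit(
                    _biexp_model, t, y, p0=p0,
                    bounds=([0.0, _K_BOUNDS[0]] * 2, [_A_MAX, _K_BOUNDS[1]] * 2),
                    maxfev=20000)
                a1, k1, a2, k2 = (float(v) for v in popt)
            else:
                kf = float(fixed_fast_rate)
                model = lambda tt, a1, a2, k2: _biexp_model(tt, a1, kf, a2, k2)
                p0 = [a_s / 2, a_s / 2, np.clip(k_s / 5, *_K_BOUNDS)]
                popt, _ = curve_fit(
                    model, t, y, p0=p0,
                    bounds=([0.0, 0.0, _K_BOUNDS[0]],
                            [_A_MAX, _A_MAX, _K_BOUNDS[1]]),
                    maxfev=20000)
                a1, a2, k2 = (float(v) for v in popt)
                k1 = kf
    except (RuntimeError, ValueError) as exc:
        return _failed_fit("biexp", len(t), f"non-convergence: {exc}")
    if k2 > k1:
        (a1, k1), (a2, k2) = (a2, k2), (a1, k1)
    if k2 <= 0 or k1 / k2 < 3.0:
        warnings.warn("bi-exponential components unresolved (k1/k2 < 3); "
                      "falling back to the single-exponential model",
                      stacklevel=2)
        single.notes = (single.notes + " " if single.notes else "") + \
            "biexp collapsed; single model returned"
        return single
    sse = float(np.sum((_biexp_model(t, a1, k1, a2, k2) - y) ** 2))
    n_params = 3 if fixed_fast_rate is not None else 4
    return FrapFit(model="biexp", amplitudes=(a1, a2), rates=(k1, k2),
                   half_times=(_LN2 / k1, _LN2 / k2),
                   mobile_fraction=a1 + a2, residual_sse=sse,
                   n_points=len(t), fit_ok=True,
                   aicc=_aicc(sse, len(t), n_params),
                   mobile_in_range=0.0 <= a1 + a2 <= 1.05)


def choose_model(curve: RecoveryCurve) -> FrapFit:
    """Fit both recovery models and return the one with the lower
    small-sample-corrected AIC; both scores are recorded on the result.

    A collapsed bi-exponential fit (unresolved components) already falls
    back to the single model inside :func:`fit_biexponential`, so spurious
    two-component wins on one-component data are rare.
    """
    single = fit_single_exponential(curve)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        biexp = fit_biexponential(curve)
    scores = {"single": single.aicc if single.fit_ok else np.inf,
              "biexp": biexp.aicc if (biexp.fit_ok and biexp.model == "biexp")
              else np.inf}
    if not single.fit_ok and not biexp.fit_ok:
        out = _failed_fit("single", len(curve.times),
                          "both model fits failed")
    elif scores["biexp"] < scores["single"]:
        out = biexp
    else:
        out = single
    out.aicc_scores = scores
    return out


def diffusion_coefficient(t_half: float, radius: float) -> float:
    """Diffusion coefficient from a recovery half-time in a circular bleach
    spot, via the uniform-disk relation D = gamma r^2 / t_half with
    gamma ~ 0.224 (the half-recovery root of the closed-form disk curve).

    Parameters are the half-time in seconds and the bleach-spot radius in
    micrometres; the result is in um^2/s.
    """
    if t_half <= 0 or radius <= 0:
        raise ValueError("t_half and radius must be positive")
    return SOUMPASIS_GAMMA * radius * radius / t_half


def summarize_replicates(fits: Sequence[FrapFit]) -> FrapSummary:
    """Mean and sample SD of half-times and mobile fraction over the
    successful fits of one condition; failed fits are excluded and counted."""
    fits = list(fits)
    ok = [f for f in fits if f.fit_ok]
    if not ok:
        raise ValueError("all fits failed; nothing to summarize")
    models = {f.model for f in ok}
    if len(models) > 1:
        # mixed model choice across replicates: summarize the slowest
        # component, which both models share
        model = "mixed"
        ht = np.array([[f.half_times[-1]] for f in ok])
    else:
        model = ok[0].model
        ht = np.array([f.half_times for f in ok])
    mob = np.array([f.mobile_fraction for f in ok])
    sd_ht = tuple(ht.std(axis=0, ddof=1)) if len(ok) >= 2 else None
    sd_mob = float(mob.std(ddof=1)) if len(ok) >= 2 else None
    return FrapSummary(n_fits=len(ok), n_failed=len(fits) - len(ok),
                       model=model, mean_half_times=tuple(ht.mean(axis=0)),
                       sd_half_times=sd_ht, mean_mobile=float(mob.mean()),
                       sd_mobile=sd_mob, fits=fits)
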