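"""Fluorescence recovery after photobleaching (FRAP) analysis.

The pipeline mirrors standard confocal practice for condensates and
nucleoli:

1. background / photofading correction of the bleach-ROI trace, using
   either the mean nuclear intensity (cells) or an unbleached reference
   droplet (in vitro):  I_corr = (I - I_bkgd) / (I_norm - I_bkgd);
2. rescaling so the ten pre-bleach frames average to 1 and the first
   post-bleach frame maps to 0;
3. a hyperbolic recovery fit  R(t) = R_post + R_inf * (t/t_half) /
   (1 + t/t_half)  over post-bleach frames, whose value at t = t_half
   is R_post + R_inf/2;
4. percent mobility M = (mean of the last ten plateau frames) /
   (mean of the ten pre-bleach frames) on the normalized trace;
5. the effective bleach radius r_e from the first post-bleach image,
   normalized by the pre-bleach image and fit to the exponential of a
   Gaussian laser profile  phi(x, y) = F_i * exp(-K * exp(-2 r^2 /
   r_e^2));
6. the apparent diffusion coefficient  D_app = (r_e^2 + r_n^2) /
   (8 * t_half)  with r_n the nominal (user-set) bleach radius.

The mobility statistic uses the plateau average of the last ten frames;
the fitted recovery amplitude R_inf is reported separately (the two
notions coincide only for a fully converged recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FrapSeries",
    "RecoveryFit",
    "FrapError",
    "correct_cell",
    "correct_droplet",
    "normalize_recovery",
    "fit_recovery",
    "mobility",
    "fit_bleach_profile",
    "compute_dapp",
    "extract_traces",
    "analyze",
]


class FrapError(RuntimeError):
    """Raised on degenerate inputs or non-convergent FRAP fits."""


@dataclass
class FrapSeries:
    """Time-stamped FRAP traces plus the images needed for r_e fitting.

    ``bleach_index`` is the index of the first post-bleach frame.
    ``normalizer`` is I_cell(t) for cell FRAP or I_ref(t) for droplet
    FRAP.  Radii and pixel size in micrometers.
    """

    timestamps: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    normalizer: np.ndarray
    bleach_index: int
    r_nominal: float
    pixel_size: float
    postbleach_image: np.ndarray | None = None
    prebleach_image: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.normalizer = np.asarray(self.normalizer, dtype=float)
        n = self.timestamps.size
        if not (self.roi.size == self.background.size == self.normalizer.size == n):
            raise ValueError("trace lengths differ")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.bleach_index < 10:
            raise ValueError("need at least 10 pre-bleach frames")
        if n - self.bleach_index < 10:
            raise ValueError("need at least 10 post-bleach (plateau) frames")
        if self.r_nominal <= 0 or self.pixel_size <= 0:
            raise ValueError("r_nominal and pixel_size must be > 0")


def _correct(series: FrapSeries, what: str) -> np.ndarray:
    denom = series.normalizer - series.background
    bad = np.where(denom <= 0)[0]
    if bad.size:
        raise FrapError(
            f"{what} correction denominator <= 0 at frame {int(bad[0])}"
        )
    return (series.roi - series.background) / denom


def correct_cell(series: FrapSeries) -> np.ndarray:
    """Background/photofading correction against the mean cell intensity."""
    return _correct(series, "cell")


def correct_droplet(series: FrapSeries) -> np.ndarray:
    """Background correction against an unbleached reference droplet."""
    return _correct(series, "droplet")


def normalize_recovery(corrected: np.ndarray, bleach_index: int) -> np.ndarray:
    """Rescale so pre-bleach mean -> 1 and the first post-bleach frame -> 0.

    Uses the mean of the ten frames preceding the bleach and the ROI
    value immediately following the bleach event.
    """
    corrected = np.asarray(corrected, dtype=float)
    if bleach_index < 10 or bleach_index >= corrected.size:
        raise ValueError("bleach_index must allow 10 pre-bleach frames")
    pre = float(np.mean(corrected[bleach_index - 10 : bleach_index]))
    post = float(corrected[bleach_index])
    if pre == post:
        raise FrapError("no bleach depth: pre-bleach mean equals post-bleach value")
    return (corrected - post) / (pre - post)


def fit_recovery(
    normalized: np.ndarray,
    timestamps: np.ndarray,
    bleach_index: int,
) -> tuple[float, float]:
    """Fit the hyperbolic recovery model over post-bleach frames.

    Returns (t_half [s], R_inf).  Time is measured from the bleach
    frame; R_post is fixed at the observed first post-bleach value (0
    on a normalized trace).  Fails explicitly on non-convergence or a
    half-time pinned at its bounds.
    """
    normalized = np.asarray(normalized, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    t = timestamps[bleach_index:] - timestamps[bleach_index]
    y = normalized[bleach_index:]
    r_post = float(y[0])
    dt = float(np.median(np.diff(timestamps)))
    duration = float(t[-1]) if t[-1] > 0 else dt
    lo_t, hi_t = dt / 10.0, 10.0 * duration

    def resid(p):
        t_half, r_inf = p
        return r_post + r_inf * (t / t_half) / (1.0 + t / t_half) - y

    guesses = [duration / 10.0, duration / 2.0, dt]
    best = None
    for g in guesses:
        sol = least_squares(
            resid,
            [np.clip(g, lo_t, hi_t), max(float(y[-1] - r_post), 0.1)],
            bounds=([lo_t, -2.0], [hi_t, 2.0]),
            method="trf",
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FrapError("recovery fit did not converge")
    t_half, r_inf = best.x
    if abs(r_inf) < 1e-3:
        raise FrapError("no measurable recovery amplitude; half-time undetermined")
    if t_half <= lo_t * 1.0001 or t_half >= hi_t * 0.9999:
        raise FrapError(f"recovery half-time pinned at bound (t_half={t_half:.3g} s)")
    return float(t_half), float(r_inf)


def mobility(normalized: np.ndarray, bleach_index: int | None = None) -> float:
    """Percent mobility: plateau average (last ten frames) over the
    pre-bleach average (ten frames before the bleach; 1 on a normalized
    trace when ``bleach_index`` is None)."""
    normalized = np.asarray(normalized, dtype=float)
    plateau = float(np.mean(normalized[-10:]))
    if bleach_index is None:
        pre = 1.0
    else:
        pre = float(np.mean(normalized[bleach_index - 10 : bleach_index]))
    return plateau / pre


def fit_bleach_profile(series: FrapSeries) -> dict:
    """Effective bleach radius from the first post-bleach image.

    The post-bleach image is normalized by the pre-bleach image and fit
    to phi(x,y) = F_i * exp(-K * exp(-2((x-x0)^2+(y-y0)^2)/r_e^2)) with
    center, F_i, K and r_e free.  Returns a dict with r_e in
    micrometers (plus F_i, K and the center in pixels).  Fails when the
    bleach cannot be localized (fitted K <= 0).
    """
    if series.postbleach_image is None or series.prebleach_image is None:
        raise FrapError("bleach-profile fit needs pre- and post-bleach images")
    pre = np.asarray(series.prebleach_image, dtype=float)
    post = np.asarray(series.postbleach_image, dtype=float)
    if pre.shape != post.shape:
        raise FrapError("pre- and post-bleach image shapes differ")
    norm = post / np.clip(pre, 1e-12, None)
    ny, nx = norm.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    # initial guesses: center at the deepest depletion, F_i at the median
    iy, ix = np.unravel_index(np.argmin(norm), norm.shape)
    fi0 = float(np.median(norm))
    k0 = max(float(-np.log(max(norm[iy, ix], 1e-6) / max(fi0, 1e-6))), 0.05)
    re0 = max(series.r_nominal / series.pixel_size, 2.0)

    flat = norm.ravel()
    x_f, y_f = xx.ravel().astype(float), yy.ravel().astype(float)

    def resid(p):
        x0, y0, fi, k, re_px = p
        r2 = (x_f - x0) ** 2 + (y_f - y0) ** 2
        return fi * np.exp(-k * np.exp(-2.0 * r2 / re_px**2)) - flat

    lo = [0.0, 0.0, 0.0, 0.0, 0.5]
    hi = [float(nx), float(ny), 10.0, 20.0, float(max(nx, ny))]
    sol = least_squares(
        resid, [float(ix), float(iy), fi0, k0, re0], bounds=(lo, hi), method="trf"
    )
    if not sol.success:
        raise FrapError("bleach-profile fit did not converge")
    x0, y0, fi, k, re_px = sol.x
    if k <= 1e-3:
        raise FrapError("bleach center not localizable (fitted K <= 0)")
    return {
        "r_e": float(re_px * series.pixel_size),
        "F_i": float(fi),
        "K": float(k),
        "center_px": (float(x0), float(y0)),
    }


def compute_dapp(r_e: float, r_n: float, t_half: float) -> float:
    """Apparent diffusion coefficient D_app = (r_e^2 + r_n^2)/(8 t_half)."""
    if r_e <= 0 or r_n <= 0 or t_half <= 0:
        raise ValueError("radii and half-time must be > 0")
    return (r_e**2 + r_n**2) / (8.0 * t_half)


@dataclass
class RecoveryFit:
    """Full FRAP analysis output for one bleach series."""

    t_half: float
    r_inf: float
    r_post: float
    mobility: float
    r_e: float
    d_app: float

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be > 0")
        if not (-0.2 <= self.mobility <= 1.1):
            raise ValueError(f"mobility {self.mobility:.3f} outside plausible range")
        if self.d_app <= 0:
            raise ValueError("D_app must be > 0")


def _disk_mean(frame: np.ndarray, center, radius_px: float) -> float:
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    mask = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius_px**2
    return float(frame[mask].mean())


def extract_traces(movie: np.ndarray, meta: dict) -> FrapSeries:
    """Build a :class:`FrapSeries` from a movie and its ROI/timing sidecar.

    ``meta`` keys: bleach_index, frame_interval [s], pixel_size [um],
    r_nominal [um], roi_center (x, y) [px], a background source -
    background_box (x0, y0, x1, y1) [px] or a constant dark-frame
    background_value - and either reference_center (droplet mode) or
    normalizer_region ("field" = field/whole-frame mean, cell mode).
    """
    movie = np.asarray(movie, dtype=float)
    n_frames = movie.shape[0]
    dt = float(meta["frame_interval"])
    timestamps = np.arange(n_frames) * dt
    cx, cy = meta["roi_center"]
    r_px = float(meta["r_nominal"]) / float(meta["pixel_size"])
    roi = np.array([_disk_mean(f, (cx, cy), r_px) for f in movie])
    if "background_box" in meta:
        x0, y0, x1, y1 = meta["background_box"]
        bkgd = np.array([float(f[y0:y1, x0:x1].mean()) for f in movie])
    else:
        bkgd = np.full(n_frames, float(meta["background_value"]))
    if "reference_center" in meta:
        rx, ry = meta["reference_center"]
        normalizer = np.array([_disk_mean(f, (rx, ry), r_px) for f in movie])
    else:
        region = meta.get("normalizer_region", "field")
        if region != "field":
            raise ValueError("normalizer_region must be 'field' or give reference_center")
        if "field_center" in meta:
            fx, fy = meta["field_center"]
            fr = float(meta["field_radius_px"])
            normalizer = np.array([_disk_mean(f, (fx, fy), fr) for f in movie])
        else:
            normalizer = np.array([float(f.mean()) for f in movie])
    b = int(meta["bleach_index"])
    return FrapSeries(
        timestamps=timestamps,
        roi=roi,
        background=bkgd,
        normalizer=normalizer,
        bleach_index=b,
        r_nominal=float(meta["r_nominal"]),
        pixel_size=float(meta["pixel_size"]),
        postbleach_image=movie[b],
        prebleach_image=movie[b - 1],
    )


def analyze(series: FrapSeries, mode: str = "droplet") -> RecoveryFit:
    """Run the full pipeline on one series: correction, normalization,
    recovery fit, mobility, bleach-profile fit and D_app."""
    corrected = correct_cell(series) if mode == "cell" else correct_droplet(series)
    norm = normalize_recovery(corrected, series.bleach_index)
    t_half, r_inf = fit_recovery(norm, series.timestamps, series.bleach_index)
    m = mobility(norm)
    profile = fit_bleach_profile(series)
    d_app = compute_dapp(profile["r_e"], series.r_nominal, t_half)
    return RecoveryFit(
        t_half=t_half,
        r_inf=r_inf,
        r_post=float(norm[series.bleach_index]),
        mobility=m,
        r_e=profile["r_e"],
        d_app=d_app,
    )
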