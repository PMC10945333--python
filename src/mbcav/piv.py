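"""Blood-flow particle image velocimetry on RBC speckle.

Preprocessing follows the chain used for the microscopy data: vertical-
stripe suppression in the frequency domain, Gaussian smoothing, contrast
histogram equalization, a rank-maximum filter of radius 2, and Niblack
local-threshold binarization.  Velocimetry is a three-pass cross-correlation
PIV (64→32→16 px interrogation windows, 50% overlap): each pass offsets its
interrogation windows by the previous pass's displacement field, correlates
mean-subtracted windows via FFT, and refines the correlation peak to
sub-pixel precision with a 3-point Gaussian fit.  Low-correlation or
textureless windows are masked invalid, never extrapolated.

Frames coinciding with bubble-driven vessel motion are excluded by a global
inter-frame difference criterion before velocimetry, and slow flow can be
handled by frame skipping (displacements are divided by the skipped
interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sp_signal
from skimage import exposure
from skimage.filters import threshold_niblack

from mbcav.core import FrameSequence


@dataclass
class PreprocessConfig:
    stripe_removal: bool = True
    smoothing_sigma: float = 1.0  # px; 0 disables
    equalization: bool = True
    max_filter_radius: int = 2
    niblack_window: int = 25  # odd
    niblack_k: float = -0.2
    invert: bool = True  # brightfield RBCs are dark; work on bright particles

    def validate(self) -> None:
        if self.max_filter_radius < 1:
            raise ValueError("max_filter_radius must be >= 1")
        if self.niblack_window % 2 == 0 or self.niblack_window < 3:
            raise ValueError("niblack_window must be odd and >= 3")


@dataclass
class PIVConfig:
    window_sizes: tuple[int, ...] = (64, 32, 16)
    overlap: float = 0.5
    frame_skip: int = 0
    subpixel: str = "gaussian-3pt"  # or "parabolic"
    min_correlation: float = 0.2  # NCC peak threshold for validity
    motion_exclusion_factor: float = 5.0  # × median pre-onset frame difference

    def validate(self) -> None:
        ws = self.window_sizes
        if len(ws) < 1 or any(b >= a for a, b in zip(ws, ws[1:])):
            raise ValueError("window sizes must be strictly decreasing")
        if not 0.0 <= self.overlap <= 0.9:
            raise ValueError("overlap must be in [0, 0.9]")
        if self.frame_skip < 0:
            raise ValueError("frame_skip must be >= 0")
        if self.subpixel not in ("gaussian-3pt", "parabolic"):
            raise ValueError("unknown subpixel estimator")


@dataclass
class VelocityField:
    """PIV displacement field on a regular grid (px and px/frame units)."""

    x: np.ndarray  # grid-center columns (px)
    y: np.ndarray  # grid-center rows (px)
    u: np.ndarray  # (ny, nx) horizontal displacement, px per frame pair
    v: np.ndarray  # vertical displacement
    valid: np.ndarray
    window_size: int

    def mean_displacement(self) -> tuple[float, float]:
        if not np.any(self.valid):
            raise ValueError("no valid cells in the velocity field")
        return (
            float(np.mean(self.u[self.valid])),
            float(np.mean(self.v[self.valid])),
        )


# ---------------------------------------------------------------------------
# preprocessing

def remove_vertical_stripes(frame: np.ndarray) -> np.ndarray:
    """Suppress purely vertical stripes in the frequency domain.

    Image content constant along the vertical axis (vertical stripes) lives
    on the zero-vertical-frequency line of the 2-D spectrum; that line is
    zeroed with the DC term preserved.
    """
    spectrum = np.fft.fft2(frame)
    spectrum[0, 1:] = 0.0
    return np.real(np.fft.ifft2(spectrum))


def preprocess_frame(
    frame: np.ndarray, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Apply the preprocessing chain and return a binary particle mask."""
    config = config or PreprocessConfig()
    config.validate()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    if config.invert:
        img = img.max() - img
    if config.stripe_removal:
        img = remove_vertical_stripes(img)
    if config.smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, config.smoothing_sigma)
    span = img.max() - img.min()
    if span == 0:
        return np.zeros_like(img, dtype=bool)
    img = (img - img.min()) / span
    if config.equalization:
        img = exposure.equalize_hist(img)
    r = config.max_filter_radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    img = ndimage.maximum_filter(img, footprint=xx**2 + yy**2 <= r**2)
    thresh = threshold_niblack(
        img, window_size=config.niblack_window, k=config.niblack_k
    )
    return img > thresh


# ---------------------------------------------------------------------------
# multipass cross-correlation

def _correlate(win_a: np.ndarray, win_b: np.ndarray):
    """Full linear cross-correlation of mean-subtracted windows.

    The raw surface carries a triangular overlap weighting that biases the
    peak toward zero lag; it is divided out (unbiased estimator) before the
    peak search, and lags beyond half a window — where the estimator becomes
    noisy — are masked.  Returns (surface, normalization for the NCC
    coefficient at the peak).
    """
    a = win_a - win_a.mean()
    b = win_b - win_b.mean()
    corr = sp_signal.fftconvolve(b, a[::-1, ::-1], mode="full")
    h, w = a.shape

    def tri(n: int) -> np.ndarray:
        return np.concatenate([np.arange(1, n), [n], np.arange(n - 1, 0, -1)])

    overlap = np.outer(tri(h), tri(w)).astype(float)
    corr = corr / overlap * (h * w)
    lag_y = np.arange(corr.shape[0]) - (h - 1)
    lag_x = np.arange(corr.shape[1]) - (w - 1)
    outside = (np.abs(lag_y)[:, None] > h / 2) | (np.abs(lag_x)[None, :] > w / 2)
    corr[outside] = -np.inf
    norm = a.size * a.std() * b.std()
    return corr, norm


def _subpixel_offset(corr: np.ndarray, peak: tuple[int, int], mode: str) -> tuple[float, float]:
    out = []
    for axis, idx in enumerate(peak):
        if idx <= 0 or idx >= corr.shape[axis] - 1:
            out.append(0.0)
            continue
        sl = [peak[0], peak[1]]
        vals = []
        for d in (-1, 0, 1):
            sl[axis] = idx + d
            vals.append(corr[tuple(sl)])
        cm, c0, cp = vals
        if not np.all(np.isfinite(vals)):
            out.append(0.0)
            continue
        if mode == "gaussian-3pt" and min(vals) > 0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
            denom = lm - 2 * l0 + lp
            delta = 0.5 * (lm - lp) / denom if denom != 0 else 0.0
        else:
            denom = cm - 2 * c0 + cp
            delta = 0.5 * (cm - cp) / denom if denom != 0 else 0.0
        out.append(float(np.clip(delta, -1.0, 1.0)))
    return out[0], out[1]


def multipass_piv(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    config: PIVConfig | None = None,
    roi: np.ndarray | None = None,
) -> VelocityField:
    """Multipass window-correlation displacement field from frame a to b.

    Each pass centers its interrogation windows in ``frame_b`` at the
    position predicted by the previous (coarser) pass, so the finest pass
    measures only a residual displacement.  Units are px per frame pair;
    divide by the frame interval actually spanned to get a velocity.

    ``roi`` optionally restricts the field to windows whose center lies in
    a boolean mask (e.g. the vessel lumen), so static background does not
    enter spatial means.
    """
    config = config or PIVConfig()
    config.validate()
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have equal shapes")
    h, w = a.shape

    prev = None  # (x, y, u_filled, v_filled)
    result = None
    for win in config.window_sizes:
        if win > min(h, w):
            raise ValueError(f"window size {win} exceeds frame size {a.shape}")
        step = max(1, int(round(win * (1.0 - config.overlap))))
        xs = np.arange(win // 2, w - win // 2 + 1, step)
        ys = np.arange(win // 2, h - win // 2 + 1, step)
        u = np.full((ys.size, xs.size), np.nan)
        v = np.full((ys.size, xs.size), np.nan)
        valid = np.zeros((ys.size, xs.size), dtype=bool)

        for yi, yc in enumerate(ys):
            for xi, xc in enumerate(xs):
                if roi is not None and not roi[yc, xc]:
                    continue
                du0 = dv0 = 0
                if prev is not None:
                    du0 = int(round(_interp2(prev, xc, yc, 2)))
                    dv0 = int(round(_interp2(prev, xc, yc, 3)))
                ax0, ay0 = xc - win // 2, yc - win // 2
                bx0, by0 = ax0 + du0, ay0 + dv0
                if bx0 < 0 or by0 < 0 or bx0 + win > w or by0 + win > h:
                    bx0, by0 = ax0, ay0
                    du0 = dv0 = 0
                win_a = a[ay0 : ay0 + win, ax0 : ax0 + win]
                win_b = b[by0 : by0 + win, bx0 : bx0 + win]
                if win_a.std() < 1e-9 or win_b.std() < 1e-9:
                    continue
                corr, norm = _correlate(win_a, win_b)
                peak = np.unravel_index(np.argmax(corr), corr.shape)
                if corr[peak] / norm < config.min_correlation:
                    continue
                ddy, ddx = _subpixel_offset(corr, peak, config.subpixel)
                v_meas = peak[0] - (win - 1) + ddy
                u_meas = peak[1] - (win - 1) + ddx
                # reject wrap-around artefacts beyond half a window
                if abs(u_meas) > win / 2 or abs(v_meas) > win / 2:
                    continue
                u[yi, xi] = du0 + u_meas
                v[yi, xi] = dv0 + v_meas
                valid[yi, xi] = True

        valid = _normalized_median_test(u, v, valid)
        u_fill, v_fill = _fill_invalid(u, v, valid)
        prev = (xs, ys, u_fill, v_fill)
        result = VelocityField(x=xs, y=ys, u=u, v=v, valid=valid, window_size=win)
    return result


def _normalized_median_test(
    u: np.ndarray, v: np.ndarray, valid: np.ndarray,
    threshold: float = 2.0, eps: float = 0.1,
) -> np.ndarray:
    """Normalized median outlier detection on a vector field.

    Each vector is compared with the median of its valid 3×3 neighbours; the
    residual, normalized by the median neighbour residual plus ``eps`` px,
    must stay below ``threshold`` in both components.
    """
    ny, nx = u.shape
    out = valid.copy()
    for yi in range(ny):
        for xi in range(nx):
            if not valid[yi, xi]:
                continue
            y0, y1 = max(0, yi - 1), min(ny, yi + 2)
            x0, x1 = max(0, xi - 1), min(nx, xi + 2)
            nb = valid[y0:y1, x0:x1].copy()
            nb[yi - y0, xi - x0] = False
            if nb.sum() < 3:
                continue
            for comp in (u, v):
                vals = comp[y0:y1, x0:x1][nb]
                med = np.median(vals)
                fluct = np.median(np.abs(vals - med))
                if abs(comp[yi, xi] - med) / (fluct + eps) > threshold:
                    out[yi, xi] = False
                    break
    return out


def _fill_invalid(u, v, valid):
    """Replace invalid cells by the median of valid ones (pass-to-pass
    predictor only; the reported field keeps them masked)."""
    if not np.any(valid):
        return np.zeros_like(u), np.zeros_like(v)
    u_fill = np.where(valid, u, np.median(u[valid]))
    v_fill = np.where(valid, v, np.median(v[valid]))
    return u_fill, v_fill


def _interp2(prev, xq: float, yq: float, comp: int) -> float:
    xs, ys = prev[0], prev[1]
    grid = prev[comp]
    xi = np.clip(np.interp(xq, xs, np.arange(xs.size)), 0, xs.size - 1)
    yi = np.clip(np.interp(yq, ys, np.arange(ys.size)), 0, ys.size - 1)
    x0, y0 = int(np.floor(xi)), int(np.floor(yi))
    x1, y1 = min(x0 + 1, xs.size - 1), min(y0 + 1, ys.size - 1)
    fx, fy = xi - x0, yi - y0
    return float(
        grid[y0, x0] * (1 - fx) * (1 - fy)
        + grid[y0, x1] * fx * (1 - fy)
        + grid[y1, x0] * (1 - fx) * fy
        + grid[y1, x1] * fx * fy
    )


# ---------------------------------------------------------------------------
# sequence-level operations

def exclude_motion_frames(
    seq: FrameSequence,
    threshold: float | None = None,
    factor: float = 5.0,
) -> tuple[FrameSequence, list[int]]:
    """Drop frames whose global mean absolute difference from the previous
    frame exceeds the threshold (default: ``factor`` × the median inter-frame
    difference of the pre-onset segment).

    Returns the filtered sequence and the removed frame indices.  The first
    frame is always kept.
    """
    diffs = np.array(
        [np.mean(np.abs(seq.frames[i] - seq.frames[i - 1]))
         for i in range(1, seq.n_frames)]
    )
    if threshold is None:
        pre = diffs[seq.times[1:] < seq.onset_time]
        baseline = pre if pre.size else diffs
        med = float(np.median(baseline))
        if med == 0:
            med = float(np.mean(baseline))
        threshold = factor * med if med > 0 else np.inf
    keep = np.concatenate([[True], diffs <= threshold])
    removed = np.flatnonzero(~keep).tolist()
    if not np.any(keep):
        raise ValueError("all frames excluded: nothing to analyze")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 frames left after motion exclusion")
    return (
        FrameSequence(
            frames=seq.frames[keep],
            times=seq.times[keep],
            frame_rate=seq.frame_rate,
            pixel_pitch=seq.pixel_pitch,
            onset_time=seq.onset_time,
            metadata={**seq.metadata, "excluded_frames": removed},
        ),
        removed,
    )


@dataclass
class FlowSummary:
    """Signed along-vessel velocity time series and reversal classification."""

    times: np.ndarray  # s, midpoint of each frame pair
    velocity_mm_s: np.ndarray  # signed, + = pre-onset flow direction
    peak_speed_mm_s: float
    peak_time: float
    reversal: str  # none | transient | sustained
    reversal_onset_time: float | None
    axis: tuple[float, float]


def vessel_roi(seq: FrameSequence, margin: float = 0.8) -> np.ndarray | None:
    """Lumen mask from phantom ground-truth metadata, if available.

    ``margin`` shrinks the mask so interrogation windows centered on it stay
    clear of the static wall edges.
    """
    meta = seq.metadata
    if "centerline_px" not in meta or "diameter_um" not in meta:
        return None
    pts = np.asarray(meta["centerline_px"], dtype=float)
    radius_px = (
        margin * 0.5 * float(np.min(meta["diameter_um"])) / seq.pixel_pitch
    )
    h, w = seq.frames.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]
    p = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    best = np.full(p.shape[0], np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        ln = np.hypot(*seg)
        if ln == 0:
            continue
        t = np.clip((p - a) @ (seg / ln), 0.0, ln)
        closest = a + t[:, None] * (seg / ln)
        best = np.minimum(best, np.hypot(*(p - closest).T))
    return (best <= radius_px).reshape(h, w)


def piv_sequence(
    seq: FrameSequence,
    config: PIVConfig | None = None,
    roi: np.ndarray | None = None,
) -> tuple[list[VelocityField], np.ndarray]:
    """PIV over consecutive (skip-aware) frame pairs.

    Returns one field per analyzed pair and the pair midpoint times.
    """
    config = config or PIVConfig()
    stride = config.frame_skip + 1
    fields = []
    times = []
    for i in range(0, seq.n_frames - stride, stride):
        fields.append(
            multipass_piv(seq.frames[i], seq.frames[i + stride], config, roi=roi)
        )
        times.append(0.5 * (seq.times[i] + seq.times[i + stride]))
    if not fields:
        raise ValueError("sequence too short for the configured frame skip")
    return fields, np.asarray(times)


def velocity_summary(
    fields: list[VelocityField],
    times: np.ndarray,
    pixel_pitch: float,
    frame_rate: float,
    frame_skip: int = 0,
    onset_time: float = 0.0,
    axis: tuple[float, float] | None = None,
    reversal_threshold_mm_s: float = 0.05,
) -> FlowSummary:
    """Summarize a field sequence into a signed along-vessel velocity trace.

    The along-vessel axis defaults to the mean pre-onset flow direction, so
    positive velocity means "in the original flow direction"; a reversal is
    a sign flip beyond ``reversal_threshold_mm_s``, classified transient if
    the original direction recovers within the sequence and sustained
    otherwise.  Displacements are converted with the pixel pitch and the
    (1 + frame_skip) frame interval actually spanned by each pair.
    """
    times = np.asarray(times, dtype=float)
    px_to_mm_s = pixel_pitch * frame_rate / (1 + frame_skip) / 1000.0
    mean_uv = np.array([f.mean_displacement() for f in fields])  # px/pair

    if axis is None:
        pre = mean_uv[times < onset_time]
        if pre.size == 0:
            raise ValueError(
                "no pre-onset fields to define the flow axis; pass axis="
            )
        direction = pre.mean(axis=0)
        norm = np.hypot(*direction)
        if norm == 0:
            raise ValueError("zero pre-onset flow: axis undefined; pass axis=")
        axis = (direction[0] / norm, direction[1] / norm)
    else:
        norm = np.hypot(*axis)
        axis = (axis[0] / norm, axis[1] / norm)

    signed = (mean_uv @ np.asarray(axis)) * px_to_mm_s
    ipeak = int(np.argmax(np.abs(signed)))
    below = signed < -reversal_threshold_mm_s
    if not np.any(below):
        reversal, onset = "none", None
    else:
        first = int(np.argmax(below))
        recovered = np.any(signed[first:] > reversal_threshold_mm_s)
        reversal = "transient" if recovered else "sustained"
        onset = float(times[first])
    return FlowSummary(
        times=times,
        velocity_mm_s=signed,
        peak_speed_mm_s=float(np.abs(signed[ipeak])),
        peak_time=float(times[ipeak]),
        reversal=reversal,
        reversal_onset_time=onset,
        axis=axis,
    )
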