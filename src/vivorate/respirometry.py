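"""Video respirometry: track flank motion, build a waveform, estimate rate.

The measurement chain mirrors the non-contact technique it re-implements:

1. Shi-Tomasi corners are seeded inside user-drawn (or automatic) regions
   of interest on the first frame — up to 10 per region.
2. The corners are tracked through the clip with pyramidal Lucas-Kanade
   optical flow, with forward-backward re-tracking as a failure check.
3. Each track is projected onto its principal motion axis, detrended and
   normalized; the per-frame median across sign-aligned tracks is the
   respiration waveform. Amplitude depends on camera distance and angle;
   the frequency does not, and is the quantity of interest.
4. The rate in breaths/min is the interpolated periodogram peak within a
   physiological band (default 60-400 bpm), with quality control based on
   spectral peak prominence and inter-breath-interval regularity —
   automating the manual "regular breathing only" clip screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter, uniform_filter1d
from shapely.geometry import Point, Polygon
from skimage.draw import polygon2mask
from skimage.feature import corner_shi_tomasi, peak_local_max

from ._lucas_kanade import LKParams, track_points
from .video import FrameSequence

__all__ = [
    "FrameSequence",
    "RoiContour",
    "FeatureTrack",
    "RespirationSignal",
    "RateEstimate",
    "MouseRateResult",
    "detect_features",
    "track_features",
    "build_waveform",
    "estimate_rate",
    "summarize_mouse",
    "validate_against_reference",
    "auto_roi",
    "estimate_rate_from_clip",
    "run_synthetic_validation",
]


@dataclass
class RoiContour:
    """Simple polygon (row, col vertices) delimiting a tracked region."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3 or self.vertices.shape[1] != 2:
            raise ValueError("RoiContour needs >= 3 (row, col) vertices")
        if not Polygon(self.vertices).is_valid:
            raise ValueError("ROI polygon is self-intersecting or degenerate")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def check_in_frame(self, shape: tuple[int, int]) -> None:
        v = self.vertices
        if v[:, 0].min() < 0 or v[:, 1].min() < 0 or v[:, 0].max() > shape[0] - 1 or v[
            :, 1
        ].max() > shape[1] - 1:
            raise ValueError("ROI polygon extends outside the frame")


@dataclass
class FeatureTrack:
    """One corner's trajectory through the clip.

    Once a point is lost (tracker failure or forward-backward error above
    threshold) it stays lost; ``positions`` are NaN on invalid frames.
    """

    point_id: int
    positions: np.ndarray  # (n_frames, 2) (row, col), sub-pixel
    valid: np.ndarray      # (n_frames,) bool

    @property
    def coverage(self) -> float:
        return float(self.valid.mean())

    @property
    def seed(self) -> np.ndarray:
        return self.positions[0]


@dataclass
class RespirationSignal:
    """Detrended, zero-mean 1-D respiratory motion waveform."""

    samples: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fps


@dataclass
class RateEstimate:
    rate_bpm: float
    band_bpm: tuple[float, float]
    peak_prominence: float
    ibi_cv: float
    n_points_used: int
    qc_pass: bool


@dataclass
class MouseRateResult:
    clip_estimates: list[RateEstimate]
    summary_bpm: float
    n_clips: int  # number of QC-passing clips contributing to the summary


def detect_features(
    seq: FrameSequence,
    rois: list[RoiContour],
    max_per_roi: int = 10,
    min_distance: int = 7,
    sigma: float = 1.5,
) -> np.ndarray:
    """Seed up to ``max_per_roi`` Shi-Tomasi corners per ROI on frame 0.

    Corners are ranked by the minimum eigenvalue of the local gradient
    structure tensor and separated by at least ``min_distance`` px; every
    seed lies strictly inside its ROI polygon. A region with no detectable
    corner yields a warning and contributes nothing; if all regions are
    empty a ``ValueError`` is raised.

    Returns an (N, 2) array of (row, col) seed positions.
    """
    frame = np.asarray(seq.frames[0], dtype=float)
    if frame.max() > 1.5:
        frame = frame / 255.0
    shape = frame.shape
    response = corner_shi_tomasi(frame, sigma=sigma)

    seeds: list[np.ndarray] = []
    for k, roi in enumerate(rois):
        roi.check_in_frame(shape)
        mask = polygon2mask(shape, roi.vertices)
        masked = np.where(mask, response, 0.0)
        peaks = peak_local_max(
            masked,
            min_distance=min_distance,
            num_peaks=max_per_roi,
            threshold_abs=1e-8,
            exclude_border=True,
        )
        poly = roi.polygon()
        peaks = np.array([p for p in peaks if poly.contains(Point(p))], dtype=float)
        if len(peaks) == 0:
            warnings.warn(f"ROI {k} contains no detectable corners", stacklevel=2)
            continue
        seeds.append(peaks)
    if not seeds:
        raise ValueError("no detectable corners in any ROI")
    return np.concatenate(seeds)


def track_features(
    seq: FrameSequence,
    seeds: np.ndarray,
    params: LKParams | None = None,
    fb_threshold: float = 1.0,
) -> list[FeatureTrack]:
    """Track frame-0 seeds through the clip with pyramidal Lucas-Kanade.

    Raises ``RuntimeError("tracking lost")`` when every point is lost
    before half of the frames have been tracked.
    """
    seeds = np.asarray(seeds, dtype=float)
    positions, valid = track_points(seq.frames, seeds, params=params, fb_threshold=fb_threshold)
    any_alive = valid.any(axis=1)
    if not any_alive.all():
        last = int(np.nonzero(any_alive)[0].max()) if any_alive.any() else -1
        if (last + 1) < 0.5 * seq.n_frames:
            raise RuntimeError("tracking lost: all points invalid before 50% of frames")
    return [
        FeatureTrack(point_id=i, positions=positions[:, i], valid=valid[:, i])
        for i in range(len(seeds))
    ]


def _principal_projection(track: FeatureTrack) -> np.ndarray:
    """Project positions onto the track's first principal motion axis."""
    pos = track.positions[track.valid]
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = np.full(len(track.positions), np.nan)
    proj[track.valid] = centered @ vt[0]
    return proj


def build_waveform(
    tracks: list[FeatureTrack],
    fps: float,
    min_coverage: float = 0.5,
    detrend_s: float = 1.0,
) -> RespirationSignal:
    """Combine tracks into one respiration waveform.

    Each qualifying track (valid on >= ``min_coverage`` of frames) is
    projected on its principal axis, detrended by subtracting a 1-s moving
    average, and normalized to unit SD. Tracks are sign-aligned to the
    first (flipped when negatively correlated — flank and shadow move in
    opposite phase) and combined by pointwise median, ignoring frames
    where a track is invalid.
    """
    usable = [t for t in tracks if t.coverage >= min_coverage]
    if not usable:
        raise ValueError(f"no track is valid on >= {min_coverage:.0%} of frames")

    win = max(3, int(round(detrend_s * fps)))
    series = []
    for t in usable:
        proj = _principal_projection(t)
        filled = np.where(np.isnan(proj), np.nanmean(proj), proj)
        detrended = filled - uniform_filter1d(filled, win, mode="nearest")
        detrended[~t.valid] = np.nan
        sd = np.nanstd(detrended)
        if sd > 0:
            series.append(detrended / sd)
    if not series:
        raise ValueError("all qualifying tracks are constant after detrending")

    stack = np.vstack(series)
    ref = stack[0]
    for i in range(1, len(stack)):
        both = np.isfinite(ref) & np.isfinite(stack[i])
        if both.sum() >= 3 and np.nanstd(stack[i][both]) > 0:
            c = np.corrcoef(ref[both], stack[i][both])[0, 1]
            if c < 0:
                stack[i] = -stack[i]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        combined = np.nanmedian(stack, axis=0)
    # Trim trailing frames with no valid contribution.
    finite = np.isfinite(combined)
    if not finite.all():
        last = int(np.nonzero(finite)[0].max())
        combined = combined[: last + 1]
        combined = np.where(np.isfinite(combined), combined, 0.0)
    combined = combined - combined.mean()
    return RespirationSignal(samples=combined, fps=fps)


def _parabolic_refine(logp: np.ndarray, i: int) -> float:
    """Sub-bin peak location via parabola through log-power neighbors."""
    if i <= 0 or i >= len(logp) - 1:
        return 0.0
    a, b, c = logp[i - 1], logp[i], logp[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


def estimate_rate(
    sig: RespirationSignal,
    band_bpm: tuple[float, float] = (60.0, 400.0),
    prominence_threshold: float = 5.0,
    ibi_cv_threshold: float = 0.25,
    n_points_used: int = 0,
) -> RateEstimate:
    """Estimate breathing rate from a waveform.

    The rate is the largest periodogram peak inside ``band_bpm``, refined
    by parabolic interpolation of the log spectrum. Peak prominence (peak
    power over the median in-band power) and the coefficient of variation
    of inter-breath intervals (peak-to-peak on the band-passed waveform)
    drive the QC flag that stands in for manual clip screening.
    """
    x = np.asarray(sig.samples, dtype=float)
    if len(x) < 2 * sig.fps:
        raise ValueError("signal must span at least 2 seconds")
    x = x - x.mean()

    from scipy.fft import next_fast_len

    nfft = int(next_fast_len(8 * len(x)))
    window = np.hanning(len(x))
    spectrum = np.abs(np.fft.rfft(x * window, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sig.fps)

    lo_hz, hi_hz = band_bpm[0] / 60.0, band_bpm[1] / 60.0
    in_band = (freqs >= lo_hz) & (freqs <= min(hi_hz, sig.fps / 2))
    flagged = False
    if not in_band.any() or spectrum[in_band].max() <= 0:
        i = int(np.argmax(spectrum[1:]) + 1)
        flagged = True
    else:
        band_idx = np.nonzero(in_band)[0]
        i = int(band_idx[np.argmax(spectrum[band_idx])])
    logp = np.log(np.maximum(spectrum, 1e-300))
    f_hat = freqs[i] + _parabolic_refine(logp, i) * (freqs[1] - freqs[0])
    rate_bpm = 60.0 * f_hat

    med = np.median(spectrum[in_band]) if in_band.any() else np.median(spectrum[1:])
    prominence = float(spectrum[i] / med) if med > 0 else np.inf

    ibi_cv = _ibi_cv(x, sig.fps, f_hat)

    qc = (
        not flagged
        and prominence >= prominence_threshold
        and ibi_cv <= ibi_cv_threshold
        and band_bpm[0] <= rate_bpm <= band_bpm[1]
    )
    return RateEstimate(
        rate_bpm=float(rate_bpm),
        band_bpm=tuple(band_bpm),
        peak_prominence=prominence,
        ibi_cv=float(ibi_cv),
        n_points_used=int(n_points_used),
        qc_pass=bool(qc),
    )


def _ibi_cv(x: np.ndarray, fps: float, f_hz: float) -> float:
    """CV of inter-breath intervals from peaks of the band-passed signal."""
    if f_hz <= 0 or not np.isfinite(f_hz):
        return np.inf
    lo = max(0.5 * f_hz, 0.05)
    hi = min(1.8 * f_hz, 0.49 * fps)
    if lo >= hi:
        return np.inf
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fps, output="sos")
    xb = sps.sosfiltfilt(sos, x)
    min_dist = max(1, int(round(0.6 * fps / f_hz)))
    peaks, _ = sps.find_peaks(xb, distance=min_dist, prominence=0.5 * np.std(xb))
    if len(peaks) < 3:
        return np.inf
    ibis = np.diff(peaks) / fps
    return float(np.std(ibis) / np.mean(ibis))


def summarize_mouse(estimates: list[RateEstimate], min_clips: int = 5) -> MouseRateResult:
    """Median breathing rate across a mouse's QC-passing clips.

    Emits a warning (not an error) when fewer than ``min_clips`` clips
    pass QC; raises when none do.
    """
    if not estimates:
        raise ValueError("need at least one clip estimate")
    passing = [e.rate_bpm for e in estimates if e.qc_pass]
    if not passing:
        raise ValueError("no clip passed QC; cannot summarize")
    if len(passing) < min_clips:
        warnings.warn(
            f"only {len(passing)} QC-passing clips (< {min_clips}); summary may be unstable",
            stacklevel=2,
        )
    return MouseRateResult(
        clip_estimates=list(estimates),
        summary_bpm=float(np.median(passing)),
        n_clips=len(passing),
    )


def validate_against_reference(
    pairs: list[tuple[float, float]], tol_bpm: float = 5.0
) -> float:
    """Fraction of (estimated, reference) pairs agreeing within ``tol_bpm``."""
    if len(pairs) == 0:
        raise ValueError("need at least one (estimated, reference) pair")
    arr = np.asarray(pairs, dtype=float)
    return float(np.mean(np.abs(arr[:, 0] - arr[:, 1]) <= tol_bpm))


def auto_roi(
    seq: FrameSequence,
    n_frames: int = 150,
    quantile: float = 0.90,
    smooth_sigma: float = 3.0,
) -> RoiContour:
    """Select the highest-temporal-variance region as a rectangular ROI.

    A hands-off stand-in for manually drawn contours: respiration moves
    fur, so per-pixel temporal variance highlights the flank.
    """
    sub = np.asarray(seq.frames[: min(n_frames, seq.n_frames)], dtype=float)
    var = gaussian_filter(sub.var(axis=0), smooth_sigma)
    thresh = np.quantile(var, quantile)
    mask = var >= thresh
    from scipy.ndimage import label

    labels, n = label(mask)
    if n == 0:
        raise ValueError("no moving region found")
    sizes = np.bincount(labels.ravel())[1:]
    rr, cc = np.nonzero(labels == 1 + int(np.argmax(sizes)))
    r0, r1, c0, c1 = rr.min(), rr.max(), cc.min(), cc.max()
    if r1 - r0 < 4 or c1 - c0 < 4:
        raise ValueError("moving region too small for an ROI")
    return RoiContour(np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=float))


def estimate_rate_from_clip(
    seq: FrameSequence,
    rois: list[RoiContour] | None = None,
    band_bpm: tuple[float, float] = (60.0, 400.0),
    max_per_roi: int = 10,
    lk_params: LKParams | None = None,
    **rate_kwargs,
) -> RateEstimate:
    """Full pipeline on one clip: detect -> track -> waveform -> rate."""
    if rois is None:
        rois = [auto_roi(seq)]
    seeds = detect_features(seq, rois, max_per_roi=max_per_roi)
    tracks = track_features(seq, seeds, params=lk_params)
    wave = build_waveform(tracks, seq.fps)
    est = estimate_rate(wave, band_bpm=band_bpm, **rate_kwargs)
    est.n_points_used = len(tracks)
    return est


def run_synthetic_validation(
    n_clips: int = 100,
    seed: int = 1,
    rate_range_bpm: tuple[float, float] = (100.0, 250.0),
    amplitude_px: float = 2.0,
    jitter_cv: float = 0.05,
    noise_sd: float = 0.02,
    duration_s: float = 20.0,
    fps: float = 30.0,
):
    """Pipeline validation on seeded synthetic clips with known rates.

    Renders ``n_clips`` clips with rates drawn uniformly from
    ``rate_range_bpm`` and runs the full detect -> track -> waveform ->
    rate chain on each, using the ground-truth flank region as the ROI.
    This is the synthetic surrogate for validation against visually
    counted breaths on real videos (agreement within 5 bpm expected on
    ~98% of clips).

    Returns a DataFrame with columns ``true_bpm``, ``estimated_bpm``,
    ``abs_error_bpm``, ``qc_pass``.
    """
    import pandas as pd

    from .synthetic_video import BreathingScenario, flank_roi, render_breathing_clip

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_clips):
        rate = float(rng.uniform(*rate_range_bpm))
        clip_seed = int(rng.integers(0, 2**31 - 1))
        scenario = BreathingScenario(
            rate_bpm=rate,
            amplitude_px=amplitude_px,
            fps=fps,
            duration_s=duration_s,
            jitter_cv=jitter_cv,
            noise_sd=noise_sd,
            seed=clip_seed,
        )
        seq, truth = render_breathing_clip(scenario)
        est = estimate_rate_from_clip(seq, [RoiContour(flank_roi(scenario))])
        rows.append(
            {
                "true_bpm": truth.true_rate_bpm,
                "estimated_bpm": est.rate_bpm,
                "abs_error_bpm": abs(est.rate_bpm - truth.true_rate_bpm),
                "qc_pass": est.qc_pass,
            }
        )
    return pd.DataFrame(rows)
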