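"""Ground-truth breathing-video generator.

Renders clips that emulate an overhead webcam view of a sleeping mouse:
a static speckle background and an elliptical "flank" patch whose texture
translates along a fixed axis following a quasi-periodic breathing
waveform. The generator exists so the respirometry pipeline can be tested
against known rates, displacements and breath onsets without animal
footage.

The breathing waveform is a raised cosine per cycle with a 0.4/0.6
inhale/exhale asymmetry — inhalation is faster than exhalation in rodents —
which keeps the fundamental frequency exactly at the breath rate while
avoiding a pure sinusoid. Inter-breath intervals are jittered with a
truncated normal of the requested coefficient of variation. Three event
kinds stress the quality-control logic that replaces manual clip
screening: ``gasp`` (one cycle at 3x amplitude), ``pause`` (a flat,
breathless segment) and ``sniff`` (a burst at 3x rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .video import FrameSequence, read_frames, write_frames  # noqa: F401  (re-export)

EVENT_KINDS = ("gasp", "pause", "sniff")
_INHALE_FRACTION = 0.4  # raised-cosine peak position within a cycle


@dataclass(frozen=True)
class BreathingEvent:
    kind: str
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class BreathingScenario:
    """Declarative description of a synthetic breathing clip.

    Parameters
    ----------
    rate_bpm
        Nominal breathing rate in breaths per minute.
    amplitude_px
        Peak flank-texture displacement in pixels.
    fps, duration_s
        Frame rate and clip length.
    jitter_cv
        Coefficient of variation of inter-breath intervals (< 1).
    drift_px_per_s
        Global linear scene drift (row, col) in px/s, emulating slow
        camera or whole-body motion.
    noise_sd
        Additive Gaussian intensity noise, as a fraction of the 8-bit
        dynamic range.
    events
        Irregular-breathing events (gasp / pause / sniff).
    frame_shape
        (rows, cols) of the rendered frames; default desk-scale 256x256.
    axis_deg
        Direction of breathing motion (0 = along columns, 90 = along rows).
    """

    rate_bpm: float = 150.0
    amplitude_px: float = 2.0
    fps: float = 30.0
    duration_s: float = 20.0
    jitter_cv: float = 0.0
    drift_px_per_s: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    events: tuple[BreathingEvent, ...] = ()
    seed: int = 0
    frame_shape: tuple[int, int] = (256, 256)
    axis_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0 or self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("rate_bpm, fps and duration_s must be positive")
        if self.amplitude_px < 0 or self.noise_sd < 0:
            raise ValueError("amplitude_px and noise_sd must be non-negative")
        if not self.rate_bpm / 60.0 < self.fps / 2.0:
            raise ValueError(
                f"rate {self.rate_bpm} bpm is at or above the Nyquist limit "
                f"for fps={self.fps} ({self.fps * 30} bpm)"
            )
        if self.duration_s * self.rate_bpm / 60.0 < 2.0:
            raise ValueError("clip must span at least 2 full breath periods")
        if not 0 <= self.jitter_cv < 1:
            raise ValueError("jitter_cv must lie in [0, 1)")
        object.__setattr__(self, "events", tuple(
            e if isinstance(e, BreathingEvent) else BreathingEvent(*e) for e in self.events
        ))

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit motion axis as a (row, col) vector."""
        theta = np.deg2rad(self.axis_deg)
        return np.array([np.sin(theta), np.cos(theta)])


@dataclass
class GroundTruth:
    """Realized truth for one rendered clip."""

    true_rate_bpm: float
    breath_onsets_s: np.ndarray
    displacement_series: np.ndarray  # (n_frames, 2) true patch offset, (row, col) px
    ellipse_center: tuple[float, float]
    ellipse_axes: tuple[float, float]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.breath_onsets_s, float)
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("breath onsets must be strictly increasing")
        self.breath_onsets_s = onsets
        self.displacement_series = np.asarray(self.displacement_series, float)


def _cycle_shape(u: np.ndarray) -> np.ndarray:
    """Raised-cosine breath shape on cycle phase u in [0, 1): 0 -> 1 -> 0."""
    s = np.empty_like(u)
    a = _INHALE_FRACTION
    rising = u < a
    s[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / a))
    s[~rising] = 0.5 * (1.0 + np.cos(np.pi * (u[~rising] - a) / (1.0 - a)))
    return s


def _breath_cycles(
    scenario: BreathingScenario, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """March breath cycles across the clip: (onset_s, interval_s, amp_mult)."""
    base = 60.0 / scenario.rate_bpm
    pauses = [e for e in scenario.events if e.kind == "pause"]
    sniffs = [e for e in scenario.events if e.kind == "sniff"]
    gasps = [e for e in scenario.events if e.kind == "gasp"]

    cycles: list[tuple[float, float, float]] = []
    t = -rng.uniform(0.0, 1.0) * base  # random initial phase
    while t < scenario.duration_s:
        skipped = True
        while skipped:
            skipped = False
            for p in pauses:
                if p.contains(t):
                    t = p.end_s
                    skipped = True
        if t >= scenario.duration_s:
            break
        interval = base * max(0.2, 1.0 + scenario.jitter_cv * rng.standard_normal())
        if any(s.contains(t) for s in sniffs):
            interval /= 3.0
        amp = 3.0 if any(g.contains(t) for g in gasps) else 1.0
        cycles.append((t, interval, amp))
        t += interval
    return cycles


def _waveform(
    scenario: BreathingScenario, cycles: list[tuple[float, float, float]], times: np.ndarray
) -> np.ndarray:
    """Evaluate the unit breathing waveform s(t) at the frame times."""
    s = np.zeros_like(times)
    for onset, interval, amp in cycles:
        in_cycle = (times >= onset) & (times < onset + interval)
        if np.any(in_cycle):
            u = (times[in_cycle] - onset) / interval
            s[in_cycle] = amp * _cycle_shape(u)
    return s


def _speckle(shape: tuple[int, int], rng: np.random.Generator, sigma: float = 1.2) -> np.ndarray:
    """Smooth speckle texture in [0.15, 0.85]; dense in trackable corners."""
    tex = gaussian_filter(rng.uniform(size=shape), sigma)
    lo, hi = tex.min(), tex.max()
    return 0.15 + 0.7 * (tex - lo) / (hi - lo)


def render_breathing_clip(scenario: BreathingScenario) -> tuple[FrameSequence, GroundTruth]:
    """Render a clip and its ground truth.

    The whole scene (background and flank ellipse) drifts linearly with
    ``drift_px_per_s``; the flank texture additionally translates by
    ``amplitude_px * s(t)`` along the motion axis. The returned
    :class:`GroundTruth` records the realized rate (from the jittered
    cycles actually placed in the clip), the breath onsets within the
    clip, and the per-frame total patch offset (breathing + drift).
    Identical scenarios (including seed) render bit-identical frames.
    """
    rng = np.random.default_rng(scenario.seed)
    h, w = scenario.frame_shape
    n_frames = int(round(scenario.duration_s * scenario.fps))
    times = np.arange(n_frames) / scenario.fps

    cycles = _breath_cycles(scenario, rng)
    s = _waveform(scenario, cycles, times)
    onsets = np.array([c[0] for c in cycles if 0.0 <= c[0] < scenario.duration_s])
    intervals = np.array([c[1] for c in cycles])
    true_rate = 60.0 / float(np.mean(intervals))

    drift = np.asarray(scenario.drift_px_per_s, float)
    scene_offset = times[:, None] * drift[None, :]  # (n, 2)
    breath_offset = scenario.amplitude_px * s[:, None] * scenario.axis_unit[None, :]
    patch_offset = scene_offset + breath_offset

    # Textures on padded canvases so drifted sampling never leaves them.
    max_off = int(np.ceil(np.abs(patch_offset).max())) + 4 if n_frames else 4
    bg_tex = _speckle((h + 2 * max_off, w + 2 * max_off), rng)
    patch_tex = _speckle((h + 2 * max_off, w + 2 * max_off), rng)

    center = np.array([0.5 * h, 0.5 * w])
    axes = np.array([0.22 * h, 0.30 * w])  # ellipse semi-axes (rows, cols)

    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    static_scene = not np.any(drift)
    if static_scene:
        bg0 = bg_tex[max_off : max_off + h, max_off : max_off + w]
        inside0 = ((rows - center[0]) / axes[0]) ** 2 + ((cols - center[1]) / axes[1]) ** 2 <= 1.0
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for i in range(n_frames):
        so = scene_offset[i]
        if static_scene:
            bg, inside = bg0.copy(), inside0
        else:
            bg = map_coordinates(
                bg_tex, [rows + max_off - so[0], cols + max_off - so[1]], order=1, mode="nearest"
            )
            # Ellipse rides the scene drift.
            c = center + so
            inside = ((rows - c[0]) / axes[0]) ** 2 + ((cols - c[1]) / axes[1]) ** 2 <= 1.0
        if np.any(inside):
            po = patch_offset[i]
            patch = map_coordinates(
                patch_tex,
                [rows[inside] + max_off - po[0], cols[inside] + max_off - po[1]],
                order=1,
                mode="nearest",
            )
            bg[inside] = patch
        if scenario.noise_sd > 0:
            bg = bg + scenario.noise_sd * rng.standard_normal(bg.shape)
        frames[i] = np.clip(np.round(bg * 255), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        true_rate_bpm=true_rate,
        breath_onsets_s=onsets,
        displacement_series=patch_offset,
        ellipse_center=tuple(center),
        ellipse_axes=tuple(axes),
    )
    return FrameSequence(frames=frames, fps=scenario.fps), truth


def flank_roi(scenario: BreathingScenario, inset: float = 0.6, n_vertices: int = 16) -> np.ndarray:
    """Polygon (row, col vertices) well inside the flank ellipse at frame 0.

    ``inset`` scales the ellipse semi-axes so tracked corners stay clear of
    the patch boundary throughout the clip.
    """
    h, w = scenario.frame_shape
    center = np.array([0.5 * h, 0.5 * w])
    axes = inset * np.array([0.22 * h, 0.30 * w])
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([
        center[0] + axes[0] * np.sin(theta),
        center[1] + axes[1] * np.cos(theta),
    ])
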