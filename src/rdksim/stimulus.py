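"""Transparent random-dot stimuli and static line-angle comparison stimuli.

Two spatially overlapping random-dot patches drift inside a static circular
aperture.  Each patch carries a *signal* direction; motion coherence is the
fraction of a patch's dots translating in that direction while the remaining
noise dots translate in their own random directions.  Dots have unlimited
lifetime and wrap to the far side of the aperture when they exit.  The
perceived direction separation of the pair is probed with a static two-line
angle stimulus.

Angles follow the mathematical convention: degrees counter-clockwise, 90°
pointing upward, so the default stimulus drifts upward on average.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "DotFieldState",
    "LineStimulus",
    "ValidationError",
    "ContractError",
    "make_stimulus_spec",
    "make_line_stimulus",
    "dots_per_patch",
    "init_dot_field",
    "advance_frame",
    "wrap_position",
    "empirical_coherence",
    "direction_histogram",
    "render_frame",
    "simulate_trajectory",
    "trajectory_table",
]


class ValidationError(ValueError):
    """Raised when stimulus or configuration parameters are out of range."""


class ContractError(RuntimeError):
    """Raised when an operation is called outside its contract."""


@dataclass(frozen=True)
class StimulusSpec:
    """Full parameterization of one transparent-motion trial stimulus.

    Defaults reproduce the standard display: a 7.5° aperture, 3.4 dots/deg²
    per patch, 0.075° dots, 5°/s drift, 100 Hz refresh, 3 s presentation,
    vector-averaged direction 90° (upward).
    """

    direction_separation: float
    coherence: float
    aperture_diameter: float = 7.5
    dot_density: float = 3.4
    dot_size: float = 0.075
    speed: float = 5.0
    refresh_rate: float = 100.0
    duration: float = 3.0
    vector_average_direction: float = 90.0
    pixel_pitch: float = 0.0375
    #: "fixed": each noise dot keeps one random direction for the whole
    #: presentation (default; unlimited lifetime reading).  "walk": noise
    #: directions are re-drawn every frame (random-walk noise).
    noise_mode: str = "fixed"
    #: recorded metadata only; luminance is never modelled
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.direction_separation < 0:
            raise ValidationError(
                f"direction_separation must be >= 0, got {self.direction_separation}"
            )
        if not 0.0 <= self.coherence <= 1.0:
            raise ValidationError(f"coherence must lie in [0, 1], got {self.coherence}")
        for name in ("aperture_diameter", "speed", "refresh_rate", "duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.dot_density < 0:
            raise ValidationError("dot_density must be >= 0")
        if self.noise_mode not in ("fixed", "walk"):
            raise ValidationError(f"unknown noise_mode {self.noise_mode!r}")
        n_frames = self.duration * self.refresh_rate
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValidationError(
                "duration x refresh_rate must be a whole number of frames"
            )

    @property
    def radius(self) -> float:
        return self.aperture_diameter / 2.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.refresh_rate))

    @property
    def frame_displacement(self) -> float:
        """Per-frame dot displacement in degrees."""
        return self.speed / self.refresh_rate

    @property
    def component_directions(self) -> tuple[float, float]:
        """The two patch directions, vector-averaged at 90° by default."""
        half = self.direction_separation / 2.0
        return (
            self.vector_average_direction - half,
            self.vector_average_direction + half,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("metadata")
        return d


def make_stimulus_spec(
    direction_separation: float, coherence: float, **overrides
) -> StimulusSpec:
    """Build a fully defaulted :class:`StimulusSpec`."""
    return StimulusSpec(
        direction_separation=direction_separation, coherence=coherence, **overrides
    )


@dataclass(frozen=True)
class LineStimulus:
    """Two static lines meeting at the aperture center, forming an angle."""

    angle: float
    line_length: float = 3.75
    line_width: float = 0.04
    vector_average_orientation: float = 90.0

    def __post_init__(self) -> None:
        if self.angle < 0:
            raise ValidationError(f"line angle must be >= 0, got {self.angle}")

    @property
    def orientations(self) -> tuple[float, float]:
        half = self.angle / 2.0
        return (
            self.vector_average_orientation - half,
            self.vector_average_orientation + half,
        )


def make_line_stimulus(angle: float, **overrides) -> LineStimulus:
    return LineStimulus(angle=angle, **overrides)


@dataclass
class DotFieldState:
    """Per-dot positions, patch/signal assignments and directions at one frame.

    Arrays are parallel over dots (both patches concatenated).  ``direction``
    holds the patch direction for signal dots and the dot's own random
    direction for noise dots.
    """

    frame_index: int
    patch_id: np.ndarray  # int, 1 or 2
    x: np.ndarray
    y: np.ndarray
    is_signal: np.ndarray  # bool
    direction: np.ndarray  # degrees

    @property
    def n_dots(self) -> int:
        return self.x.size

    def copy(self) -> "DotFieldState":
        return DotFieldState(
            frame_index=self.frame_index,
            patch_id=self.patch_id.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            is_signal=self.is_signal.copy(),
            direction=self.direction.copy(),
        )


def dots_per_patch(spec: StimulusSpec) -> int:
    """Number of dots in each patch: round(density × aperture area)."""
    area = math.pi * spec.radius**2
    return int(round(spec.dot_density * area))


def init_dot_field(spec: StimulusSpec, seed) -> DotFieldState:
    """Scatter two dot patches uniformly in the aperture and assign signal dots.

    Exactly ``round(coherence × N)`` dots per patch are flagged as signal;
    the remaining dots receive independent uniform-random directions.
    ``seed`` may be an int, a SeedSequence or a Generator.
    """
    rng = np.random.default_rng(seed)
    n = dots_per_patch(spec)
    n_signal = int(round(spec.coherence * n))
    dir1, dir2 = spec.component_directions

    patch_id = np.repeat(np.array([1, 2], dtype=np.int8), n)
    # uniform in the disk via sqrt-radius sampling
    r = spec.radius * np.sqrt(rng.uniform(size=2 * n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=2 * n)
    x = r * np.cos(theta)
    y = r * np.sin(theta)

    is_signal = np.zeros(2 * n, dtype=bool)
    direction = np.empty(2 * n, dtype=float)
    for patch, patch_dir in ((1, dir1), (2, dir2)):
        idx = np.flatnonzero(patch_id == patch)
        chosen = rng.permutation(idx)[:n_signal]
        is_signal[chosen] = True
        direction[idx] = rng.uniform(0.0, 360.0, size=idx.size)
        direction[chosen] = patch_dir
    return DotFieldState(
        frame_index=0,
        patch_id=patch_id,
        x=x,
        y=y,
        is_signal=is_signal,
        direction=direction,
    )


def wrap_position(
    position: tuple[float, float], direction: float, radius: float
) -> tuple[float, float]:
    """Wrap a dot that stepped onto or past the aperture boundary.

    The dot re-enters at the boundary point diametrically opposite its exit
    location, keeping its direction of motion.  Calling this on a position
    strictly inside the aperture is a contract violation.
    """
    x, y = position
    rho = math.hypot(x, y)
    if rho < radius:
        raise ContractError(
            f"wrap_position called for position inside the aperture (|p|={rho:.4f} < {radius})"
        )
    scale = radius / rho
    return (-x * scale, -y * scale)


def advance_frame(
    state: DotFieldState, spec: StimulusSpec, rng: np.random.Generator
) -> DotFieldState:
    """Advance the dot field by one frame.

    Every dot is displaced by ``speed / refresh_rate`` along its stored
    direction; dots leaving the aperture wrap to the antipodal boundary
    point.  In ``noise_mode="walk"`` noise dots are re-assigned a fresh
    random direction before the step.
    """
    new = state.copy()
    if spec.noise_mode == "walk":
        noise = ~new.is_signal
        new.direction[noise] = rng.uniform(0.0, 360.0, size=int(noise.sum()))
    step = spec.frame_displacement
    rad = np.deg2rad(new.direction)
    new.x += step * np.cos(rad)
    new.y += step * np.sin(rad)

    rho = np.hypot(new.x, new.y)
    out = rho >= spec.radius
    if np.any(out):
        scale = spec.radius / rho[out]
        new.x[out] *= -scale
        new.y[out] *= -scale
    new.frame_index = state.frame_index + 1
    return new


def empirical_coherence(state: DotFieldState, patch_id: int) -> float:
    """Fraction of signal dots in one patch (verification helper)."""
    mask = state.patch_id == patch_id
    total = int(mask.sum())
    if total == 0:
        raise ValidationError(f"patch {patch_id} contains no dots")
    return float(state.is_signal[mask].sum()) / total


def direction_histogram(
    states: Sequence[DotFieldState] | Iterable[DotFieldState], n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-dot directions over frames into a normalized histogram.

    Returns ``(density, bin_centers)`` where ``density`` sums to 1 and the
    bins tile [0°, 360°).
    """
    states = list(states)
    if len(states) == 0:
        raise ValidationError("at least one frame is required")
    if n_bins < 4:
        raise ValidationError("n_bins must be >= 4")
    dirs = np.concatenate([np.mod(s.direction, 360.0) for s in states])
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(dirs, bins=edges)
    density = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return density, centers


def render_frame(state: DotFieldState, spec: StimulusSpec) -> np.ndarray:
    """Rasterize one frame: each dot painted as a 2×2-pixel square.

    Dot positions are computed at sub-pixel accuracy and rounded to the
    nearest pixel; rendering is deterministic and off the analysis path
    (model observers consume geometry, not pixels).
    """
    if spec.pixel_pitch <= 0:
        raise ValidationError("pixel_pitch must be positive")
    n_px = int(math.ceil(spec.aperture_diameter / spec.pixel_pitch)) + 2
    grid = np.zeros((n_px, n_px), dtype=np.uint8)
    col = np.rint((state.x + spec.radius) / spec.pixel_pitch).astype(int)
    row = np.rint((state.y + spec.radius) / spec.pixel_pitch).astype(int)
    for dr in (0, 1):
        for dc in (0, 1):
            r = np.clip(row + dr, 0, n_px - 1)
            c = np.clip(col + dc, 0, n_px - 1)
            grid[r, c] = 1
    return grid


def simulate_trajectory(
    spec: StimulusSpec, seed, n_frames: int | None = None
) -> list[DotFieldState]:
    """Generate the full per-frame dot-field sequence for one presentation."""
    rng = np.random.default_rng(seed)
    state = init_dot_field(spec, rng)
    states = [state]
    total = spec.n_frames if n_frames is None else n_frames
    for _ in range(total):
        state = advance_frame(state, spec, rng)
        states.append(state)
    return states


def trajectory_table(states: Sequence[DotFieldState]) -> pd.DataFrame:
    """Tidy per-dot trajectory table (frame, patch_id, dot_id, x, y, ...)."""
    frames = []
    for s in states:
        frames.append(
            pd.DataFrame(
                {
                    "frame": s.frame_index,
                    "patch_id": s.patch_id,
                    "dot_id": np.arange(s.n_dots),
                    "x_deg": s.x,
                    "y_deg": s.y,
                    "is_signal": s.is_signal,
                    "direction_deg": s.direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
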