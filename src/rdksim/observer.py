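"""Synthetic observers for the transparent-motion matching task.

Two observer families are provided:

* A **parametric observer** mapping a condition (direction separation Δ,
  coherence c) to an internal perceived separation
  ``Δ · (1 + b(c) · R(Δ))``, plus trial noise, a lapse rate and a merge
  threshold below which the two directions collapse into a single percept.
  ``b(c)`` is a signed coherence gain that crosses zero at the crossover
  coherence (≈0.8): above it the observer over-estimates the separation
  (direction repulsion), below it the separation is under-estimated
  (direction attraction).  ``R(Δ)`` is a unimodal tuning profile peaking
  near 25° separation; the attraction branch decays more slowly and keeps a
  low-level effect at large separations.  This observer drives all
  quantitative simulations.

* A **population-channel observer**: a bank of direction-tuned channels with
  broad subtractive mutual inhibition.  Two sufficiently separated motion
  directions evoke two response peaks; inhibition repels the peaks at high
  coherence, while at low coherence the noise pedestal fills the inter-peak
  trough and the decoding smoothing draws the peaks together.  It is a
  mechanistic demonstrator of the repulsion-to-attraction switch, not the
  quantitative pipeline.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .stimulus import (
    StimulusSpec,
    ValidationError,
    direction_histogram,
    init_dot_field,
)

__all__ = [
    "Choice",
    "ParametricObserverParams",
    "ParametricObserver",
    "FixedPerceptObserver",
    "ChannelBankParams",
    "internal_separation",
    "trial_percept",
    "decide_2afc",
    "channel_responses",
    "decode_two_peaks",
    "population_percept",
    "draw_cohort",
]


class Choice(enum.Enum):
    """Response alternatives of the 2AFC angle-comparison task."""

    LINES_WIDER = "lines_wider"
    LINES_NARROWER = "lines_narrower"


@dataclass(frozen=True)
class ParametricObserverParams:
    """Parameters of the parametric observer.

    The defaults are calibrated so that, at a veridical separation of 30°,
    the observer perceives ≈42° at full coherence and ≈16° at 60% coherence,
    with the zero-crossing of the effect at 80% coherence and the normalized
    effect strongest at 25° separation.  The repulsion gain equals
    ``(1 - attraction_floor)`` times the attraction gain at 60% coherence,
    which makes the normalized repulsion and attraction profiles mirror each
    other up to a constant — the configuration in which the separation main
    effect of the pooled two-way analysis vanishes.
    """

    crossover_coherence: float = 0.8  # c0: zero-effect coherence
    repulsion_gain: float = 0.513  # g+: b(1.0)
    attraction_gain_slope: float = 2.9  # g-: d|b|/dc below c0
    tuning_peak: float = 25.0  # Δ* (deg)
    tuning_width: float = 5.0  # sd of the narrow peak component (deg)
    broad_width: float = 45.0  # sd of the broad component (deg)
    narrow_weight: float = 0.55  # mixture weight of the narrow component
    attraction_floor: float = 0.115  # residual attraction at large Δ
    trial_noise: float = 3.0  # σ: per-trial percept SD (deg)
    lapse_rate: float = 0.02  # λ: probability of a random response
    merge_threshold: float = 4.0  # percepts below this collapse to 0 (deg)
    line_angle_bias: float = 0.0  # additive bias on the perceived line angle

    def __post_init__(self) -> None:
        if not 0.0 < self.crossover_coherence < 1.0:
            raise ValidationError("crossover_coherence must lie in (0, 1)")
        if self.trial_noise < 0:
            raise ValidationError("trial_noise must be >= 0")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValidationError("lapse_rate must lie in [0, 0.5]")
        if self.tuning_peak <= 0:
            raise ValidationError("tuning_peak must be positive")
        if self.repulsion_gain < 0 or self.attraction_gain_slope < 0:
            raise ValidationError("gains must be >= 0")
        if not 0.0 <= self.attraction_floor < 1.0:
            raise ValidationError("attraction_floor must lie in [0, 1)")
        if not 0.0 <= self.narrow_weight <= 1.0:
            raise ValidationError("narrow_weight must lie in [0, 1]")


def _tuning_profile(delta: float, p: ParametricObserverParams) -> float:
    """Unimodal separation-tuning profile, normalized to 1 at the peak."""
    d = delta - p.tuning_peak
    narrow = math.exp(-0.5 * (d / p.tuning_width) ** 2)
    broad = math.exp(-0.5 * (d / p.broad_width) ** 2)
    return p.narrow_weight * narrow + (1.0 - p.narrow_weight) * broad


def _coherence_gain(c: float, p: ParametricObserverParams) -> float:
    """Signed gain b(c): 0 at the crossover, g+ at c=1, negative below."""
    c0 = p.crossover_coherence
    if c >= c0:
        return p.repulsion_gain * (c - c0) / (1.0 - c0)
    return -p.attraction_gain_slope * (c0 - c)


def internal_separation(
    delta: float, coherence: float, params: ParametricObserverParams
) -> float:
    """Mean perceived direction separation for a (Δ, coherence) condition.

    ``Δ · (1 + b(c) · R(Δ))`` floored at zero.  On the attraction branch
    (b < 0) the profile is ``(1 - floor) · R(Δ) + floor`` so a low-level
    attraction persists at separations of 90° and beyond, where repulsion
    has already decayed to near zero.
    """
    if delta < 0:
        raise ValidationError("direction separation must be >= 0")
    if not 0.0 <= coherence <= 1.0:
        raise ValidationError("coherence must lie in [0, 1]")
    if delta == 0:
        return 0.0
    b = _coherence_gain(coherence, params)
    profile = _tuning_profile(delta, params)
    if b < 0:
        floor = params.attraction_floor
        profile = (1.0 - floor) * profile + floor
    return max(0.0, delta * (1.0 + b * profile))


def trial_percept(
    delta: float,
    coherence: float,
    params: ParametricObserverParams,
    rng: np.random.Generator,
) -> float:
    """Single-trial perceived separation: mean + Gaussian noise, merge rule.

    Percepts below ``merge_threshold`` collapse to zero — the observer sees a
    single (noisy) motion direction rather than two.
    """
    x = internal_separation(delta, coherence, params)
    if params.trial_noise > 0:
        x += params.trial_noise * rng.standard_normal()
    x = max(0.0, x)
    if x < params.merge_threshold:
        return 0.0
    return x


def decide_2afc(
    percept: float,
    line_angle: float,
    params: ParametricObserverParams,
    rng: np.random.Generator,
) -> Choice:
    """Report which interval had the larger angle (lines vs motion percept).

    Exact ties are broken by a fair coin, except the fully degenerate
    comparison of a merged (zero-separation) percept against a zero-angle
    line pair: there the observer keeps reporting the lines as wider —
    collinear lines cannot look wider than a single motion direction — which
    is what lets a zero-percept staircase pin at the floor instead of
    reversing.
    """
    if percept < 0 or line_angle < 0:
        raise ValidationError("percept and line angle must be >= 0")
    if params.lapse_rate > 0 and rng.uniform() < params.lapse_rate:
        return Choice.LINES_WIDER if rng.uniform() < 0.5 else Choice.LINES_NARROWER
    line = line_angle + params.line_angle_bias
    if line > percept:
        return Choice.LINES_WIDER
    if line < percept:
        return Choice.LINES_NARROWER
    if percept == 0.0 and line == 0.0:
        return Choice.LINES_WIDER
    return Choice.LINES_WIDER if rng.uniform() < 0.5 else Choice.LINES_NARROWER


class ParametricObserver:
    """Bundles :class:`ParametricObserverParams` behind the observer protocol
    consumed by the staircase engine."""

    def __init__(self, params: ParametricObserverParams | None = None):
        self.params = params or ParametricObserverParams()

    def trial_percept(
        self, delta: float, coherence: float, rng: np.random.Generator
    ) -> float:
        return trial_percept(delta, coherence, self.params, rng)

    def decide(
        self, percept: float, line_angle: float, rng: np.random.Generator
    ) -> Choice:
        return decide_2afc(percept, line_angle, self.params, rng)


class FixedPerceptObserver:
    """Observer whose internal separation is a constant, for calibration
    studies of the staircase estimator (point-of-subjective-equality
    recovery)."""

    def __init__(self, percept: float, trial_noise: float = 0.0, lapse_rate: float = 0.0):
        self.percept = percept
        self.params = ParametricObserverParams(
            trial_noise=trial_noise, lapse_rate=lapse_rate, merge_threshold=0.0
        )

    def trial_percept(
        self, delta: float, coherence: float, rng: np.random.Generator
    ) -> float:
        x = self.percept
        if self.params.trial_noise > 0:
            x += self.params.trial_noise * rng.standard_normal()
        return max(0.0, x)

    def decide(
        self, percept: float, line_angle: float, rng: np.random.Generator
    ) -> Choice:
        return decide_2afc(percept, line_angle, self.params, rng)


def draw_cohort(
    n_subjects: int,
    seed,
    base: ParametricObserverParams | None = None,
    gain_sd: float = 0.15,
    crossover_sd: float = 0.02,
    noise_sd: float = 0.5,
) -> list[ParametricObserverParams]:
    """Draw a cohort of observers around the default parameters.

    One lognormal gain factor per subject scales both the repulsion and the
    attraction gain (subjects differ in overall susceptibility, not in the
    sign pattern); the crossover coherence and trial noise jitter mildly.
    """
    rng = np.random.default_rng(seed)
    base = base or ParametricObserverParams()
    cohort = []
    for _ in range(n_subjects):
        gain = math.exp(gain_sd * rng.standard_normal())
        c0 = min(0.95, max(0.55, base.crossover_coherence + crossover_sd * rng.standard_normal()))
        sigma = max(0.5, base.trial_noise + noise_sd * rng.standard_normal())
        cohort.append(
            replace(
                base,
                repulsion_gain=base.repulsion_gain * gain,
                attraction_gain_slope=base.attraction_gain_slope * gain,
                crossover_coherence=c0,
                trial_noise=sigma,
            )
        )
    return cohort


# --------------------------------------------------------------------------
# Population-channel observer
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelBankParams:
    """Direction-tuned channel bank with broad subtractive inhibition.

    ``integration_gain`` implements noise-prompted motion integration: with
    the uniform-noise fraction ``u`` estimated from the direction density,
    the factor ``φ(u) = 1 / (1 + integration_gain · u)`` simultaneously
    broadens the excitatory pooling (``κ_eff = κ · φ``) and weakens the
    mutual inhibition (``s_eff = s · φ``).  A clean stimulus is processed by
    sharply tuned, strongly inhibiting channels (segmentation, repulsion); a
    noisy one by broadly pooling, weakly inhibiting channels (integration,
    attraction).
    """

    n_channels: int = 72
    tuning_kappa: float = 40.0  # von Mises concentration of the tuning curve
    inhibition_strength: float = 1.2
    inhibition_kappa: float = 6.0  # broader than the tuning curve
    integration_gain: float = 15.0  # noise-dependent integration shift
    decoding_smoothing: float = 8.0  # circular Gaussian SD (deg)
    peak_min_prominence: float = 0.3  # fraction of the max activity

    def __post_init__(self) -> None:
        if self.n_channels < 8:
            raise ValidationError("n_channels must be >= 8")
        if self.inhibition_kappa >= self.tuning_kappa:
            raise ValidationError(
                "inhibition must be broader than the tuning curve "
                "(inhibition_kappa < tuning_kappa)"
            )
        if self.inhibition_strength < 0:
            raise ValidationError("inhibition_strength must be >= 0")
        if self.integration_gain < 0:
            raise ValidationError("integration_gain must be >= 0")


def estimate_noise_fraction(density: np.ndarray) -> float:
    """Uniform-noise mass fraction of a direction density.

    The median bin mass is a robust estimate of the uniform pedestal
    (signal directions occupy few bins), scaled back to a total fraction.
    """
    density = np.asarray(density, dtype=float)
    return float(min(1.0, density.size * np.median(density)))


def _preferred_directions(params: ChannelBankParams) -> np.ndarray:
    return np.arange(params.n_channels) * (360.0 / params.n_channels)


def channel_responses(
    density: np.ndarray, bin_centers: np.ndarray, params: ChannelBankParams
) -> np.ndarray:
    """Channel activity for a binned direction density.

    Excitation is the tuning-weighted sum of the density; each channel is
    then suppressed by a broad inhibitory pool (the convolution of the
    excitation with a wider von Mises kernel) and rectified:

    ``A = max(0, E - s_eff · (K_inh * E))``

    Motion noise shifts the segmentation/integration balance: with the
    uniform-noise fraction ``u`` of the density and
    ``φ = 1 / (1 + integration_gain · u)``, the tuning concentration is
    ``κ_eff = κ · φ`` (broader pooling) and the inhibition strength is
    ``s_eff = s · φ`` (weaker mutual inhibition).
    """
    density = np.asarray(density, dtype=float)
    if density.ndim != 1 or density.size != np.asarray(bin_centers).size:
        raise ValidationError("density and bin_centers must be 1-D and aligned")
    if not math.isclose(float(density.sum()), 1.0, abs_tol=1e-6):
        raise ValidationError("density must be normalized to sum 1")
    noise_fraction = estimate_noise_fraction(density)
    phi = 1.0 / (1.0 + params.integration_gain * noise_fraction)
    prefs = _preferred_directions(params)
    dmat = np.deg2rad(prefs[:, None] - np.asarray(bin_centers)[None, :])
    tuning = np.exp(params.tuning_kappa * phi * (np.cos(dmat) - 1.0))
    excitation = tuning @ density

    cmat = np.deg2rad(prefs[:, None] - prefs[None, :])
    kernel = np.exp(params.inhibition_kappa * (np.cos(cmat) - 1.0))
    kernel /= kernel.sum(axis=1, keepdims=True)
    inhibition = params.inhibition_strength * phi * (kernel @ excitation)
    return np.maximum(0.0, excitation - inhibition)


def _circular_smooth(activity: np.ndarray, sd_deg: float, spacing: float) -> np.ndarray:
    if sd_deg <= 0:
        return activity.astype(float)
    n = activity.size
    offsets = np.arange(n)
    offsets = np.minimum(offsets, n - offsets) * spacing
    kernel = np.exp(-0.5 * (offsets / sd_deg) ** 2)
    kernel /= kernel.sum()
    return np.real(np.fft.ifft(np.fft.fft(activity) * np.fft.fft(kernel)))


def decode_two_peaks(
    activity: np.ndarray, params: ChannelBankParams
) -> tuple[float, float] | None:
    """Read out the two stimulus directions from the channel activity.

    The activity is circularly smoothed, local maxima above
    ``peak_min_prominence × max`` are located, and the two largest are
    refined by parabolic (sub-channel) interpolation.  Returns ``None`` when
    the profile is unimodal (single-direction percept).
    """
    activity = np.asarray(activity, dtype=float)
    if np.all(activity <= 0):
        raise ValidationError("activity is all zero; nothing to decode")
    spacing = 360.0 / activity.size
    smooth = _circular_smooth(activity, params.decoding_smoothing, spacing)
    n = smooth.size
    prev = np.roll(smooth, 1)
    nxt = np.roll(smooth, -1)
    is_peak = (smooth > prev) & (smooth >= nxt)
    threshold = params.peak_min_prominence * smooth.max()
    peaks = np.flatnonzero(is_peak & (smooth >= threshold))
    if peaks.size < 2:
        return None
    order = np.argsort(smooth[peaks])[::-1]
    chosen = peaks[order[:2]]
    prefs = _preferred_directions(params)
    refined = []
    for k in chosen:
        y0, y1, y2 = smooth[(k - 1) % n], smooth[k], smooth[(k + 1) % n]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        refined.append((prefs[k] + shift * spacing) % 360.0)
    return (refined[0], refined[1])


def _circular_separation(d1: float, d2: float) -> float:
    diff = abs(d1 - d2) % 360.0
    return min(diff, 360.0 - diff)


def population_percept(
    spec: StimulusSpec,
    params: ChannelBankParams,
    rng: np.random.Generator,
    n_frames: int = 0,
) -> float:
    """Perceived separation of the channel-bank observer for one stimulus.

    Simulates the dot field, pools the per-dot direction histogram, runs the
    channel bank and decodes the peak pair; a unimodal profile reads out as
    zero separation.  ``n_frames > 0`` additionally pools over evolved
    frames (only informative in random-walk noise mode).
    """
    state = init_dot_field(spec, rng)
    states = [state]
    if n_frames > 0:
        from .stimulus import advance_frame

        for _ in range(n_frames):
            state = advance_frame(state, spec, rng)
            states.append(state)
    density, centers = direction_histogram(states, params.n_channels)
    activity = channel_responses(density, centers, params)
    peaks = decode_two_peaks(activity, params)
    if peaks is None:
        return 0.0
    return _circular_separation(*peaks)
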