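"""Synthetic scanpath cohorts for two viewer classes.

The simulator produces labeled fixation sequences with the qualitative
structure reported for museum visitors viewing paintings on a 1920x1080
display: adults concentrate their gaze near the image center, while
children sweep back and forth between the left and right halves with much
larger horizontal dispersion.  Fixation durations are log-normal with a
300 ms mean, and each (subject, stimulus) trial accumulates fixations until
the 15 s viewing budget is reached.

Two hard-coded default profiles operationalize that contrast; every
parameter is overridable, and the gap between the two spatial dispersions
is the knob that controls downstream class separability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fixation_io import FixationRecord, Scanpath


@dataclass(frozen=True)
class BehaviorProfile:
    """Generative model of one viewer class.

    Parameters
    ----------
    label:
        Class label attached to every generated fixation.
    spatial_model:
        ``"center_gaussian"`` — isotropic Gaussian at screen center —
        or ``"sweeping"`` — the horizontal mean drifts left<->right as a
        triangular wave while the gaze scatters around it.
    center_std_frac:
        Isotropic positional std as a fraction of screen width
        (center_gaussian model).
    sweep_amplitude_frac:
        Half-range of the drifting horizontal mean as a fraction of screen
        width (sweeping model).
    sweep_period:
        Number of fixations per full left->right->left sweep cycle.
    sweep_std_frac:
        Positional scatter around the drifting mean, as a fraction of
        screen width (horizontal) and height (vertical).
    mean_duration_ms / duration_cv:
        Log-normal fixation-duration model: target mean and coefficient of
        variation.
    saccade_jitter_frac:
        Extra isotropic per-step positional noise, fraction of width.
    """

    label: str
    spatial_model: str = "center_gaussian"
    center_std_frac: float = 0.08
    sweep_amplitude_frac: float = 0.30
    sweep_period: int = 16
    sweep_std_frac: float = 0.12
    mean_duration_ms: float = 300.0
    duration_cv: float = 0.30
    saccade_jitter_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.mean_duration_ms <= 0 or self.duration_cv <= 0:
            raise ValueError("duration model parameters must be positive")
        if min(self.center_std_frac, self.sweep_std_frac,
               self.saccade_jitter_frac) <= 0:
            raise ValueError("dispersion parameters must be positive")
        if self.spatial_model not in ("center_gaussian", "sweeping"):
            raise ValueError(f"unknown spatial model {self.spatial_model!r}")


ADULT_PROFILE = BehaviorProfile(label="adult", spatial_model="center_gaussian")
CHILD_PROFILE = BehaviorProfile(label="child", spatial_model="sweeping")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition-level settings shared by all simulated trials."""

    screen_dims: tuple[int, int] = (1920, 1080)
    budget_ms: float = 15000.0
    n_stimuli: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget_ms <= 0:
            raise ValueError("budget_ms must be positive")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and coefficient of variation."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_durations(n: int, profile: BehaviorProfile, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` fixation durations (ms) from the profile's log-normal model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu, sigma = _lognormal_params(profile.mean_duration_ms, profile.duration_cv)
    return rng.lognormal(mu, sigma, size=n)


def _sample_position(
    i: int,
    profile: BehaviorProfile,
    screen_dims: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One in-bounds fixation position; out-of-bounds proposals are resampled."""
    w, h = screen_dims
    cx, cy = w / 2.0, h / 2.0
    jitter = profile.saccade_jitter_frac * w
    for _ in range(1000):
        if profile.spatial_model == "center_gaussian":
            std = profile.center_std_frac * w
            x = rng.normal(cx, std)
            y = rng.normal(cy, std)
        else:  # sweeping
            # triangular wave in [-1, 1] over sweep_period fixations
            phase = (i % profile.sweep_period) / profile.sweep_period
            tri = 4 * abs(phase - 0.5) - 1
            mean_x = cx + tri * profile.sweep_amplitude_frac * w
            x = rng.normal(mean_x, profile.sweep_std_frac * w)
            y = rng.normal(cy, profile.sweep_std_frac * h)
        x += rng.normal(0, jitter)
        y += rng.normal(0, jitter)
        if 0 <= x < w and 0 <= y < h:
            return x, y
    raise RuntimeError("could not draw an in-bounds fixation in 1000 proposals")


def sample_scanpath(
    profile: BehaviorProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    subject: str = "sim",
    stimulus: str = "stim",
) -> Scanpath:
    """Simulate one viewing trial.

    Fixations accumulate until adding the next one would exceed the viewing
    budget; the overshooting fixation is discarded, so the total duration is
    always <= ``budget_ms`` and, in expectation, within about half a mean
    fixation of it.
    """
    if config.budget_ms < profile.mean_duration_ms / 10:
        raise ValueError("viewing budget smaller than a plausible fixation")
    records: list[FixationRecord] = []
    total = 0.0
    i = 0
    while True:
        duration = float(sample_durations(1, profile, rng)[0])
        if total + duration > config.budget_ms:
            break
        x, y = _sample_position(i, profile, config.screen_dims, rng)
        records.append(
            FixationRecord(
                x=x, y=y, duration_ms=duration,
                subject=subject, stimulus=stimulus, label=profile.label,
            )
        )
        total += duration
        i += 1
    if not records:
        raise ValueError("budget too small: no fixation fit within it")
    return Scanpath(records=records, screen_dims=config.screen_dims)


def generate_cohort(
    n_adults: int,
    n_children: int,
    config: SimulationConfig | None = None,
    *,
    adult_profile: BehaviorProfile = ADULT_PROFILE,
    child_profile: BehaviorProfile = CHILD_PROFILE,
) -> list[Scanpath]:
    """Simulate a labeled two-class cohort.

    One scanpath per (subject, stimulus); per-subject sub-seeds are spawned
    from the master seed so the cohort is reproducible as a whole and per
    subject.
    """
    if n_adults < 1 or n_children < 1:
        raise ValueError("both classes need at least one subject")
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(n_adults + n_children)
    scanpaths: list[Scanpath] = []
    roster = [("adult", adult_profile, i) for i in range(n_adults)] + [
        ("child", child_profile, i) for i in range(n_children)
    ]
    for (cls, profile, idx), sub_ss in zip(roster, subject_seeds):
        rng = np.random.default_rng(sub_ss)
        subject = f"{cls}_{idx:03d}"
        for s in range(config.n_stimuli):
            scanpaths.append(
                sample_scanpath(
                    profile, config, rng,
                    subject=subject, stimulus=f"stim_{s + 1}",
                )
            )
    return scanpaths
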