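"""Synthetic laser-EEG cohort generator.

Emulates the statistical structure of a laser-evoked-potential (LEP)
experiment: a cohort of individuals, each receiving trains of laser pulses
over a ladder of stimulus energies, rating each pulse on the 0-10 numerical
rating scale (NRS), while EEG is recorded around each stimulus.

The generative model has three ingredients:

* a per-individual multiplicative *scale factor* (log-normal, median 1)
  standing in for anatomical/recording factors (skull thickness, electrode
  impedance) that attenuate or amplify *both* spontaneous and evoked EEG —
  this is what induces the cross-individual correlation between spontaneous
  and evoked magnitudes and what z-score normalization is meant to cancel;
* band-limited (1-30 Hz) Gaussian background noise in both the pre-stimulus
  (spontaneous) and post-stimulus segments;
* a biphasic evoked waveform (N2-like negative lobe near 200 ms, P2-like
  positive lobe near 350 ms) whose amplitude is flat for ratings at or below
  the pinprick threshold (NRS 4) and increases linearly above it.

The evoked template is normalized to unit RMS over the post-stimulus window,
so ``evoked_base`` and ``evoked_slope`` are expressed directly in µV of
post-segment RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from numpy.random import Generator, default_rng

from .errors import ConfigurationError, DomainError
from .features import design_bandpass, sos_filtfilt

__all__ = [
    "CohortConfig",
    "IndividualProfile",
    "EpochedTrial",
    "sample_individual_profiles",
    "simulate_trial",
    "simulate_cohort",
    "evoked_template",
]

#: Expected rating at an individual's maximum calibrated energy.
TOP_RATING = 8.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and generative parameters for a simulated cohort.

    Defaults mirror the experimental design being emulated: 34 individuals,
    energies from 1 J upward in 0.25 J steps to a per-individual maximum in
    [3.75, 4.5] J (12-15 levels), 10 pulses per level (120-150 trials),
    1000 Hz sampling, ±0.5 s epochs, 1-30 Hz band, NRS break point 4.
    """

    n_individuals: int = 34
    energy_min: float = 1.0
    energy_step: float = 0.25
    pulses_per_level: int = 10
    sampling_rate: float = 1000.0
    epoch_halfwidth: float = 0.5
    break_point: float = 4.0
    max_energy_range: tuple[float, float] = (3.75, 4.5)
    band: tuple[float, float] = (1.0, 30.0)
    # generative parameters
    noise_sd: float = 10.0          # µV, spontaneous background SD (common to all)
    scale_sigma: float = 0.4        # log-SD of the individual scale factor
    evoked_base: float = 15.0       # µV RMS, evoked magnitude at/below break point
    evoked_slope: float = 10.0      # µV RMS per NRS unit above the break point
    profile_cv: float = 0.15        # log-SD of per-individual base/slope spread
    rating_noise_sd: float = 1.0    # NRS units, trial-to-trial rating noise
    trial_jitter_sd: float = 2.0    # µV RMS, trial-to-trial evoked-amplitude jitter
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be >= 2")
        if self.pulses_per_level < 1:
            raise ConfigurationError("pulses_per_level must be >= 1")
        if self.energy_step <= 0:
            raise ConfigurationError("energy_step must be > 0")
        if self.energy_min <= 0:
            raise ConfigurationError("energy_min must be > 0")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.epoch_halfwidth <= 0:
            raise ConfigurationError("epoch_halfwidth must be > 0")
        n = self.sampling_rate * self.epoch_halfwidth
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "sampling_rate * epoch_halfwidth must be a whole number of samples"
            )
        lo, hi = self.max_energy_range
        if not (self.energy_min < lo <= hi):
            raise ConfigurationError("max_energy_range must satisfy energy_min < lo <= hi")
        if not (0 < self.band[0] < self.band[1] < self.sampling_rate / 2):
            raise ConfigurationError("band must satisfy 0 < low < high < Nyquist")
        for name in ("noise_sd", "evoked_base", "evoked_slope"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("scale_sigma", "profile_cv", "rating_noise_sd", "trial_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        """Samples per epoch segment (pre or post)."""
        return int(round(self.sampling_rate * self.epoch_halfwidth))

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualProfile:
    """Latent per-individual parameters of the generative model."""

    individual_id: str
    scale: float           # multiplies both spontaneous SD and evoked amplitude
    noise_sd: float        # µV, baseline spontaneous SD before scaling
    sensitivity: float     # NRS units per J
    max_energy: float      # J; top energy elicits expected rating ~8
    evoked_base: float     # µV RMS at and below the break point
    evoked_slope: float    # µV RMS per NRS unit above the break point
    trial_noise_sd: float  # µV RMS, trial-to-trial amplitude jitter

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError("scale must be > 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.evoked_slope < 0:
            raise ConfigurationError("evoked_slope must be >= 0")


@dataclass(frozen=True)
class EpochedTrial:
    """One stimulus event: spontaneous (pre) and evoked (post) segments."""

    individual_id: str
    trial_index: int
    pre_samples: np.ndarray   # µV on [-0.5 s, 0 s)
    post_samples: np.ndarray  # µV on [0 s, +0.5 s)
    rating: int               # NRS, 0..10
    energy: float             # J

    def __post_init__(self) -> None:
        if len(self.pre_samples) != len(self.post_samples):
            raise ConfigurationError("pre and post segments must have equal length")
        if not (0 <= self.rating <= 10):
            raise ConfigurationError("rating must be in [0, 10]")


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(x + 0.5)


@lru_cache(maxsize=32)
def _noise_gain(sampling_rate: float, low: float, high: float) -> float:
    """RMS gain of the zero-phase band-pass applied to unit white noise.

    filtfilt applies |H(f)|^2 in magnitude, so the output variance of unit
    white noise is the frequency average of |H|^4.
    """
    from scipy.signal import sosfreqz

    sos = design_bandpass(sampling_rate, low, high)
    _, h = sosfreqz(sos, worN=8192)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def bandlimited_noise(
    n_samples: int, sd: float, sampling_rate: float, band: tuple[float, float], rng: Generator
) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` with ensemble SD ``sd``.

    White noise is passed through the same zero-phase filter used in
    preprocessing so that simulated and preprocessed spectra match; the white
    input is pre-scaled so the *filtered* process has the requested SD.
    Generated with one-second pads on each side to avoid edge transients.
    """
    if sd == 0:
        return np.zeros(n_samples)
    pad = int(round(sampling_rate))
    gain = _noise_gain(sampling_rate, band[0], band[1])
    white = rng.standard_normal(n_samples + 2 * pad) * (sd / gain)
    filtered = sos_filtfilt(white, sampling_rate, band[0], band[1])
    return filtered[pad : pad + n_samples]


@lru_cache(maxsize=32)
def evoked_template(n_samples: int, sampling_rate: float) -> np.ndarray:
    """Unit-RMS biphasic evoked waveform on [0, n_samples/sampling_rate).

    Negative lobe peaking at 200 ms (sigma 30 ms), positive lobe at 350 ms
    (sigma 50 ms) — an N2/P2-like laser-evoked shape. Amplitude, not shape,
    carries the signal; the template is fixed across trials.
    """
    t = np.arange(n_samples) / sampling_rate
    w = -np.exp(-0.5 * ((t - 0.200) / 0.030) ** 2) + 0.9 * np.exp(
        -0.5 * ((t - 0.350) / 0.050) ** 2
    )
    rms = np.sqrt(np.mean(w**2))
    return w / rms


def sample_individual_profiles(
    config: CohortConfig, rng: Generator | None = None
) -> list[IndividualProfile]:
    """Draw ``n_individuals`` latent profiles.

    Scale factors are log-normal with median 1 and log-SD ``scale_sigma``
    (shared by spontaneous and evoked channels); the maximum calibrated
    energy is uniform on ``max_energy_range``; sensitivity is calibrated so
    the top energy elicits an expected rating of 8.
    """
    config.validate()
    if rng is None:
        rng = default_rng(config.seed)
    width = len(str(config.n_individuals))
    profiles = []
    for j in range(config.n_individuals):
        scale = float(np.exp(rng.normal(0.0, config.scale_sigma))) if config.scale_sigma > 0 else 1.0
        max_energy = float(rng.uniform(*config.max_energy_range))
        base = config.evoked_base * float(np.exp(rng.normal(0.0, config.profile_cv)))
        slope = config.evoked_slope * float(np.exp(rng.normal(0.0, config.profile_cv)))
        profiles.append(
            IndividualProfile(
                individual_id=f"S{j + 1:0{width}d}",
                scale=scale,
                noise_sd=config.noise_sd if config.noise_sd > 0 else 1e-12,
                sensitivity=TOP_RATING / max_energy,
                max_energy=max_energy,
                evoked_base=base,
                evoked_slope=slope,
                trial_noise_sd=config.trial_jitter_sd * scale,
            )
        )
    return profiles


def evoked_amplitude(
    profile: IndividualProfile, rating: float, break_point: float = 4.0, jitter: float = 0.0
) -> float:
    """Evoked post-segment RMS amplitude for a given rating (flat-then-linear)."""
    amp = profile.scale * (
        profile.evoked_base + profile.evoked_slope * max(0.0, rating - break_point)
    )
    return max(0.0, amp + jitter)


def simulate_trial(
    profile: IndividualProfile,
    energy: float,
    config: CohortConfig,
    rng: Generator,
    trial_index: int = 0,
    rating: int | None = None,
) -> EpochedTrial:
    """Simulate one laser pulse for one individual.

    The rating is the latent response ``sensitivity * energy`` plus Gaussian
    noise, rounded half-up and clipped to [0, 10]; pass ``rating`` to force
    it (the rating-noise draw is then skipped). The pre segment is
    band-limited noise with SD ``scale * noise_sd``; the post segment is
    independent such noise plus the evoked template scaled by the
    flat-then-linear amplitude rule.
    """
    tol = 1e-9
    if not (config.energy_min - tol <= energy <= profile.max_energy + tol):
        raise DomainError(
            f"energy {energy} J outside [{config.energy_min}, {profile.max_energy}] J"
        )
    if rating is None:
        latent = profile.sensitivity * energy + rng.normal(0.0, config.rating_noise_sd)
        rating = int(np.clip(_round_half_up(latent), 0, 10))
    k = config.n_samples
    sd = profile.scale * profile.noise_sd
    pre = bandlimited_noise(k, sd, config.sampling_rate, config.band, rng)
    post = bandlimited_noise(k, sd, config.sampling_rate, config.band, rng)
    jitter = rng.normal(0.0, profile.trial_noise_sd) if profile.trial_noise_sd > 0 else 0.0
    amp = evoked_amplitude(profile, rating, config.break_point, jitter)
    post = post + amp * evoked_template(k, config.sampling_rate)
    return EpochedTrial(
        individual_id=profile.individual_id,
        trial_index=trial_index,
        pre_samples=pre,
        post_samples=post,
        rating=rating,
        energy=energy,
    )


def energy_levels(config: CohortConfig, max_energy: float) -> np.ndarray:
    """Energy ladder from energy_min to max_energy in energy_step increments."""
    n_levels = int(np.floor((max_energy - config.energy_min) / config.energy_step + 1e-9)) + 1
    return config.energy_min + config.energy_step * np.arange(n_levels)


def simulate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[EpochedTrial], list[IndividualProfile]]:
    """Simulate the full cohort; returns trials plus the ground-truth profiles.

    Per individual: ``pulses_per_level`` pulses at each energy of the ladder,
    delivered in randomized order (trial_index is delivery order).
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = default_rng(config.seed)
    profiles = sample_individual_profiles(config, rng)
    trials: list[EpochedTrial] = []
    for profile in profiles:
        levels = energy_levels(config, profile.max_energy)
        energies = np.repeat(levels, config.pulses_per_level)
        order = rng.permutation(len(energies))
        for idx, pos in enumerate(order):
            trials.append(
                simulate_trial(profile, float(energies[pos]), config, rng, trial_index=idx)
            )
    return trials, profiles
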