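"""Coupled-oscillator surrogate for multichannel EEG.

Real scalp recordings for the two-memory-load task are not publicly
deposited, so every downstream stage is exercised on synthetic narrowband
signals with *controllable* pairwise phase coupling:

* each **coupling group** of channels shares a common band-limited driver
  oscillator (narrowband-filtered Gaussian noise);
* every channel on top of its driver receives independent Gaussian phase
  jitter of marginal standard deviation ``phase_jitter_sigma`` (radians);
* channels outside any group get independent drivers, i.e. asymptotically
  zero phase locking.

Because the jitter of two coupled channels is independent with variance
sigma^2 each, their phase difference has variance 2*sigma^2 and the
population phase-locking value is exactly ``exp(-sigma**2)`` — a closed
form the test-suite calibrates against.  The jitter is band-limited (not
sample-white) so that the instantaneous phase of the *real* signal, as
recovered by the Hilbert transform downstream, carries the jitter
faithfully; its marginal variance is still exactly sigma^2, which is all
the closed form requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert

from .containers import MultichannelEpoch
from .montage import CHANNELS_62

__all__ = [
    "OscillatorSpec",
    "ConditionSpec",
    "generate_epoch",
    "generate_condition_epochs",
    "generate_dataset",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class OscillatorSpec:
    """Parameters of one narrowband oscillator population.

    Parameters
    ----------
    band_center, band_width:
        Center frequency and full bandwidth in Hz of the driver
        oscillators.  The band ``center +/- width/2`` must lie strictly
        inside ``(0, rate/2)``.
    coupling_groups:
        Disjoint sets of channel labels; channels within a group share one
        driver phase.  Channels in no group are mutually independent.
    phase_jitter_sigma:
        Marginal std (radians) of the per-channel Gaussian phase jitter.
        ``0`` gives perfect within-group phase locking; the expected PLV
        between two coupled channels is ``exp(-sigma**2)``.
    amplitude_noise_sigma:
        Std of additive broadband Gaussian noise, as a fraction of the
        oscillation RMS.
    sample_rate, epoch_seconds:
        Sampling rate (Hz) and epoch length (s); defaults 500 Hz / 10 s
        match a standard working-memory recording protocol.
    channels:
        Channel labels (canonical montage order); default is the
        62-channel extended 10-20 analysis set.
    """

    band_center: float
    band_width: float
    coupling_groups: tuple[tuple[str, ...], ...] = ()
    phase_jitter_sigma: float = 0.4
    amplitude_noise_sigma: float = 0.05
    sample_rate: float = 500.0
    epoch_seconds: float = 10.0
    channels: tuple[str, ...] = CHANNELS_62

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coupling_groups",
            tuple(tuple(g) for g in self.coupling_groups))
        object.__setattr__(self, "channels", tuple(self.channels))
        self.validate()

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.sample_rate))

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_center - self.band_width / 2,
                self.band_center + self.band_width / 2)

    def validate(self) -> None:
        if self.phase_jitter_sigma < 0:
            raise ConfigurationError("phase_jitter_sigma must be >= 0")
        if self.amplitude_noise_sigma < 0:
            raise ConfigurationError("amplitude_noise_sigma must be >= 0")
        if self.band_width <= 0:
            raise ConfigurationError("band_width must be > 0")
        lo, hi = self.band
        nyq = self.sample_rate / 2
        if not (0 < lo and hi < nyq):
            raise ConfigurationError(
                f"band {lo:.3g}-{hi:.3g} Hz outside (0, {nyq:.3g}) Hz")
        seen: set[str] = set()
        for group in self.coupling_groups:
            for lab in group:
                if lab not in self.channels:
                    raise ConfigurationError(
                        f"coupling-group channel {lab!r} not in montage")
                if lab in seen:
                    raise ConfigurationError(
                        f"channel {lab!r} in more than one coupling group")
                seen.add(lab)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: a labeled set of per-band oscillators.

    Two conditions of a dataset are meant to differ only in their coupling
    topology and/or jitter levels, mimicking two memory-load states.
    """

    label: str
    oscillator_specs: dict[str, OscillatorSpec] = field(default_factory=dict)
    n_epochs: int = 20
    seed: int = 0

    @property
    def channels(self) -> tuple[str, ...]:
        return next(iter(self.oscillator_specs.values())).channels

    @property
    def sample_rate(self) -> float:
        return next(iter(self.oscillator_specs.values())).sample_rate

    @property
    def epoch_seconds(self) -> float:
        return next(iter(self.oscillator_specs.values())).epoch_seconds


# ---------------------------------------------------------------------------
# signal construction


def _odd_taps(n: int, cap: int) -> int:
    n = min(n, cap)
    return max(n | 1, 3)


def _narrowband_drivers(rng: np.random.Generator, n_drivers: int, n: int,
                        rate: float, lo: float, hi: float,
                        pad: int) -> np.ndarray:
    """Analytic (complex) narrowband drivers from filtered white noise,
    shape ``(n, n_drivers)``."""
    x = rng.standard_normal((n + 2 * pad, n_drivers))
    # ~3 cycles of the low cutoff; cap so filtfilt padding stays valid
    ntaps = _odd_taps(int(3 * rate / lo), (n + 2 * pad) // 4)
    taps = firwin(ntaps, [lo, hi], pass_zero=False, fs=rate)
    y = filtfilt(taps, 1.0, x, axis=0)
    return hilbert(y, axis=0)[pad:pad + n]


def _band_limited_jitter(rng: np.random.Generator, n_series: int, n: int,
                         rate: float, cutoff: float, sigma: float,
                         pad: int) -> np.ndarray:
    """Gaussian phase jitter, low-passed, exact marginal std sigma per
    column; shape ``(n, n_series)``."""
    x = rng.standard_normal((n + 2 * pad, n_series))
    ntaps = _odd_taps(int(2 * rate / cutoff), (n + 2 * pad) // 4)
    y = filtfilt(firwin(ntaps, cutoff, fs=rate), 1.0, x,
                 axis=0)[pad:pad + n]
    s = y.std(axis=0, keepdims=True)
    s[s == 0] = 1.0
    return sigma * y / s


def generate_epoch(spec: OscillatorSpec, seed: int) -> MultichannelEpoch:
    """Generate one multichannel epoch; bit-identical for identical seed.

    Coupled channels share a driver phase; every channel adds independent
    band-limited Gaussian phase jitter of marginal std
    ``spec.phase_jitter_sigma`` plus broadband amplitude noise.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n, rate = spec.n_samples, spec.sample_rate
    lo, hi = spec.band
    pad = int(2 * rate)
    jitter_cut = min(spec.band_width / 2, spec.band_center / 2)

    group_of = {lab: gi for gi, g in enumerate(spec.coupling_groups)
                for lab in g}
    # drivers in deterministic order: one per group, then one per free
    # channel in montage order
    free_labels = [lab for lab in spec.channels if lab not in group_of]
    n_drivers = len(spec.coupling_groups) + len(free_labels)
    drivers = _narrowband_drivers(rng, n_drivers, n, rate, lo, hi, pad)
    driver_col = {**{lab: gi for lab, gi in group_of.items()},
                  **{lab: len(spec.coupling_groups) + k
                     for k, lab in enumerate(free_labels)}}

    cols = [driver_col[lab] for lab in spec.channels]
    z = drivers[:, cols]
    phase = np.angle(z)
    if spec.phase_jitter_sigma > 0:
        phase = phase + _band_limited_jitter(
            rng, spec.n_channels, n, rate, jitter_cut,
            spec.phase_jitter_sigma, pad)
    data = np.abs(z) * np.cos(phase)
    rms = data.std(axis=0, keepdims=True)
    rms[rms == 0] = 1.0
    data = data / rms
    if spec.amplitude_noise_sigma > 0:
        data = data + spec.amplitude_noise_sigma * rng.standard_normal(
            (n, spec.n_channels))
    data = 10.0 * data  # arbitrary ~10 uV scale

    return MultichannelEpoch(data=data, rate=rate, channels=spec.channels,
                             meta={"seed": seed})


def _epoch_seed(base_seed: int, epoch_index: int, band_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), epoch_index, band_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_condition_epochs(cond: ConditionSpec) -> list[MultichannelEpoch]:
    """Generate all epochs of one condition.

    A multi-band condition sums its per-band components sample-wise, so a
    single epoch carries oscillations in every configured band.
    """
    if not cond.oscillator_specs:
        raise ConfigurationError("condition has no oscillator specs")
    specs = list(cond.oscillator_specs.values())
    for s in specs[1:]:
        if (s.channels != specs[0].channels
                or s.sample_rate != specs[0].sample_rate
                or s.epoch_seconds != specs[0].epoch_seconds):
            raise ConfigurationError(
                "per-band specs must share montage, rate and epoch length")
    epochs = []
    for e in range(cond.n_epochs):
        data = np.zeros((specs[0].n_samples, specs[0].n_channels))
        for bi, spec in enumerate(specs):
            data += generate_epoch(spec, _epoch_seed(cond.seed, e, bi)).data
        epochs.append(MultichannelEpoch(
            data=data, rate=cond.sample_rate, channels=cond.channels,
            label=cond.label, epoch_id=e,
            meta={"condition_seed": cond.seed}))
    return epochs


def generate_dataset(easy: ConditionSpec,
                     hard: ConditionSpec) -> list[MultichannelEpoch]:
    """Generate the labeled two-condition epoch collection."""
    if easy.channels != hard.channels:
        raise ConfigurationError("conditions use different montages")
    if (easy.sample_rate != hard.sample_rate
            or easy.epoch_seconds != hard.epoch_seconds):
        raise ConfigurationError(
            "conditions differ in rate or epoch length")
    return generate_condition_epochs(easy) + generate_condition_epochs(hard)
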