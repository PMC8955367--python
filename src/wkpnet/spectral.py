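"""Band definitions, filtering, epoching and Welch band power.

Standard rhythm bands: theta 3-7, alpha 7-13, beta 13-30, gamma 30-60 Hz.
All filtering is zero-phase (forward-backward FIR) because phase-locking
analysis downstream is phase-sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import MultichannelEpoch

__all__ = [
    "BandSpec", "BANDS", "preprocess", "band_filter",
    "welch_band_power", "band_power_table", "paired_band_test",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band {self.low}-{self.high} Hz")

    @property
    def center(self) -> float:
        return (self.low + self.high) / 2

    @property
    def width(self) -> float:
        return self.high - self.low


BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 3.0, 7.0),
    "alpha": BandSpec("alpha", 7.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 60.0),
}


def _fir_bandpass(low: float, high: float, rate: float,
                  n_samples: int) -> np.ndarray:
    """FIR band-pass taps, ~3 cycles of the low cutoff, capped for filtfilt."""
    ntaps = min(int(3 * rate / low), n_samples // 4)
    ntaps = max(ntaps | 1, 3)
    return signal.firwin(ntaps, [low, high], pass_zero=False, fs=rate)


def preprocess(data: np.ndarray, rate: float,
               channels: tuple[str, ...],
               epoch_seconds: float = 10.0,
               band: tuple[float, float] = (0.5, 60.0),
               notch_hz: float = 50.0) -> list[MultichannelEpoch]:
    """Filter a continuous recording and cut it into epochs.

    Applies a zero-phase 0.5-60 Hz band-pass plus a 50 Hz notch (power-line
    interference), segments into non-overlapping ``epoch_seconds`` epochs
    and removes each epoch's per-channel mean (baseline correction).

    Parameters
    ----------
    data:
        Continuous samples, shape ``(n_samples, n_channels)``.
    rate:
        Sampling rate in Hz; must exceed twice the upper band edge.

    Returns
    -------
    List of baseline-corrected :class:`MultichannelEpoch`; empty (with a
    warning) if the recording is shorter than one epoch.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if rate <= 2 * band[1]:
        raise ValueError(
            f"rate {rate} Hz too low for a {band[1]} Hz low-pass")
    n = data.shape[0]
    n_epoch = int(round(epoch_seconds * rate))
    if n < n_epoch:
        warnings.warn("recording shorter than one epoch; no output",
                      stacklevel=2)
        return []

    taps = _fir_bandpass(band[0], band[1], rate, n)
    filtered = signal.filtfilt(taps, 1.0, data, axis=0)
    if 0 < notch_hz < rate / 2:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=rate)
        filtered = signal.filtfilt(b, a, filtered, axis=0)

    epochs = []
    for k in range(n // n_epoch):
        seg = filtered[k * n_epoch:(k + 1) * n_epoch]
        seg = seg - seg.mean(axis=0, keepdims=True)
        epochs.append(MultichannelEpoch(
            data=seg, rate=rate, channels=channels, epoch_id=k))
    return epochs


def band_filter(epoch: MultichannelEpoch, band: BandSpec) -> MultichannelEpoch:
    """Zero-phase narrowband filter of every channel of an epoch."""
    nyq = epoch.rate / 2
    if not (0 < band.low < band.high < nyq):
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) outside "
            f"(0, {nyq}) Hz")
    taps = _fir_bandpass(band.low, band.high, epoch.rate, epoch.n_samples)
    out = signal.filtfilt(taps, 1.0, epoch.data, axis=0)
    return MultichannelEpoch(data=out, rate=epoch.rate,
                             channels=epoch.channels, label=epoch.label,
                             epoch_id=epoch.epoch_id,
                             meta={**epoch.meta, "band": band.name})


def welch_band_power(epoch: MultichannelEpoch, band: BandSpec,
                     window_seconds: float = 2.0) -> np.ndarray:
    """Mean Welch PSD over the band's frequency bins, per channel.

    Welch estimate with Hann windows of ``window_seconds`` (default 2 s,
    i.e. at least two cycles of the slowest theta component) and 50%
    overlap.  Returns one non-negative power value per channel.
    """
    nperseg = int(round(window_seconds * epoch.rate))
    if epoch.n_samples < 2 * nperseg:
        raise ValueError("epoch shorter than two Welch windows")
    freqs, psd = signal.welch(epoch.data, fs=epoch.rate, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2, axis=0)
    sel = (freqs >= band.low) & (freqs <= band.high)
    if not sel.any():
        raise ValueError(f"no PSD bins inside band {band.name}")
    return psd[sel].mean(axis=0)


def band_power_table(epochs: list[MultichannelEpoch],
                     bands: dict[str, BandSpec] | None = None,
                     condition: str | None = None) -> pd.DataFrame:
    """Tidy per-(epoch, channel, band) power table.

    Columns: ``epoch, channel, band, power, condition``.  ``condition``
    falls back to each epoch's own label when not given.
    """
    bands = bands or BANDS
    rows = []
    for k, ep in enumerate(epochs):
        eid = ep.epoch_id if ep.epoch_id is not None else k
        cond = condition if condition is not None else ep.label
        for name, band in bands.items():
            power = welch_band_power(ep, band)
            rows.extend(
                {"epoch": eid, "channel": ch, "band": name,
                 "power": p, "condition": cond}
                for ch, p in zip(ep.channels, power))
    return pd.DataFrame(rows)


def paired_band_test(easy: pd.DataFrame, hard: pd.DataFrame,
                     alpha: float = 0.05,
                     correct: bool = False) -> pd.DataFrame:
    """Paired two-sided t-test of band power per channel x band.

    Epochs are paired by their ``epoch`` ids, which must match between
    conditions.  Degenerate all-zero differences return p = 1.0 (no
    evidence of a difference).  Benjamini-Hochberg correction across
    channels is available behind ``correct`` but off by default.

    Returns a frame with columns ``channel, band, t, p, significant``.
    """
    rows = []
    for (ch, band), e_grp in easy.groupby(["channel", "band"], sort=False):
        h_grp = hard[(hard["channel"] == ch) & (hard["band"] == band)]
        e = e_grp.sort_values("epoch")
        h = h_grp.sort_values("epoch")
        if len(e) != len(h) or not np.array_equal(
                e["epoch"].to_numpy(), h["epoch"].to_numpy()):
            raise ValueError(
                f"unmatched epoch pairing for channel {ch}, band {band}")
        diff = h["power"].to_numpy() - e["power"].to_numpy()
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(h["power"], e["power"])
            if np.isnan(p):  # zero-variance nonzero diff: exact constant shift
                t, p = np.inf * np.sign(diff.mean()), 0.0
        rows.append({"channel": ch, "band": band, "t": t, "p": p})
    out = pd.DataFrame(rows)
    if correct:
        from statsmodels.stats.multitest import multipletests
        for band in out["band"].unique():
            m = out["band"] == band
            out.loc[m, "p"] = multipletests(out.loc[m, "p"],
                                            method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    return out
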