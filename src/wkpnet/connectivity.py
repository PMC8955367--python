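"""Phase-locking-value connectivity and surrogate-data binarization.

The functional network of one epoch/band is built in three steps:

1. instantaneous phase of every channel via the Hilbert analytic signal
   ``Z(t) = X(t) + j*HT(X(t))``;
2. for every channel pair, the phase-locking value
   ``PLV = |mean_t exp(j*(phi_1(t) - phi_2(t)))|`` in [0, 1];
3. a per-band significance threshold T from circular time-shift surrogate
   data (shifting destroys cross-channel phase relations while preserving
   each channel's power spectrum); edges are kept where PLV strictly
   exceeds T, yielding an undirected binary network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .containers import MultichannelEpoch
from .spectral import BandSpec, band_filter

__all__ = [
    "PLVMatrix", "ThresholdSpec", "BinaryNetwork",
    "analytic_phase", "plv_from_phases", "plv_pair", "plv_matrix",
    "surrogate_threshold", "binarize",
]

#: Seconds discarded at each epoch end before phase averaging: the Hilbert
#: transform is unreliable near the boundaries of a finite window.
DEFAULT_EDGE_TRIM_SECONDS = 0.25


@dataclass
class PLVMatrix:
    """Symmetric channel-by-channel PLV matrix for one epoch and band."""

    values: np.ndarray
    band: str
    node_labels: tuple[str, ...]
    epoch_id: int | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if v.shape[0] != len(self.node_labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PLV matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLV values must lie in [0, 1]")
        self.values = v
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ThresholdSpec:
    """A per-band binarization threshold and how it was obtained."""

    band: str
    threshold: float
    n_surrogates: int = 200
    alpha: float = 0.05
    method: str = "circular_shift"

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must lie in [0, 1]")
        if self.n_surrogates < 19:
            raise ValueError(
                "need >= 19 surrogates for a 0.05-level percentile")


@dataclass
class BinaryNetwork:
    """Undirected 0/1 adjacency with node labels; no self-loops."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...]
    band: str | None = None
    condition: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.node_labels):
            raise ValueError("label count does not match adjacency size")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8).copy()
        np.fill_diagonal(a, 0)
        self.adjacency = a
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edge_list(self) -> list[tuple[str, str]]:
        i, j = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[i, j] == 1
        return [(self.node_labels[a], self.node_labels[b])
                for a, b in zip(i[keep], j[keep])]


# ---------------------------------------------------------------------------


def analytic_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, wrapped to (-pi, pi]) of a narrowband
    series, via the argument of its analytic signal."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D series")
    if np.ptp(x) == 0:
        raise ValueError("constant signal has undefined phase")
    return np.angle(hilbert(x))


def plv_from_phases(phi1: np.ndarray, phi2: np.ndarray) -> float:
    """PLV of two phase series: magnitude of the mean difference phasor."""
    if len(phi1) != len(phi2):
        raise ValueError("phase series length mismatch")
    return float(np.abs(np.mean(np.exp(1j * (phi1 - phi2)))))


def plv_pair(x1: np.ndarray, x2: np.ndarray, rate: float | None = None,
             edge_trim_seconds: float = DEFAULT_EDGE_TRIM_SECONDS) -> float:
    """Phase-locking value of two equal-length narrowband series.

    When ``rate`` is given, ``edge_trim_seconds`` are discarded at both
    ends before averaging to suppress Hilbert boundary transients.
    Identical inputs give exactly 1.0; independent phases give a value
    near ``sqrt(pi)/(2*sqrt(N))``.
    """
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    if x1.shape != x2.shape:
        raise ValueError("input length mismatch")
    if x1.size < 100:
        raise ValueError("need at least 100 samples")
    trim = int(edge_trim_seconds * rate) if rate else 0
    if 2 * trim >= x1.size:
        raise ValueError("edge trim longer than the signal")
    sl = slice(trim, x1.size - trim if trim else None)
    return plv_from_phases(analytic_phase(x1)[sl], analytic_phase(x2)[sl])


def _phase_array(epoch: MultichannelEpoch, band: BandSpec | None,
                 edge_trim_seconds: float) -> np.ndarray:
    """Channels-by-time matrix of instantaneous phases, edges trimmed."""
    ep = band_filter(epoch, band) if band is not None else epoch
    trim = int(edge_trim_seconds * ep.rate)
    if 2 * trim >= ep.n_samples:
        raise ValueError("edge trim longer than the epoch")
    sl = slice(trim, ep.n_samples - trim if trim else None)
    phases = np.angle(hilbert(ep.data, axis=0))[sl]
    return phases.T  # (n_channels, n_times)


def _plv_from_phase_matrix(phases: np.ndarray) -> np.ndarray:
    z = np.exp(1j * phases)
    m = np.abs(z @ z.conj().T) / phases.shape[1]
    m = np.clip((m + m.T) / 2, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m


def plv_matrix(epoch: MultichannelEpoch, band: BandSpec | None = None,
               edge_trim_seconds: float = DEFAULT_EDGE_TRIM_SECONDS
               ) -> PLVMatrix:
    """PLV between all channel pairs of one epoch.

    The epoch is narrowband-filtered to ``band`` first unless ``band`` is
    None (signal already narrowband).  Equivalent to calling
    :func:`plv_pair` on every pair, but vectorized.
    """
    if epoch.n_channels < 2:
        raise ValueError("need at least 2 channels")
    const = np.ptp(epoch.data, axis=0) == 0
    if const.any():
        bad = [epoch.channels[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant signal on channel(s) {bad}: "
                         "phase undefined")
    phases = _phase_array(epoch, band, edge_trim_seconds)
    return PLVMatrix(values=_plv_from_phase_matrix(phases),
                     band=band.name if band else "broadband",
                     node_labels=epoch.channels, epoch_id=epoch.epoch_id,
                     condition=epoch.label)


def surrogate_threshold(epochs: list[MultichannelEpoch],
                        band: BandSpec | None,
                        n_surrogates: int = 200,
                        alpha: float = 0.05,
                        seed: int = 0,
                        method: str = "circular_shift",
                        edge_trim_seconds: float = DEFAULT_EDGE_TRIM_SECONDS,
                        min_shift_seconds: float = 1.0) -> ThresholdSpec:
    """Per-band edge-significance threshold from surrogate data.

    Each surrogate circularly time-shifts every channel's phase series by
    an independent random offset of at least ``min_shift_seconds``, which
    preserves the power spectrum but destroys genuine cross-channel phase
    relations.  ``n_surrogates`` surrogate draws are taken in total,
    cycling over the supplied epochs; the threshold is the ``1 - alpha``
    quantile of the pooled surrogate PLV distribution over all pairs and
    draws.
    """
    if n_surrogates < 19:
        raise ValueError("n_surrogates must be >= 19")
    if method != "circular_shift":
        raise NotImplementedError(f"surrogate method {method!r}")
    if not epochs:
        raise ValueError("no epochs given")
    rate = epochs[0].rate
    min_shift = int(min_shift_seconds * rate)
    rng = np.random.default_rng(seed)

    used = epochs[:min(len(epochs), n_surrogates)]
    phasor_arrays = []
    for ep in used:
        if ep.duration < 2.0:
            raise ValueError("epochs shorter than 2 s cannot be "
                             "meaningfully circular-shifted")
        phases = _phase_array(ep, band, edge_trim_seconds)
        if phases.shape[1] <= 2 * min_shift:
            raise ValueError("epoch too short for the minimum shift")
        phasor_arrays.append(np.exp(1j * phases))

    iu = np.triu_indices(phasor_arrays[0].shape[0], k=1)
    pooled: list[np.ndarray] = []
    for s in range(n_surrogates):
        z = phasor_arrays[s % len(phasor_arrays)]
        n_ch, n_t = z.shape
        shifts = rng.integers(min_shift, n_t - min_shift, size=n_ch)
        shifted = np.empty_like(z)
        for c in range(n_ch):
            shifted[c] = np.roll(z[c], int(shifts[c]))
        m = np.abs(shifted @ shifted.conj().T) / n_t
        pooled.append(m[iu])
    thr = float(np.quantile(np.concatenate(pooled), 1 - alpha))
    return ThresholdSpec(band=band.name if band else "broadband",
                         threshold=thr, n_surrogates=n_surrogates,
                         alpha=alpha, method=method)


def binarize(plv: PLVMatrix, thr: ThresholdSpec) -> BinaryNetwork:
    """Edge where PLV strictly exceeds the band threshold; no self-loops."""
    if plv.band != thr.band:
        raise ValueError(
            f"band mismatch: PLV is {plv.band!r}, threshold is {thr.band!r}")
    adj = (plv.values > thr.threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adjacency=adj, node_labels=plv.node_labels,
                         band=plv.band, condition=plv.condition,
                         meta={"threshold": thr.threshold,
                               "alpha": thr.alpha,
                               "n_surrogates": thr.n_surrogates})
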