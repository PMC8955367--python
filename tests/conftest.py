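import numpy as np
import pytest

from wkpnet.connectivity import BinaryNetwork
from wkpnet.containers import MultichannelEpoch
from wkpnet.spectral import BANDS
from wkpnet.synth import OscillatorSpec, generate_epoch


def make_network(edges: list[tuple[str, str]],
                 labels: tuple[str, ...]) -> BinaryNetwork:
    idx = {lab: i for i, lab in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    return BinaryNetwork(adjacency=adj, node_labels=labels)


@pytest.fixture
def path_abc() -> BinaryNetwork:
    """Path graph A - B - C."""
    return make_network([("A", "B"), ("B", "C")], ("A", "B", "C"))


@pytest.fixture
def star4() -> BinaryNetwork:
    """Star: center S with three leaves."""
    return make_network([("S", "L1"), ("S", "L2"), ("S", "L3")],
                        ("S", "L1", "L2", "L3"))


@pytest.fixture
def coupled_pair_epoch() -> MultichannelEpoch:
    """Two perfectly coupled theta channels (no jitter, no noise)."""
    b = BANDS["theta"]
    spec = OscillatorSpec(band_center=b.center, band_width=b.width,
                          coupling_groups=(("C3", "C4"),),
                          phase_jitter_sigma=0.0,
                          amplitude_noise_sigma=0.0,
                          channels=("C3", "C4"))
    return generate_epoch(spec, seed=7)


@pytest.fixture
def sine_epoch() -> MultichannelEpoch:
    """Unit-amplitude 10 Hz sinusoid plus a second, phase-shifted copy."""
    rate, dur = 500.0, 10.0
    t = np.arange(int(rate * dur)) / rate
    data = np.column_stack([np.sin(2 * np.pi * 10 * t),
                            np.sin(2 * np.pi * 10 * t + 0.7)])
    return MultichannelEpoch(data=data, rate=rate, channels=("A", "B"))
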