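# wkpnet

Functional brain-network analysis for two-state EEG experiments:
phase-locking-value (PLV) connectivity, surrogate-data network
binarization, **K-order propagation-number (WKPN)** node-importance
ranking with structure-entropy weighting, and SVM classification of
cognitive state from node-importance feature vectors.

The package targets researchers analyzing multichannel scalp EEG under
two task conditions (e.g. low vs high working-memory load) who want to
locate the electrodes that act as network hubs in each rhythm band and
to quantify how well those hub profiles separate the two states. Because
such recordings are rarely shareable, the package ships a fully
controllable coupled-oscillator signal generator, so every stage is
testable against closed-form ground truth.

## The method

For each epoch and band, channels are narrowband filtered and the
instantaneous phase φ(t) of each channel is taken from the Hilbert
analytic signal Z(t) = X(t) + j·HT(X(t)). For channels a, b the
phase-locking value is

    PLV(a,b) = | ⟨ exp( j·(φ_a(t) − φ_b(t)) ) ⟩_t |  ∈ [0, 1].

A per-band threshold T is the (1−α) quantile of PLVs computed from
circular time-shift surrogates (same spectra, destroyed cross-channel
phase relations); edges with PLV > T form the binary network.

On that network, with D(v,u) the shortest-path length and d its maximum
finite value, the K-order propagation number of node v is

    N_v^K = #{ u : D(v,u) ≤ K },       K = 0 … d,

the number of nodes an "infection" seeded at v reaches within K steps.
Each order is weighted by its structure entropy
H_K = −Σ_i p_i ln p_i with p_i = N_i^K / Σ_j N_j^K, and the importance
score is the entropy-weighted average of normalized propagation numbers

    Q_v = Σ_K c_K · S_v^K,    c_K = H_K / Σ H,   S_v^K = N_v^K / Σ_j N_j^K,

so Σ_v Q_v = 1. Unlike degree or PageRank, Q rewards nodes that reach
many others *quickly* — including low-degree bridge nodes. Weighted
degree centrality (WDC) and weighted PageRank (WPR) are provided as
baselines, and an RBF-kernel SVM evaluated on repeated stratified 3:2
splits turns per-epoch Q vectors into a state classifier.

## Worked example

`examples/04_node_importance.py` ranks a 7-node bridge topology — two
triangles joined through node X:

```
max distance d = 4
rank  node  Q        degree  pagerank
   1  X    0.1597   2       0.1250
   2  A3   0.1563   3       0.1828
   3  B1   0.1563   3       0.1828
   4  A1   0.1319   2       0.1273
...
marked nodes (normalized Q > 0.8): ('A3', 'X', 'B1')
```

The bridge X has the *lowest* degree and PageRank, yet tops the
propagation-number ranking (Q = 0.1597): within two steps it reaches
five of seven nodes, more than any other vertex. The marking rule
(min–max normalized Q > 0.8) highlights the hub backbone X–A3–B1.

The other examples generate coupled oscillators and verify
PLV = exp(−σ²) (`01`), localize band power and flag between-state
differences (`02`), binarize a 62-channel network recovering a planted
coupled group (`03`), classify two coupling states from importance
vectors (`05`), and run the full pipeline from a config (`06`). Each
prints the numbers it computes and what they mean.

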