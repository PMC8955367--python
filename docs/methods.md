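# Methods

This note documents the models, parameter choices and numerical
decisions behind `wkpnet`, and what the synthetic-data experiments do
and do not establish about real EEG.

## Signal model of the generator

`synth` emulates the statistical structure the connectivity analysis
relies on, not EEG biophysics. Each **coupling group** of channels
shares one driver oscillator: Gaussian white noise, zero-phase FIR
band-pass filtered to the band (center ± width/2), extended to its
analytic signal z(t) = A(t)·e^{jφ(t)}. A channel's signal is
A(t)·cos(φ(t) + ε_c(t)) plus optional additive broadband noise, where
ε_c is per-channel Gaussian phase jitter. Channels in no group get
independent drivers. Defaults: 500 Hz sampling, 10 s epochs, the
62-channel extended 10–20 montage (a 64-electrode cap minus the mastoid
references M1/M2), jitter σ = 0.4 rad, amplitude noise 5% of signal
RMS — values typical of a two-condition working-memory protocol.

**Phase jitter is band-limited, not sample-white.** Two coupled
channels with independent jitter of marginal variance σ² have phase
difference variance 2σ², hence population PLV = |E e^{jΔφ}| = e^{−σ²}.
That closed form only requires the *marginal* distribution, so the
jitter may be correlated in time — and it must be: a real signal's
analytic phase cannot carry white jitter (half its power lies at
negative frequencies and is discarded by the Hilbert projection, which
would bias recovered PLV toward e^{−σ²/2}). The jitter is therefore
low-pass filtered at min(band_width, band_center)/2 and rescaled to
exact marginal std σ. Monte-Carlo calibration (400 epochs per σ)
confirms the recovered mean PLV matches e^{−σ²} to within ~0.15
standard errors of the 50-epoch experiments used in validation.

What the generator does **not** model: volume conduction and common
reference (which inflate zero-lag synchrony between neighbors on real
scalp data), 1/f background spectra, artifacts (ocular, muscle, line),
non-stationarity across epochs, and inter-subject variability. Passing
tests therefore demonstrate correctness and calibration of the
*algorithms* under controlled coupling, not performance on recordings.

## Spectral stage

Bands follow the standard split: theta 3–7, alpha 7–13, beta 13–30,
gamma 30–60 Hz. Preprocessing applies a zero-phase FIR band-pass
0.5–60 Hz plus a 50 Hz notch (Q = 30), cuts non-overlapping 10 s
epochs, and removes each epoch's per-channel mean. All filtering is
forward–backward (zero net phase shift) because the downstream PLV is
phase-sensitive; FIR length is ~3 cycles of the low cutoff, capped at a
quarter of the signal for filter stability. Welch PSD uses 2 s Hann
windows with 50% overlap — at least two cycles of the slowest theta
component per window; band power is the mean PSD over in-band bins.
The between-state comparison is a per-channel, per-band two-sided
paired t-test at α = 0.05. All-zero differences return p = 1.0 (no
evidence) by convention; an exactly constant nonzero shift (zero
variance) returns p = 0. No multiple-comparison correction is applied
by default, matching common practice for exploratory topographies; a
Benjamini–Hochberg flag is available.

## Connectivity stage

Instantaneous phase comes from `scipy.signal.hilbert`; 0.25 s are
discarded at each epoch end before phase averaging because the
transform is unreliable near window boundaries (configurable). The PLV
matrix is computed for all pairs at once via the complex phasor Gram
matrix; it equals pairwise evaluation to rounding error.

Surrogate thresholding uses circular time-shift surrogates: every
channel's phase series is rolled by an independent uniform offset of at
least 1 s, preserving each spectrum while destroying cross-channel
alignment. `n_surrogates` (default 200) draws are pooled over all pairs
(cycling over epochs when several are supplied) and the threshold is
the (1−α) quantile, one threshold per band. Edges require PLV
*strictly* above T, so T = 1 yields an empty network and edge count is
non-increasing in T. Calibration: on ≥ 1000 truly independent pairs the
fraction of supra-threshold PLVs matches α to within ±0.02.

**Choosing α.** The pipeline default α = 0.05 is a per-pair level. With
62 channels there are 1891 simultaneous pair tests, so a *calibrated*
0.05 threshold necessarily admits ≈ 95 spurious edges per epoch
network — a random background of mean degree ≈ 3. That is acceptable
when networks are averaged or compared statistically, but it is fatal
to single-network *structure recovery*: the K-order reach terms of the
importance score respond strongly to giant-component fluctuations of
that background (in our experiments a planted 6-channel clique was
recovered at rank 1 in only 20% of replicates at α = 0.05, and
end-to-end classification accuracy dropped from ~0.95 to ~0.73). The
structure-recovery and classification experiments therefore use a
multiplicity-aware edge level, α = 0.001, which keeps the expected
network-wide false-edge count near 2. This is a design choice of the
validation experiments; the per-pair default remains 0.05.

## Importance ranking

`k_order_numbers` takes unweighted BFS distances (scipy's sparse graph
machinery) and counts N_v^K = #{u : D(v,u) ≤ K} for K = 0…d, self
included, where d is the largest *finite* distance (edgeless network:
d = 0). Unreachable nodes never satisfy the indicator, so N_v^d is the
size of v's component. Structure entropy uses natural logarithms; the
weights c_K = H_K/ΣH are base-invariant, so the base affects only
reported H values. Both normalizations in Q are sum-normalizations
(c over orders, S per order over nodes), making Q a weighted average
with Σ_v Q_v = 1; a min–max variant sits behind
`normalization="minmax"`. K = 0 contributes a uniform c_0/n to every
node — rank-neutral, kept for fidelity to the definition.

Two points in the formulation are genuinely ambiguous and both options
are shipped. First, the entropy-weighting *direction*: the literal
formula up-weights high-entropy orders, while the accompanying
intuition ("the larger H_K, the less the nodes differ") argues for the
opposite; `invert_weights=True` gives (1 − c_K)-proportional weights,
and the literal form is the default. Second, ranking ties are broken by
ascending node label for determinism. A single-node graph returns
Q = [1] by convention (H_0 = 0 would make the weights 0/0).

The independent cross-check `experiments.wkpn_bruteforce` computes
distances by boolean matrix powers and evaluates every formula with
plain Python loops; production and oracle agree to < 1e-12 on random
graphs up to n = 12, including disconnected ones.

Baselines: WDC is node strength (row sums of the weighted or binary
adjacency); WPR is weighted PageRank (damping 0.85, each undirected
edge as two arcs with weight-proportional transition probability),
delegated to networkx and verified against the dense Google-matrix
eigenvector.

## Classification

One epoch's network yields one feature vector (per-node Q, strength, or
PageRank, in canonical montage order). Evaluation repeats stratified
3:2 train:test splits (default 20 repetitions, seeded); each repetition
standardizes features on the training fold and fits an RBF-kernel SVM
(C = 1, γ = 1/(m·Var)). When a reduced length m < n is requested, the
top-m nodes are chosen by mean feature value on the *training fold
only* (default) to avoid selection leakage; a `global` mode exists for
comparison. A pure-noise leakage probe (200 samples, top-20 selection)
stays within [0.4, 0.6] accuracy, as does a label-permutation null —
the latter averaged over five permutations, since any single
permutation of 80 labels can be weakly learnable by chance.

## Validation experiment sizes

The seeded experiments in `wkpnet.experiments` use: 100 random graphs
(n ≤ 12) for oracle equivalence; 50 epochs per σ ∈ {0.3, 0.6, 1.0} for
PLV calibration, judged at 3 standard errors; 200 draws of N = 5000
uniform phases for the estimator noise floor √π/(2√N); 46 independent
channels (1035 pairs) for threshold calibration; 50 replicates of a
62-channel epoch with one coupled 6-channel frontal-parietal group for
hub recovery; and 40 epochs per condition (easy: occipital group only;
hard: plus the frontal-parietal group, differing in topology alone) for
end-to-end classification. These sizes keep the full validation run to
a few minutes on one CPU while leaving each statistical check several
standard errors of headroom.

## Known limitations

* The gamma band is defined and usable in the spectral stage, but
  network construction defaults to theta/alpha/beta: narrowband PLV at
  gamma is low and unstable at these epoch lengths.
* WKPN operates on *binary* networks; a weighted-distance variant is
  not implemented.
* Undirected connectivity only — no directed/causal networks.
* The EDF path covers reading only; the native signal container is a
  NumPy array file plus JSON sidecar.
* Surrogate thresholds assume stationary epochs ≥ 2 s; the circular
  shift is the only surrogate method implemented.
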