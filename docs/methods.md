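# Methods

This note documents the models, estimators and numerical choices behind
`hyperlink`, what its synthetic dyads do and do not emulate, and the known
limitations of each stage.

## Data model

The unit container is an epoch array: `(epochs × channels × samples)` in
volts, with sampling rate, ordered unique channel labels, optional 3-D
sensor positions (head-centered RAS, meters) and a set of bad-channel
labels. A two-participant "hyper-epoch" is the channel-wise concatenation
of two aligned containers with `"_1"`/`"_2"` label suffixes (configurable);
`merge`/`split` are exact inverses, epochs are aligned strictly index-wise,
and unequal epoch counts are an error rather than a silent truncation.

On-disk formats: FIF (read/write) and EDF (read) through MNE, plus a
plain-text columnar dialect for fixtures that round-trips float32 values
bit-exactly (`%.9g` printing). The EDF writer included here is minimal —
one data record per epoch, int16 samples with per-channel physical
scaling — so epoch boundaries survive a round trip through the record
duration field; amplitude fidelity is limited to the 16-bit quantization
step of the channel's range.

## Preprocessing

The scientific content of the preprocessing stage is the
*cross-participant intersection rule*: only epochs and channels good for
every participant are kept, so the dyad stays aligned epoch-for-epoch.
Epoch rejection uses one global peak-to-peak threshold (default 150 µV)
applied to channels not already marked bad; rejected channels are dropped
(not interpolated) on both participants. Learned per-sensor thresholds and
ICA-based artifact removal are deliberately out of scope: they substitute
an estimator, not the matching rule, and their semi-automatic component
choices are not reproducible in a test suite. A 4th-order zero-phase
Butterworth high-pass (default 1 Hz) is available for drift removal.

## Spectral decomposition

* **Welch PSD** (`welch_psd`): Hann windows, 50 % overlap, constant
  detrend per segment; frequency spacing `sfreq / (n_fft or n_per_seg)`;
  `n_fft ≥ n_per_seg` enforced. Per-epoch estimates are averaged when
  requested. The four-period rule `min_segment_length(fmin, sfreq) =
  ceil(4·sfreq/fmin)` is advisory: shorter segments trigger a warning, not
  an error.
* **Analytic signal** (`compute_freq_bands`): each band is decomposed into
  every integer frequency inside it (a band of 7.5–11 Hz yields bins
  8, 9, 10, 11 — edges inclusive), at a fixed 1 Hz resolution. Each bin is
  a zero-phase Hamming-window FIR band-pass 1 Hz wide (target transition
  0.5 Hz) followed by an epoch-wise Hilbert transform; epochs are never
  concatenated. Filtering uses reflection padding (`filtfilt`), and the
  tap count is capped near a third of the epoch length so the filter stays
  well-posed on short epochs — on a 2 s epoch at 256 Hz the effective
  transition widens to a few Hz. Consequence: metric values near epoch
  edges carry Hilbert/filter edge bias; validation statistics that target
  exact constructions (e.g. unit PLV under full coupling) are therefore
  evaluated on the central 80 % of samples. The default band table
  (Theta 4–7, Alpha_Low 7.5–11, Alpha_High 11.5–13, Beta 13.5–29.5,
  Gamma 30–48 Hz) is configurable.

## Connectivity

All metrics are computed channel-pair-wise on the stacked 2N channels and
averaged (unweighted) over a band's integer bins. Epoch aggregation: phase
metrics are computed over time within each epoch, then averaged across
epochs; the coherence family pools its expectations over samples *and*
epochs when averaging (per-epoch values use within-epoch samples as the
averaging support, which is why single-sample coherence is refused as
degenerate). Denominator guards are *relative* (zero-division only), never
absolute floors — EEG-scale data (~10⁻⁵ V) makes absolute epsilons a trap.

Choices worth calling out:

* **ccorr** uses the circular-statistics sine-deviation formula, not raw
  Pearson on wrapped angles (discontinuous at ±π); the literal variant is
  available via `angle_pearson=True`.
* **proj_pow_corr** orthogonalizes per sample (`y_orth = Im(y·z̄_x/|x|)`)
  and averages both orthogonalization directions, since the one-sided
  value is direction-dependent but the metric is presented as
  non-directional. If orthogonalization annihilates the signal (y ∝ x)
  the value is defined as 0.
* **MVAR/PDC**: least-squares VAR fit per epoch with coefficients averaged
  across epochs; default order 5; stability is checked via the companion
  matrix spectral radius and an unstable fit produces a warning, not an
  error. PDC is the classic column-normalized (Baccalá–Sameshima) form, so
  squared column entries sum to 1 exactly. For the joint matrix, entry
  [i, j] of a directional metric is the influence of channel i on j.
* **Transfer entropy** is the Gaussian (linear) estimator with lag k = 1 by
  default; it equals half the linear Granger log-ratio by construction.
  Nonparametric TE estimators are out of scope.
* **Directional metrics on bands**: PDC and TE are fitted on the
  band-limited real signal, reconstructed as the mean of per-bin real
  parts of the analytic signal. Caveat: zero-phase filtering is acausal
  and smears lag structure, so band-limited TE asymmetries are attenuated
  relative to TE on the raw signals; the directed simulator fixtures are
  therefore validated both ways.
* **Standardization** follows the grand z-score recipe exactly: zero the
  diagonal, subtract the grand mean, divide by the grand standard
  deviation — all cells including the zeroed diagonal. The output has
  grand mean 0 and std 1 and is exactly invariant to positive rescaling;
  an additive offset is *not* removed exactly, because the offset
  interacts with the zeroed diagonal. A block whose off-diagonal cells are
  constant is refused as degenerate. Note the zeroed diagonal also zeroes
  homologous-channel inter-brain pairs, which is faithful to the recipe
  but means same-channel inter-brain coupling must be read off before
  standardizing.

## Statistics

* **Adjacency** (`con_matrix`): Delaunay triangulation of the montage
  after azimuthal equidistant projection to 2-D (a distance-threshold rule
  is selectable). The space–frequency expansion indexes cells
  channel-major (`c·F + k`) and connects spatial neighbors at the same bin
  and the same channel at adjacent bins. For inter-brain matrices,
  `interbrain_adjacency` declares two links neighbors when their
  endpoints are neighbors-or-identical on each head.
* **`perm_ttest_fdr`**: one-sample t against zero per cell; sign-flip
  permutation p-values (exact enumeration when `2^n_subjects ≤
  n_permutations`, otherwise random flips with the (1+b)/(1+m)
  convention); Benjamini–Hochberg step-up at α. Zero-variance cells are
  flagged undefined and excluded from the FDR family.
* **`statscluster`**: cluster-forming threshold defaults to the parametric
  critical value at α for the chosen statistic (configurable as a raw
  value); positive and negative t-clusters are formed separately for
  two-tailed tests; cluster mass is the sum of statistics over the
  connected component; the null is the maximum |mass| over label
  permutations (sign flips for the paired test), and cluster p-values use
  the (1+b)/(1+m) convention, so p = 0 is impossible. Permutation
  statistic maps are computed vectorized (sums and sums of squares under
  the permuted labeling), which is what makes 500-simulation calibration
  runs cheap. Multi-way ANOVA clustering is declared unsupported and
  raises.
* **`permute_dyads`**: epoch-level time shuffling (independent permutation
  per participant), derangement-based fake pairs within a group, and
  cross-group fake pairs. All schemes are seed-reproducible.

Calibration, measured by the acceptance script under nominal α = 0.05:
cluster type-I error over 500 null simulations (10 + 10 subjects, 12-cell
chain maps, 1000 permutations) and the FDR null flag rate over 200
simulations; both are recomputed at run time, not quoted.

## Visualization

Sensors are projected per head by the azimuthal equidistant projection and
the two heads placed side by side. Links are 10th-order Bézier curves:
the 11 control points are the endpoints plus 9 interior points displaced
perpendicular to the chord by a sinusoidal arch (peak 0.25 of the chord
length) with an orientation-normalized normal, so the curve is identical
under endpoint swap and endpoints are exact. Thresholding is signed by
default (`value > threshold`), with an absolute-value mode. Positive
values use the sequential Reds colormap, negative Blues; line width is
`0.5 + 1.5·|value|`, strictly increasing in strength. Bad channels are
drawn as crosses. Link artists carry `gid="link"`, making the rendered
link count a testable contract. The 3-D variant renders a flat sensor
cloud with links; no head mesh (a mesh is an asset, not an algorithm).

## Synthetic dyads

`simulate_coupled_dyad` builds narrow-band oscillations from a wrapped
Gaussian random-walk phase around a carrier (default 10 Hz, walk SD 0.05
rad/sample) — phase synchronization in real data is inherently
non-stationary, and the random walk reproduces that — with a small uniform
carrier detuning (±0.5 Hz) drawn per oscillator, because two individuals'
rhythms are never at exactly the same frequency; without detuning, two
independent 10 Hz oscillators look spuriously locked over a short epoch.
Envelopes are smoothed log-normal (~0.5 s correlation scale), with a
controllable envelope correlation ρ_env on the coupled pair, and white
Gaussian sensor noise is added (default 0.2 of oscillation RMS).

Coupling: participant 2's phase on a coupled channel interpolates
circularly between its own independent walk and participant 1's lagged
phase, `φ₂ = φ_ind + κ·wrap(φ₁ + lag − φ_ind)`. κ = 0 is an exact null,
κ = 1 an exact constant offset (PLV → 1); intermediate κ yields partial
locking with occasional phase slips where the wrapped difference crosses
±π. Seeding spawns one substream per participant per epoch from the
master seed, so extending the epoch count never reshuffles earlier
epochs. `simulate_directed_dyad` plants a one-sample-lagged linear
influence (`y_t += a·x_{t−1}`) for validating the causality measures.

What the simulator does *not* emulate: volume conduction and field
spread, 1/f broadband background (available only as an option), multiple
simultaneous rhythms, artifacts (blinks, muscle), or realistic montage
geometry beyond a circular ring. Passing tests therefore demonstrate
estimator correctness and calibration under clean narrow-band coupling,
not robustness to every property of real EEG.

## Problem sizes and measurement conventions

The validation suites use deliberately small but statistically adequate
problem sizes, chosen by power analysis of the generator's own
variability: Monte-Carlo oracles at n = 10⁴ samples; coupling recovery on
20 replicates per κ of 16 four-second epochs (two channels), which puts
the weakest comparison (ccorr between κ = 0 and κ = 0.3) about four
standard errors above zero; calibration on 500 null simulations of
12-cell maps at 1000 permutations. Where a construction is exact only
away from filter edges (unit PLV at κ = 1), phases are measured on the
central 80 % of each epoch at the carrier bin.

## Known limitations

* Channel labels are compared literally in the intersection rule; callers
  working with suffixed hyper-epochs should intersect before merging.
* The FIR bank's effective transition width depends on epoch length; very
  short epochs (< ~1 s) give poorly isolated 1 Hz bins.
* Gaussian TE sees only linear dependence; PDC inherits MVAR's
  sensitivity to order choice (default 5, AIC selection not default to
  keep runs deterministic).
* Cluster inference is at the cluster level: significance of a cluster
  does not license claims about individual cells within it.
* Rendering determinism is guaranteed at the artist level (same inputs
  give identical line data); byte-identical image files additionally
  require fixing matplotlib's metadata.
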