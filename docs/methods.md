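# Methods

This note documents the models, estimators, defaults and design choices in
`restsync`, and what the synthetic-data tests do and do not establish about
real recordings.

## Data model and montage

Recordings are channel × epoch × sample voltage arrays in microvolts with a
sampling rate; a continuous record is a single epoch. The packaged montage
is the standard 10-10 position set for the 64-channel Biosemi label layout,
normalized to the unit sphere (`src/restsync/data/biosemi64.tsv`). EDF
files are read through MNE (physical units converted to µV); the package's
own interchange format is a `.npy` voltage matrix with a JSON sidecar
(labels, fs, epoch length, group), which round-trips exactly.

Electrode adjacency for cluster formation connects electrodes whose chord
distance on the unit sphere is below a threshold. The default (0.58) was
chosen once so the 64-channel montage yields a connected graph with median
node degree 7 — a typical EEG neighbourhood; it is configurable and logged.
The edge set is invariant under global rotation of the montage because it
depends only on pairwise distances.

## Preprocessing

The implemented chain is the tail of a conventional cleaning pipeline and
assumes gross artifacts (line noise, ocular/muscle components, bad
channels) have already been removed — the synthetic data are clean by
construction:

1. **Band-pass 2–46 Hz**, zero-phase. Realized as a linear-phase Hamming
   FIR applied with group-delay compensation (odd tap count; default
   transition width 1 Hz, ~845 taps at 256 Hz). Passband ripple is ≈0.2%
   and stopband attenuation exceeds 50 dB one octave outside the band.
   Zero phase matters because every phase metric downstream would inherit
   a filter phase distortion.
2. **Common-average reference**: subtract the instantaneous channel mean
   (idempotent; commutes with linear filtering).
3. **Segmentation into 1-s epochs**; trailing remainder samples dropped.
4. **Epoch rejection at |z| > 2**: three per-epoch metrics, each averaged
   over channels — variance, peak-to-peak amplitude range, and deviation of
   the epoch mean from the channel's whole-record mean. An epoch is
   rejected when *any* metric's z-score across epochs exceeds the threshold
   (two-sided: "deviating" is unsigned). The metric triplet is a documented
   choice; published epoch-rejection tools use larger metric families, but
   the contract here is the 2-SD deviation rule itself.

## Spectral analysis

Welch PSD with 2-s, 50%-overlap Hamming windows (defaults; configurable)
over the retained epochs concatenated in time, density-normalized so the
PSD integral matches the signal variance up to windowing bias. Segment
windows that straddle an epoch join contribute only broadband leakage that
is negligible at these lengths.

Relative power assigns PSD bins half-open to bands. The conventional
printed integer band edges (2–3, 4–8, 9–13, 14–30, 31–45 Hz) leave 1-Hz
gaps, so the default scheme closes them into the contiguous partition
[2,4), [4,9), [9,14), [14,31), [31,46) Hz — making per-channel relative
powers sum to exactly 1. The literal integer edges remain available
(`BandScheme.printed()`) for strict replication. No 1/f removal is applied:
the aperiodic background is part of the total by design.

## Connectivity

Phase is the argument of the analytic signal of the band-filtered trace.
Filtering and the Hilbert transform act on the *continuous* record before
epoch slicing (1-s epochs are too short to band-filter cleanly at theta),
then the epoch-rejection mask is applied. The band filter reuses the
preprocessing FIR design with ≤1 Hz transitions.

PLV, iPLV and ciPLV are computed per epoch per unordered channel pair from
the complex mean phasor C of the phase difference, then averaged across
epochs — robust to slow nonstationarity and consistent with epoch-based
cleaning (whole-record estimation is the obvious alternative; epoch-wise is
the package default and is configurable upstream of the estimator, which
simply receives the epoch axis). When 1 − (Re C)² < ε (default 1e-12) the
ciPLV denominator is degenerate — perfect zero-lag locking — and ciPLV is
defined as 0, since a purely instantaneous lock carries no lagged synchrony.
ciPLV ≥ iPLV whenever Re C ≠ 0, with equality iff Re C = 0; both lie in
[0, 1]. Node strength is the mean connectivity of an electrode to all
others.

## Group statistics

- **Scalar permutation test**: pooled-variance two-sample t as statistic;
  null by random group relabelings preserving group sizes; add-one p-value
  (1 + #extreme)/(1 + n_perm). When C(n, n₁) ≤ n_perm the null is
  enumerated exhaustively and p = #extreme / #relabelings (identity
  included, so p > 0). Degenerate constant input returns p = 1.
- **Edge-wise test**: the same permutation test applied per edge with a
  *shared* relabeling schedule (preserving the spatial correlation of the
  null), then Benjamini–Hochberg FDR across edges within a band, plus
  pooled-SD Cohen's d and the direction of the difference.
- **Cluster-based permutation test**: electrode-wise pooled t; electrodes
  with |t| above the two-sided t threshold at cluster_alpha = 0.05 form
  candidate nodes; connected components under the montage adjacency —
  formed separately for positive and negative candidates, so a cluster is
  sign-consistent — have mass Σ|t|; the null is the maximum cluster mass over
  relabelings (positive and negative clusters pooled, matching the
  two-sided threshold). The cluster-forming threshold and mass statistic
  follow common practice and are configurable.
- Elementary statistics — BH-FDR (statsmodels), Spearman rho and Kendall
  tau-b (scipy, tie-corrected), Tukey 1.5·IQR fences with
  linear-interpolation quartiles, pooled-t from summary statistics — are
  thin, validated wrappers.

The pipeline default mirrors how such studies are reported: cluster
correction for electrode power maps, edge-wise FDR for connectivity. The
reference permutation count is 50,000; scaled-down runs (tests, the
acceptance script) use 999 for scalar/cluster nulls and 4,999 for edge-wise
tests — the edge test needs the finer p-value floor because BH across 2016
edges cannot reject at q = 0.05 when the smallest attainable p is 1/1000
and tens of edges share it.

Demographic-table replication: the four printed two-sample t values
(age −0.16, education −2.63, work status −3.39, MoCA −4.78) are reproduced
from the printed means/SDs by the *pooled* (not Welch) t to within |Δt| ≤
0.03, i.e., within the rounding of the printed inputs. The printed sex
chi-square (0.891) is not reproducible from the printed counts 16/12 vs
15/12 by Pearson or Yates chi-square (both ≈ 0.01), so no chi-square
operation is provided against it.

## Synthetic data generator

The generator emulates the study design the analysis targets, with every
effect recoverable:

- **Sources**: narrowband Gaussian processes (white noise band-passed to
  centre ± 1 Hz, analytic-signal form a(t)·cos φ(t)). Default layout: two
  centroparietal theta (6 Hz) sources under CPz and Pz (independent
  per-subject variability, so the regional effect is not a single shared
  amplitude draw; amplitude 0.4 each), theta sources under FT7/FT8, a beta
  (20 Hz) pair under F3/P3, and alpha (10 Hz) sources under O1/O2 (unit
  amplitude). The centroparietal amplitudes and the study SNR are balanced
  so the unaffected group's band profile stays plausible at the projection
  peak (theta share ≈ 0.4-0.5 at Pz, occipital alpha dominant) rather than
  saturating.
- **Couplings**: a coupling (i→j, lag, strength s) replaces φ_j with
  φ_i + lag + (1−s)·W(t), W a Gaussian random walk (0.35 rad/√sample), so
  s = 1 is a constant-lag lock, s = 0 decorrelates within an epoch, and
  estimated synchrony increases monotonically with s. Amplitudes stay
  independent, so couplings are invisible to power analyses. Phase
  replacement was chosen over coupled-oscillator (Kuramoto) dynamics for
  direct control of exactly the quantities ciPLV estimates.
- **Forward mixing**: strictly same-sample Gaussian leakage
  M[e,k] = exp(−d²/2w²) (chord distance, default width w = 0.25), so
  sensors can inherit zero-lag but never lagged correlations — the central
  contract, tested directly.
- **Noise**: per-channel independent 1/f^β noise (default β = 1),
  frequency-domain synthesis; SNR is the channel-mean ratio of
  projected-source variance to noise variance within 2–46 Hz, computed
  exactly from the synthesis coefficients (generic default 1.0; the default
  study template uses 0.5).
- **Two-group study**: defaults n = 28/27 subjects, 300 s at 256 Hz. The
  first group receives a theta power multiplier (1.6) at both
  centroparietal sources, a theta FT7↔FT8 coupling (lag π/2, strength 0.9),
  and a beta F3↔P3 coupling (lag π/2, strength 0.85). Per-subject log-normal
  amplitude variability (σ = 0.25) sets the between-subject spread; the
  multiplier was calibrated once so the electrode-level theta
  relative-power difference lands at Cohen's d ≈ 0.8–1.1 at n = 28/27,
  matching the effect-size range such studies report. Source count, SNR and
  subject variability have no published values; they are free, documented
  parameters chosen to look like resting EEG at a coarse level.
- **Ground truth**: electrodes receiving ≥ 25% of a power-boosted source's
  peak leakage gain are marked as planted power effects; couplings plant
  edges between the 3 nearest electrodes of each coupled source (the
  nearest–nearest pair is "primary"). Leakage genuinely spreads a coupling
  effect over neighbouring electrode pairs, so the neighbourhood — not just
  the primary pair — is excluded from the false-positive denominator.

What the simulator does *not* emulate: realistic head-model leadfields
(BEM/FEM), ocular/muscle artifacts, heteroscedastic or spatially correlated
noise, alpha-blocking dynamics, or nonstationarity beyond the oscillators'
own envelopes. Passing recovery tests therefore show the estimators and
statistics are correct and calibrated under controlled conditions — not
that any particular clinical effect exists or is detectable in real data.

## Determinism and numerics

All randomness flows from integer seeds through NumPy seed sequences;
identical config + seed reproduces recordings bit for bit and statistics
exactly. Permutation nulls for large edge sets are computed in float32
(magnitude comparisons only; the observed statistics stay float64).
Per-epoch phasors use complex64 — the epoch-mean error (~1e-7) is far below
the estimator's sampling noise. Degenerate inputs are handled explicitly:
zero pooled variance gives t = 0 (or a hard error where a ratio is
undefined), all-epochs-rejected and zero-total-power raise diagnostic
errors naming the offender.

## Problem sizes in tests

The unit suite runs on seconds-long recordings and small groups. The
validation suite uses the study-scale group sizes (28/27) with 60-s
recordings, theta band, 999/4,999 permutations, and 20 simulation seeds —
sizes chosen so the full suite completes comfortably on one CPU while the
detection probabilities being asserted stay near 1.
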