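# Methods

## Model and assumptions

Scalp EEG during motor imagery is treated as an instantaneous linear
mixture `X = E S` of independent cortical sources (volume conduction is
memoryless at EEG timescales).  Hand imagery expresses itself as
event-related desynchronization (ERD) of the μ rhythm (8–12 Hz) over the
contralateral sensorimotor cortex: a class-dependent *reduction of
band-limited power*, not a phase-locked waveform.  Two consequences shape
the method:

1. Because the discriminative signal is an amplitude-spectrum effect, the
   demixing matrix is learned on **amplitude spectra** (spectral ICA):
   channels are the variables, frequency bins the observations.  This
   targets the spatial directions that carry structured band power rather
   than directions of maximal temporal non-Gaussianity.
2. An amplitude spectrum has no phase, so it cannot be inverted back to a
   time series.  The learned `W` is therefore applied to the *time-domain*
   channels; by linearity of the DFT this is identical to demixing the
   complex spectra and inverse-transforming.  The amplitude spectra are
   used only to learn `W`.  This equivalence is asserted to 1e-10 in the
   test suite.

Per hemisphere exactly two components are extracted (relevant +
irrelevant); the four components of both hemispheres are concatenated and
passed to CSP.  Hemispheres are processed separately to stop cross-
hemisphere interference from blurring the per-hemisphere demixing.

## Pipeline stages and defaults

| stage | default | rationale |
|---|---|---|
| band-pass | 5–30 Hz, Butterworth order 4, zero-phase | standard broadband motor-imagery band; forward–backward filtering avoids phase distortion in offline analysis (causal mode available) |
| imagery window | half-open `[t0, t1)`, samples `floor(t·fs)` | filter the full trial first, then cut, so filter transients fall outside the window |
| hemisphere split | montage x-coordinate sign; midline (|x| ≤ 1e-6) excluded | midline channels belong to neither hemisphere; explicit index sets override |
| amplitude spectrum | unnormalized single-sided DFT modulus, no taper, no padding | the infomax fit is scale-equivariant, so normalization is immaterial; tapering would blur the narrow μ peak |
| spectral ICA | 2 components; row-centering (DC bins dropped), principal-axis whitening to 2 dims, natural-gradient infomax, logistic nonlinearity, lr 0.01, tol 1e-7 on the weight change, max 500 iterations | the logistic nonlinearity suits super-Gaussian (peaked-spectrum) sources; whitening reduces the problem to a rotation |
| learning-rate annealing | ×0.98 whenever the gradient direction turns by > 60° | annealing on *any* step-size increase collapsed the rate before a consistent fixed point was reached; direction-based annealing converged to the same solution from 20/20 random initializations |
| observation cap | 4096 spectral columns (seeded subsample) inside the pipeline | bounds the per-fold cost of cross-validation; whitening always uses all columns.  Analyses of single short spectra (e.g. the 6-channel simulation) instead raise `max_iter` to 5000 and tighten `tol`, because a few hundred effective bins make the infomax landscape shallow |
| component conventions | order by μ-band contrast (mean amplitude in 8–12 Hz over mean in 5–8 ∪ 12–15 Hz), deficit first; scalp patterns unit-norm with positive largest entry | removes the permutation/scale/sign indeterminacy of ICA so fits are comparable across seeds; classification is unaffected (all components are kept) |
| ICA fit scope | one `W` per hemisphere on the column-concatenated training spectra | a per-trial `W` (the literal reading of per-trial notation) is available as `ica_fit_scope="per-trial"`, but the train-concatenated fit avoids per-trial permutation ambiguity and keeps test trials transformed by a frozen model |
| CSP | per-trial trace-normalized covariances averaged per class; eigendecomposition-based whitening; eigenvalues sorted descending; filter-row signs fixed | trace normalization makes the filter invariant to per-trial gain; degenerate covariances raise (with a ridge suggestion) rather than silently regularizing |
| feature | scalar `f = var(Z1)/(var(Z1)+var(Z2))`, unbiased variance, first and last filter rows | matches a one-dimensional feature scatter; `csp_n_pairs > 1` emits the conventional normalized-variance vector.  `f` is invariant to trial scaling, so biased vs. unbiased variance only matters for unequal trial lengths |
| classifier | RBF-kernel SVM, C = 1, kernel width from the median pairwise feature distance | reproducible default without a tuning loop; the median heuristic adapts the width to the observed feature spread |
| cross-validation | K = floor(n/2) stratified folds (one trial of each class per fold when counts allow); every trial tested exactly once | the fold construction scans a seeded permutation and is symmetric under class relabeling; partitions are redrawn (≤ 100 times) if a fold would empty a class from its training complement |
| learning curve | sizes round(linspace(2, 50, 10)) = {2, 7, 13, 18, 23, 29, 34, 39, 45, 50}, 10 repeats, class-balanced draws, tested on all remaining trials | ten steps spanning 2–50 training trials |

All fitted state (ICA demixing, CSP filter, classifier, kernel width)
derives from training folds only; preprocessing is per-trial and
stateless, so it may be computed once per dataset without leakage.

## Synthetic data

`generate_fig2_simulation` builds each channel as a sum of 1–20 Hz
sinusoids with amplitude ∝ f^(−0.5) (larger at low frequencies, a crude
1/f surrogate) and uniformly random phases; on channels 5–6 the 8–12 Hz
amplitudes are scaled by 1 − depth (default 0.7).  One global rescale sets
the peak to 5 µV so every channel's max + min stays below the 12 µV bound.
The exact frequency grid, phase law and decay exponent are configurable;
integer frequencies are bin-aligned at the default 4 s / 250 Hz, giving
exactly reproducible spectra.

`generate_mi_epochs` works in source space, per hemisphere: a narrowband
8–12 Hz μ source (3 µV RMS, mild lognormal trial-to-trial jitter), 1/f
background sources (1.5 µV RMS), and optionally a class-independent
20–24 Hz oscillator whose amplitude is redrawn per trial from
Uniform(0, max) — irrelevant in-band activity.  `background_jitter` makes
the background amplitudes lognormal per trial, emulating the
nonstationary band power of resting EEG.  Sources are mixed by a
well-conditioned random block-diagonal matrix (volume conduction is kept
within hemisphere so the hemisphere-split premise holds), plus white
sensor noise (0.5 µV default).  Left-hand trials (label 1) scale the
*right*-hemisphere μ amplitude by sqrt(1 − erd_depth) and vice versa; at
`erd_depth = 0` the two class-conditional distributions are identical by
construction.  Defaults: 250 Hz, 2 s trials, 50 trials/class, 6 channels.

What the generator does **not** emulate: ocular/muscular artifacts,
electrode drift, within-trial nonstationarity, spectrally overlapping
relevant/irrelevant sources, and cross-hemisphere leakage.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
mixing model, not performance on real recordings; for real data use the
EDF/GDF readers.

The method-comparison experiment (see `tests/test_acceptance.py`) uses 16
channels, 15 trials/class, erd_depth 0.4, the irrelevant oscillator at
amplitude ≤ 8 µV and background_jitter 0.8.  The condition is deliberately
hostile to broadband variance features: with a *stationary* background and
exact low-rank mixing, plain CSP can null the irrelevant source exactly
and nothing is left to suppress — the comparison only becomes informative
when irrelevant in-band power fluctuates across trials, which is exactly
the regime the spectral integration targets (and the realistic one).

## Numerical choices and degenerate inputs

* Whitening and simultaneous diagonalization run on symmetrized matrices;
  eigenvalues of `S1` are clipped to [0, 1] against roundoff.
* Covariance eigenvalues ≤ 1e-10 raise a rank-deficiency error suggesting
  a ridge, never silent regularization.
* Zero-power trials, empty classes, coincident classes (D = 0) and
  degenerate agreement (pe = 1) raise named errors.
* Infomax non-convergence warns and returns the current `W` with
  `converged=False`; with the strict default tolerance the warning is
  common while the separation quality is already high (the Amari index in
  the recovery tests is ≈ 0.01).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces every
  array bit-for-bit.

## Known limitations

* Exactly two components per hemisphere; no extended (sub-Gaussian)
  infomax, no FastICA/JADE alternatives, no multi-class extension.
* No regularized or Riemannian CSP variants.
* The EDF/GDF readers expect cue annotations (left/right or the 769/770
  codes); recordings without usable events are rejected rather than
  segmented heuristically.
* The amplitude-spectrum reduction to two principal axes can discard
  μ-relevant variance when a single irrelevant source dominates the
  spectra; in such regimes the method degrades gracefully toward the CSP
  baseline rather than failing loudly.
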