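# sccsp — spectral-component common spatial patterns for motor-imagery EEG

Single-trial classification of two-class motor imagery (left vs. right
hand) from multichannel EEG is the workhorse of non-invasive
brain-computer interfaces.  The standard feature extractor, the common
spatial pattern (CSP), projects band-passed (5–30 Hz) EEG onto spatial
filters that maximize the variance of one class while minimizing the
other's — but because it consumes *all* variance in the selected band, it
is sensitive to noise and to class-irrelevant oscillatory activity inside
that band.

SCCSP addresses this by integrating the imagination-relevant content
*before* projecting.  Per hemisphere, an information-maximization ICA is
fitted on the multichannel **amplitude spectra** (spectral ICA, "SICA"):
with `X_f` the m × k matrix of single-sided DFT moduli, a 2 × m demixing
matrix `W` is learned so that `U = W X_f` has maximally independent rows —
one component carrying the μ-rhythm (8–12 Hz) modulation whose
event-related desynchronization (ERD) marks contralateral hand imagery,
the other the irrelevant content.  By linearity of the DFT, applying `W`
to the time-domain channels equals demixing the complex spectra and
inverse-transforming, so each trial is reduced to the 4-row component
matrix `Y_k = [Y1l, Y2l, Y1r, Y2r]`.  CSP then proceeds as usual:

* per-class trace-normalized covariances `C_i = mean( Y Yᵀ / tr(Y Yᵀ) )`,
* whitening `P` of `C = C1 + C2` (`P C Pᵀ = I`),
* simultaneous diagonalization `P C1 Pᵀ = R D1 Rᵀ` with `D2 = I − D1`,
* filter `K = Rᵀ P`, projection `Z = K Y_k`,
* scalar feature `f = var(Z1) / (var(Z1) + var(Z2))` from the most
  discriminative filter row of each class,

followed by an RBF-kernel SVM on `f`.  The package ships the SCCSP
pipeline, the plain CSP and temporal ICA-CSP baselines, the evaluation
statistics (accuracy, Cohen's κ, within-class distance B, between-class
distance D, separability ratio λ = (B1+B2)/D), a K = n/2 cross-validation
and learning-curve protocol, readers for EDF/GDF recordings and a
portable epochs container, and a synthetic ERD generator so everything is
testable without external data.

## Worked example

Spectral ICA on the 6-channel μ-suppression simulation (channels 5–6 carry
attenuated 8–12 Hz content):

```bash
python examples/02_spectral_ica_on_simulation.py
```

```
component  mu/flank contrast  filter energy on ch 5-6
    1             0.005         95.8%
    2          4763.136         66.7%
```

Component 1 has essentially no μ-band energy relative to its flanking
bands (contrast ≈ 0) — it is the μ-deficit component — and its demixing
filter draws 95.8 % of its energy from the two suppressed channels: the
suppression information has been integrated into a single component.

End-to-end comparison under irrelevant in-band activity (16 channels,
modest ERD, a class-independent 20–24 Hz oscillator, nonstationary 1/f
background):

```bash
python examples/04_end_to_end_classification.py
```

```
sccsp : accuracy  73.3% (sd 25.8) | kappa +0.467 | lambda 1.09
csp   : accuracy  53.3% (sd 29.7) | kappa +0.067 | lambda 1.32
```

Accuracy is the mean over K = n/2 cross-validation folds; κ is the
chance-corrected agreement of the pooled predictions; λ is the
within/between-class distance ratio of the pooled features (lower =
more separable).  Under these conditions plain CSP is close to chance
while SCCSP recovers a clear class contrast.

The other examples cover the simulation itself (`01`), the CSP feature
geometry (`03`) and the learning-curve protocol (`05`).  A thin CLI mirrors
the library: `sccsp simulate|preprocess|cv|learning-curve|report --help`.

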