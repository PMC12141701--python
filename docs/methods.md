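# Methods

## Signal model and scope

The pipeline operates on fixed-rate multichannel EEG split into
non-overlapping windows of `fs × window_seconds` samples (default 128 Hz ×
15 s = 1920 samples); a trailing remainder shorter than one window is
discarded. No filtering, re-referencing or artifact handling is applied —
the feature extractor is defined on raw amplitudes, and any preprocessing
belongs upstream of this package.

## Distance-pattern extraction: conventions

The per-sample statistic `DM(i,j) = sqrt(Ch_i² + Ch_j²)` is a radial
magnitude of the two instantaneous amplitudes, not a difference; its argmin
is dominated by jointly low-amplitude channel pairs and its argmax by
jointly high-amplitude pairs. Three conventions are fixed deliberately:

* **Diagonal excluded.** `DM(i,i)` would compare a channel with itself; only
  pairs `i < j` compete.
* **Upper-triangle codes.** The matrix is symmetric, so codes are made
  unique by always taking `a₁ < a₂`. Consequently only `NC(NC−1)/2` of the
  `NC²` histogram bins are reachable; the vectors keep length `NC²` so that
  code arithmetic (`val = (a₁−1)·NC + (a₂−1)` and its exact inverse
  `a₁ = ⌊val/NC⌋+1`, `a₂ = (val mod NC)+1`) stays trivial.
* **Ties.** The first pair in row-major upper-triangle order wins, making
  encoding deterministic and order-stable.

Histograms are raw counts (each sums to the window length), not
frequencies: downstream consumers either rank features or feed a kNN where
a common scale factor is irrelevant, and integer counts keep runs exactly
reproducible.

## Diagonal-weight NCA

Classical NCA learns a full linear transform; feature *selection* needs one
relevance weight per feature instead. The objective maximised here is the
regularised leave-one-out soft-neighbour probability with a per-feature
weighted L1 metric:

    F(w) = (1/n) Σ_i Σ_{j≠i, y_j=y_i} p_ij − λ Σ_f w_f²,
    p_ij ∝ exp(−Σ_f w_f² |x_if − x_jf|)

Features are z-scored internally before weighting; reported relevances are
`w_f² ≥ 0`. Optimisation is deterministic full-batch gradient ascent from
`w = 1` with backtracking step halving (growth factor 1.2 on success), an
iteration cap of 100 and objective tolerance 1e−7; λ defaults to `1/n`.
There is no stochastic element, so identical inputs give bit-identical
weights. Agreement with any particular commercial NCA implementation is not
a goal; what matters downstream is the ranking, and duplicated columns
provably receive equal weights while constant columns decay under λ > 0.

## INCA

Subset sizes *r* = 14..98 are scored by tenfold-stratified-CV
misclassification of 1-NN with city-block distance and equal weights; the
smallest *r* attaining the minimum loss wins. If the feature count is below
98 the range is clipped with a warning. For datasets where a class has
fewer than 10 members the internal stratified CV degrades to the largest
feasible fold count rather than failing.

## DLob

Channels map to eight lobe symbols via the montage table; the default
14-channel montage maps (AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6,
F4, F8, AF4) to (FL, FL, FL, FL, TL, PL, OL, OR, PR, TR, FR, FR, FR, FR).
Each selected feature contributes the symbols of *both* of its decoded
channels, in decoding order, giving a `2N`-symbol string. Merged-vector
indices above `NC²` fold into the max-distance code space before decoding;
the lobe mapping is identical in both spaces.

Entropy is standard Shannon entropy of the observed symbol frequencies,
base 2 by default (base recorded in every report). Transition counting
offers two modes: `consecutive` (all adjacent positions, total = length−1,
the default) and `per_feature_pair` (only within-feature transitions,
total = N), because features are intrinsically channel pairs. Connectome
graphs are directed, weighted by transition count, with zero-count edges
omitted; exports are GraphML, DOT and JSON.

## Ensemble kNN

Grid enumeration is distance-major (cityblock, euclidean, cosine,
spearman), then weight (squared-inverse, equal, inverse), then k = 1..10.
Edge cases the distances require: a zero-norm vector has cosine distance 1
to everything; a zero-variance vector has Spearman distance 1 (correlation
0). Under inverse and squared-inverse weighting, a zero-distance neighbour
would get infinite weight, so coincident neighbours decide alone; equal
weighting needs no such rule. All vote and accuracy ties break to the
smallest label / smallest index, and every sort is stable, so reruns are
bit-identical.

Iterative majority voting takes the element-wise mode of the top-m
accuracy-sorted outcome prefixes for m = 3..120 (118 voted outcomes); the
greedy step picks the most accurate of all 238 candidates. Branch fusion is
the mode of the three branch predictions (a strict majority always exists
for two classes and three voters) followed by a final greedy choice among
{t₁, t₂, t₃, vote} with ties resolved in that order.

## Selection protocols and their bias

The default protocol runs feature selection once on the full dataset before
outer cross-validation, and selects ensemble outcomes by their accuracy on
the held-out predictions themselves. Both steps condition on the evaluation
labels, so the reported accuracies are optimistically biased maxima — on
null data (identical class distributions, 80 segments) the default protocol
reports 77–91% LORO "accuracy" where truth is 50%, of which roughly 25–30
points come from full-data feature selection and 5–10 from taking the best
of 238 correlated outcomes. This is a property of the protocol, not a bug,
and the package reproduces it faithfully.

The `nested_selection` mode repeats NCA ranking, subset-size selection and
ensemble-configuration choice inside every outer training fold and applies
the winning single configuration to the fold's held-out segments. Its
estimates are leakage-free: on the same null data it reports ~50%
(measured 57.5% on one seeded run, within sampling noise of chance), while
a genuinely learnable planted contrast still scores 100%. Any claim that
the pipeline "recovers signal and reports chance on noise" is only testable
in this mode, which is why the end-to-end recovery test uses it.

## Synthetic data

The generator emulates the study-shaped structure — two classes, several
records per class, records split into 15-s windows at 128 Hz over 14
channels — with the minimal signal the extractor is sensitive to:
per-channel amplitude gain. Each channel is an AR(1) process
(`x_t = 0.9 x_{t−1} + ε_t`, ε ~ N(0, 1)) scaled by a class gain profile;
by default class 1 multiplies channels 1–2 (AF3, F7) by 0.1 and class 2
channels 7–8 (O1, O2) by 0.1, which forces the min-distance argmin onto
different pairs per class. Defaults are 10 records per class with 4 windows
each (real recordings average more windows per record; 4 keeps a full
nested LORO run under about two minutes while preserving the record/window
hierarchy). The `null_variant` keeps every size and noise parameter but
equalises the gain profiles, giving an unlearnable control.

What the generator does **not** emulate: oscillatory band structure, 1/f
spectra, artifacts, inter-subject variability, volume conduction. Passing
tests therefore demonstrate the pipeline's mechanics and its sensitivity to
amplitude-pair structure, not performance on physiological EEG.

## Numerical and degenerate-input choices

* Codes and histograms are exact integers; no floating-point comparisons
  enter the feature path (argmin/argmax compare squared sums, avoiding the
  monotone sqrt).
* Records shorter than one window yield an empty segment list with a
  warning, not an error.
* LORO requires ≥ 2 distinct records; metrics require both classes present;
  NCA requires ≥ 2 classes.
* All seeds are recorded in emitted reports; JSON serialisation sorts keys
  so identical runs produce byte-identical files.

## Known limitations

* The per-sample distance is a magnitude statistic, blind to inter-channel
  correlation over time; correlated but equal-amplitude classes are
  invisible to it by construction.
* The default (non-nested) protocol's accuracies should not be read as
  generalisation estimates (see above).
* Printed entropy values in external reports of this method family do not
  always correspond to base-2 or base-e Shannon entropy of their own symbol
  histograms; this package computes standard Shannon entropy and records
  the base, rather than emulating any unspecified estimator.
* EDF export is out of scope; EDF input requires the optional `mne`
  dependency.
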