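# Methods

## Problem setting

One ICU stay is a sequence of timestamped events, each a (variable
label, raw value string) pair drawn from an open-ended, mixed
discrete/continuous variable set. The task is *dynamic* in-hospital
mortality prediction: an updated probability of death at every hour of
the first 48 h after ICU admission, using **all** recorded events with
no variable selection, curation, outlier handling or unit knowledge.
Internally death = 1 and survival = 0, so the model output reads
directly as P(in-hospital mortality); sources that encode survival = 1
are inverted at ingest.

## Pipeline

### Ingest

Events are read from delimited long-format text (configurable column
mapping, so any EHR export can be ingested), attached to a stay, and
assigned 0-based, half-open hour bins [t, t+1) measured from ICU
admission; the window end is exclusive, so an event at exactly 48.0 h
is out of window. Events before admission are dropped, not clamped.
Per stay at most `max_events` (default 5000) events are kept within the
window; when the budget is exceeded the **most recent** events are
retained, since later observations are closer to the outcome. Stays
shorter than `min_stay_hours` (default 48, configurable) or lacking an
outcome are excluded and counted; dynamic evaluation at hour *t* uses
only stays that passed this filter, which keeps the evaluated
population fixed across hours. Rows with unparseable timestamps are
rejected and counted, never silently fixed.

### Tokenization

Typing is purely syntactic: a trimmed value string that parses as a
single finite float is continuous; the sentinels `""`, `nan`, `NaN`,
`NA` (configurable) are missing; everything else — including malformed
numerics such as `7.4.2` — is discrete and kept verbatim. Labels are
used verbatim with no case normalization.

Continuous values are quantized with per-label cut points at the i/B
training quantiles (linear interpolation on the sorted sample).
Assignment is half-open with 1-based bins: values below the first cut
→ bin 1, a value at or above a cut moves past it, values at or above
the last cut share bin B. Tied quantiles are collapsed, and a cut at or
below the sample minimum is dropped (it would create a permanently
empty bin 1), so integer-dense variables get fewer, wider bins and a
constant variable collapses to a single bin. B ∈ {5, 10, 20} is
supported; 10 is the default.

The vocabulary is the set of tokens *observed* in training data (not
the combinatorial label × bin maximum), plus two reserved entries: PAD
(index 0, embedding pinned to the zero vector, used for empty hours)
and a single shared UNK to which tokens first seen at
validation/test time are mapped. Binning and vocabulary are refitted
per cross-validation fold on that fold's training stays only;
`fit_binning` and `build_vocabulary` take a split tag and refuse
test-tagged data outright.

### Model

Per token: an embedding row **e**_v ∈ ℝ^d and an importance logit w_v.
Per hour, the softmax of the logits **over the tokens present that
hour** weights a convex combination of their embeddings. Softmax
normalization was chosen over an unnormalized weighted sum because it
produces a true average (invariant to event count, which otherwise
confounds importance with frequency) and makes w interpretable as a
global ranking. Exact ties in w are broken lexicographically so the
ranking is deterministic. Logits are clipped to ±30 before
exponentiation; with zero-initialized w and the learning rates used,
trained logits stay orders of magnitude below the clip.

Empty hours contribute the zero vector rather than carrying the last
observation forward — the recurrent state already carries history, and
the gap itself is information (the missingness tokens encode it).

The recurrent core is a single-layer LSTM (gate order i, f, g, o;
forget-gate bias initialized at 1; Glorot-uniform gate weights; zero
initial state) with an affine head + sigmoid applied to every hidden
state. The MLP ablation replaces the LSTM with a depth-`mlp_depth`
ReLU stack applied to each hour independently (same hidden width), so
it sees no temporal context by construction.

Training: per-hour binary cross entropy with the stay outcome
replicated as the target at every hour — the reading consistent with a
model whose every hourly output is a usable prediction. The public
`loss` returns the summed form; the optimizer minimizes its mean over
(stay, hour) cells so the stated learning rate is batch-size stable.
Probabilities are clamped to [1e−7, 1 − 1e−7] before logs. Embedding
dropout is whole-token (word-dropout style): each present token is
removed with probability p and the softmax renormalizes over the
survivors; an hour losing all tokens becomes an empty hour. Adam with
lr 5e−4 and batch size 128 are the defaults throughout.

All of this — including backpropagation through the softmax
aggregation and through time — is hand-written on NumPy arrays. The
gradients are verified against central finite differences in the test
suite. Runs are bit-reproducible given the master seed; there is no
thread-level nondeterminism.

### Training protocol

Stays are split 90/10 into a training pool and an untouched test set,
stratified by outcome. Each of `n_folds` (default 10) folds draws an
outcome-stratified validation set of `val_size` stays (default 1000,
automatically scaled to at most a tenth of the pool for small
cohorts) from the pool. Early stopping: an epoch improves if its
validation final-hour AUROC beats the running best by at least
min_delta = 1e−4; after more than 5 consecutive non-improving epochs
training stops and the best epoch's parameters are returned (never a
later epoch's). Validation selection uses the final-hour prediction,
which conditions on the full window. Grid search (over d ∈ {16, 32,
48, 64}, hidden units ∈ {32, 64, 128, 256}, dropout) is exhaustive and
global: one configuration is selected by mean validation AUROC across
folds. `max_epochs` defaults to 100 as a safety bound.

### Evaluation

AUROC uses the Mann–Whitney formulation (ties at half credit), so it
is exactly the probability that a random death is scored above a
random survivor; single-class inputs raise a distinct error rather
than returning 0.5. The dynamic curve scores each test stay at each
hour with the **mean probability across the cross-validated fold
models** (each fold encodes the test stays with its own binning and
vocabulary), then computes per-hour AUROC. Confidence bands are
percentile bootstrap over test-set resamples (default 10,000);
resamples that draw a single outcome class are redrawn and counted.
Trajectory reports list each hour's top-k tokens by aggregation weight
a_i, annotating continuous bin tokens with their nominal percentile
range (bin b of B ↦ [(b−1)/B, b/B]; nominal because collapsed cuts
widen bins). SAPS II (0.72) and OASIS (0.76) appear on plots only as
literature constants at the 24 h mark; they are never computed.

## Synthetic data generator

The generator emulates the statistical structure of ICU event tables:

- **Label frequencies** follow a Zipf law (exponent 1.1) over mixed
  continuous/discrete labels, mimicking the long tail of rare event
  types; common vitals occupy the head.
- **Event rate** per stay is an inhomogeneous Poisson profile
  r(t) = r_late + (r_early − r_late)·exp(−t/τ). The default
  configuration uses r_early = 48/h, r_late = 26/h, τ = 12 h — about
  45–50 events/h shortly after admission, below 30/h by hour 48.
- **Values** per label are normal, lognormal (heavy-tailed) or
  integer-valued; a blood-pH-like variable carries a 5% artifact
  mixture component at 5.5 ± 0.1 against a 7.40 ± 0.05 physiological
  mode, so equal-frequency binning isolates the artifact mass in an
  edge bin.
- **Stay lengths** are lognormal with median ≈ 3.7 days and
  mean/median ≈ 1.6 (a realistic ICU regime), so roughly a quarter of
  stays fall below the 48 h window and exercise the cohort filter.
- **Outcome** is Bernoulli in a logistic link of a scalar per-stay
  latent risk z ~ N(0,1); the intercept is solved numerically so the
  marginal prevalence matches the configured 13.2%. The same z drives
  the signal channels: mean shifts of chosen continuous labels (in SD
  units per unit z), the NaN-rate logit of chosen labels, and the
  probability of a designated high-risk discrete token ("Code
  status_DNR"), each optionally active only from an onset hour. A
  scalar latent risk is the simplest structure that lets these
  channels be mixed *and* yields a computable performance ceiling:
  `bayes_reference_auroc` is the Monte-Carlo AUROC of z itself.

Named presets freeze the study conditions used by the test suite:
`null` (no signal), `strong-signal` (2000 stays, β = 2.2, five value
channels at 0.8 SD/z, discrete channel at 1.8 logit/z),
`missingness-only` (1500 stays, ten NaN-rate channels at 1.2 logit/z,
values uninformative) and `late-signal` (onset hour 24, β = 2.5). The
presets run at a reduced event rate (7/h early, 3.5/h late) and 50
variables — desk-scale conditions chosen so a full
generate/train/evaluate cycle takes seconds, not hours, on one CPU.
The `late-signal` preset is sized at 4000 stays and evaluated with a
25% test split because the pre-onset check is a null test: per-hour
AUROC under the null has SE ≈ √((n+1)/(12·n₁·n₀)), and ~700 test stays
at 13% prevalence keep the pre-onset curve within a few points of 0.5.
Generation caps event times at window + 2 h: later events would be
discarded by ingest anyway, and the 2 h margin keeps the truncation
path exercised.

What the generator does **not** emulate: correlations between
variables (each label's values are conditionally independent given z),
pharmacology/intervention dynamics, demographics, non-stationary
lab panels, and free-text notes. Passing tests therefore demonstrate
that the pipeline recovers signal carried by values, missingness and
discrete tokens under realistic sparsity and artifact structure — not
that it attains any particular performance on real ICU data.

## Numerical and design notes

- Quantile cut points are serialized as `repr` decimal strings, which
  round-trip float64 exactly; binning and vocabulary reload
  bit-identically.
- Bootstrap resampling is vectorized (rank-based AUROC over a resample
  index matrix); redraws for single-class resamples are counted.
- The test suite's training runs use d = 16, h = 32, dropout 0.1, one
  fold, and max_epochs = 40 with the standard plateau rule — small
  enough that the whole suite, including ~20 full training runs,
  completes in minutes on one CPU.
- Stay files use second-resolution timestamps; two events in the same
  second are ordered by file order (sorting is stable everywhere).

## Known limitations

- The importance weights w are only softmax-identified *within* an
  hour: their global comparability emerges from co-occurrence, and the
  within-hour gradient is zero-sum. A moderately frequent informative
  token that habitually co-occurs with other high-weight tokens is
  therefore under-ranked relative to its predictive value; in the
  strong-signal experiments the injected discrete token is recovered
  in the top 10% of the ranking in every seeded run, but not always in
  the top 5%.
- Early stopping selects the prediction-optimal epoch, which can
  snapshot w before the ranking has fully concentrated.
- With ~150-stay test splits, per-hour AUROC carries sampling noise of
  several points; the bootstrap bands make this visible, but
  single-hour comparisons between runs should not be over-read.
- The per-fold vocabulary means fold models disagree on rare tokens
  (UNK-mapped in some folds); fold-averaging smooths but does not
  remove this.
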