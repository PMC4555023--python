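# Methods

## The h² estimator

For signals X, Y in one analysis window (means removed; no filtering or
further detrending, matching an unfiltered acquisition), the observed X
range is divided into `n_bins` equal-width amplitude bins. The regression
curve g passes through the per-bin anchors (mean of X in the bin, mean of
Y in the bin), linearly interpolated between anchors and linearly
extended beyond the terminal anchors with the terminal segments' slopes.
Empty bins contribute no anchor. Then

    h² = clamp(1 − var(Y − g(X)) / var(Y), 0, 1).

Anchors are placed at bin means rather than bin midpoints: this makes the
identity and affine cases exact (g reproduces any linear relation at
every observed point), which in turn pins the estimator's calibration —
h² = 1 on y = ax + b exactly, and h² ≈ ρ² on bivariate Gaussian data
(measured bias ≤ 0.016 at N = 512 with 10 bins).

Degenerate windows (constant X or constant Y) yield h² = 0 at the
pipeline level: a flat channel is uninformative, not fatal. The curve
fitter itself raises on a constant predictor so that misuse is visible
when the estimator is called directly.

**Choices left open by the method's common description** and fixed here:

- `n_bins = 10` equal-width bins. At 512 samples per 2 s window this
  leaves ~50 samples per bin, balancing curve flexibility against anchor
  variance. The measured null level (independent white noise, N = 512) is
  median h² ≈ 0.012.
- Delay scan range 0…round(0.1 s · rate) samples per direction, step one
  sample. 0.1 s comfortably exceeds plausible cortico-cortical and
  thalamo-cortical lags at 256 Hz.
- The scan computes statistics only on the N − τ overlapping samples; no
  padding (padding dilutes the dependence and biases h² toward zero).
- Ties in the scan go to the smallest τ; two directed maxima equal to
  within 1e-9, or a winning delay of zero, make the edge *undirected*: it
  keeps its connectivity weight but carries no direction.

## Windows, graphs and degrees

Windows (2 s, step 1 s) are anchored at the period start and must lie
fully inside the period — a 15 s period yields 14 windows; window time is
the centre. Times are seconds from recording start, sample indices
0-based, a time t maps to sample floor(t · rate).

Degrees are computed per window — an edge with h² > 0.4 and a definite
direction adds one to source-out and target-in — and then averaged over
the period's windows. Averaging counts over windows is what produces
fractional degree values (e.g. a thalamic output of 4.25 with 6 possible
targets); a single graph over the whole period could not. Undirected
edges are excluded from degrees entirely: splitting them half-and-half
would manufacture spurious reciprocity. The 0.4 threshold applies to the
selected (larger) directed value, i.e. after direction selection. When
roles are missing, degrees remain raw counts over the available edges
(not rescaled); availability is recorded in the outputs.

## Synchronization indices

Pair sets over the seven roles (A, Hip, EC mesial; STG, MTG, ITG
neocortical; Th): global = all pairs (21 when complete); thalamic = pairs
containing Th (6); mesio-temporal = mesial × non-mesial pairs including
the thalamus (12) — mesial–mesial pairs are excluded, reading
"between mesial structures and the remaining regions" strictly;
thalamo-mesial = Th × mesial (3). Each per-window measure is the plain
mean of edge h² over its pair set; measures with empty pair sets (absent
roles) are flagged undefined rather than failing, and downstream
averaging skips them.

A period's index averages its measure over the windows whose centres fall
within ±1.5 s of the measure's peak window (ties to the earliest window;
truncated at period edges — an interior peak at 1 s step averages three
values). Each measure is centred on **its own** peak: the alternative —
one privileged reference measure's peak for all four — is equally
consistent with the method's usual description, but per-measure peaks
make each index self-contained and reproducible without an extra
convention. Seizure duration runs from the start of the onset period
(5 s before the tonic discharge) to the end of the discharge; durations
below 30 s make the two 15 s periods overlap, which is flagged but not
fatal.

## Group statistics

- ES vs SO per index: two-sided Wilcoxon signed-rank; exact null
  distribution for n ≤ 25 with no zero differences (zero differences are
  dropped and counted), otherwise the tie-corrected normal approximation.
- ES index vs duration: Spearman rank correlation (average ranks for
  ties; two-sided p from the t-approximation on n − 2 d.f.), plus an
  ordinary least-squares R² for the thalamic index.
- Pattern A vs B: two-sided Mann–Whitney U. The default is the
  tie-corrected normal approximation **without** continuity correction —
  the per-seizure tables contain ties and near-complete separation, where
  exact enumeration is ill-defined in common practice. An exact
  enumeration path exists for tie-free data with min(n) ≤ 8; it agrees
  with the asymptotic path to ≤ 0.01 wherever p < 0.05 (the gap can reach
  ~0.06 for mid-range p, an inherent property of the normal
  approximation at these sample sizes).
- Seizures are treated as independent observations, multiple seizures per
  patient included; `per_patient=True` averages each patient's seizures
  (per pattern) first. No multiple-testing correction is applied; the
  report carries the number of tests performed.

## The synthetic generator

What it emulates: seven-region, 256 Hz recordings of band-limited (4–30
Hz Butterworth-filtered, unit-variance Gaussian) background; scheduled
directed coupling y(t) = (1 − c)·ξ(t) + c·f(x(t − δ)) with f ∈ {linear,
tanh(3·), square} — an instantaneous nonlinear map plus lag, exactly the
dependence class h² represents; targets re-standardized after mixing so
strength is not confounded with amplitude. A scenario is a baseline
epoch, a discharge epoch with weak mesial coupling (amygdala-led,
c = 0.55), and a termination epoch: pattern A drives every region from a
thalamic spike-and-wave train (c = 0.9, stable, distinct lags of 4–14
samples per target, inter-spike intervals growing 0.05 s per cycle from
0.5 s); pattern B couples the same targets at a lower nominal strength
(c = 0.45), redrawn every 2 s from U(0.2·c, 1.8·c) clipped to [0, 1] —
the simplest mechanism producing an unstable, weaker termination. Master seed → per-seizure
seeds via a spawned seed sequence, so cohorts are reproducible and
extensible.

What it does **not** emulate: biophysical neural-mass dynamics, spike
morphology variants beyond the spike-plus-slow-wave kernel (no "arched"
variant), amplitude nonstationarity, artifacts, volume conduction or
common-reference effects, or the absolute index levels of real ictal
SEEG. Passing recovery tests therefore show that the pipeline correctly
recovers coupling structure of this statistical class — not that real
seizures have any particular index value. The published per-seizure table
is the bridge to real data: its group statistics are recomputed from the
packaged transcription, while raw-signal index values are not
reproducible without the recordings.

## Problem sizes

The suite's simulation-backed checks use: 200 seeds for estimator
calibration (Gaussian linear limit, null level), 100 seeds for
delay/direction recovery at c = 0.7, 20 paired scenario seeds for
end-to-end ES-vs-SO, degree-direction and pattern-contrast recovery, and
cohort drivers of 6–22 seizures. The acceptance script uses the same
sizes with 10 paired scenario seeds. These sizes give binomial
confidence well inside the asserted margins (e.g. a ≥ 90% recovery
criterion tested at an observed 100/100).

## I/O conventions

EDF/EDF+ reading goes through `mne`; physical units are assumed µV and
immediately treated as opaque (h² is affine-invariant). EDF+ embedded
annotations are ignored — seizure annotations come only from the sidecar
file, one source of truth. The package writes EDF with a minimal 16-bit
writer (1 s records; integer-valued data round-trips exactly, floats to
one part in 65535 of the channel span) and delimited text losslessly.
Delimited recordings are column-per-channel with a header row of labels
and no timestamp column; the rate must be given explicitly.

## Known limitations

- The h² bin count, delay range and detrending of the original software
  are unstated in the method's public descriptions; the defaults above
  are this package's own calibrated choices.
- Whether the 3 s index average used each measure's own peak or a common
  one is unknown; see above for the choice and rationale.
- The Spearman p-value approximation differs slightly from the one the
  published table's p-values appear to use (t vs normal approximation);
  signs and decisions are unaffected.
- Bipolar derivation accepts any declared contact pair; adjacency is the
  channel map's responsibility.
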