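# Methods

This note documents the models, numerical choices and known limitations of
`specfx`. It is written for users who want to understand what the package
computes and what passing its tests does — and does not — demonstrate.

## The screening cascade

The screen runs in a fixed order: fingerprint matching → GRA + PLS–VIP →
union of spectrum-effect hits → binding intersection → relative-content
filter → BP-network classification. The order matters: the network consumes
the binding flag and content as features, so it runs last, and removing the
binding stage can only enlarge the candidate set (tested property).

**Union of methods.** A peak is a spectrum-effect hit if it passes GRA
(grade > `gra_threshold`, default 0.9, strict) on at least
`min_indicator_hits` indicators **or** VIP (> `vip_threshold`, default 1.0,
strict) likewise. Union is the default because the two statistics respond
to different signal shapes and each alone misses true actives; an
`intersection` mode is available for stricter screens. Both thresholds are
the conventional values of the spectrum-effect literature.

## Fingerprint matching

Peaks are clustered across batches by retention time only. Clusters are
seeded at the reference batch's peak RTs (reference = most peaks, ties by
batch id), and two greedy assignment passes are made — first against the
seed RTs, then against the consensus means of the first pass. Within a
batch, candidate (cluster, peak) pairs are accepted in order of increasing
|ΔRT| with ties going to the earlier-eluting peak; each cluster takes at
most one peak per batch. Members that drift beyond the tolerance of the
final consensus mean are dropped. The procedure is deterministic and
invariant to batch order.

Limitations: real studies corroborate peak identity with UV spectra, which
this package does not model; with `require_all_batches=False`, clusters can
only originate from the reference batch's peaks, and the resulting matrix
has NaN holes that downstream modelling refuses. The matching tolerance
(default 0.5 min) is an explicit parameter because published fingerprint
studies rarely report theirs; the generator's default peak spacing (3 min)
and RT jitter (0.05 min SD) make matching unambiguous, and the matrix then
reproduces the generated areas exactly (tested).

## Gray relational analysis

Reference and comparison series are normalized independently (default:
divide by the series mean — the common choice for fingerprint/activity
series, making them dimensionless around 1; min–max and none are
available). Δmin/Δmax are global over all peaks for a given indicator, the
classical formulation. `ρ = 0.5` throughout (convention). Grade 1.0 is
attained exactly in the identity case; when every comparison equals the
reference (Δmax = 0) all grades are defined as 1.0 with a warning.

**Orientation.** LDH and ROS point "down" (lower = more protection). By
default they are flipped to protection scores, `reference − value`, before
GRA, so a high grade always reads "contributes to protection". The
reference is the injured model-group readout when known (the generator
records it; a CSV sidecar carries it for real data) and the series maximum
otherwise. A `raw` mode uses series as measured; viability and ATP are
never transformed. The flip changes LDH/ROS grades but not viability/ATP
grades (tested).

## PLS1 and VIP

One PLS1 regression per indicator (four models), the convention for
multi-indicator spectrum-effect panels, rather than a single multi-response
fit. The response is the raw indicator series: VIP is invariant to the sign
of y, so no orientation handling is needed. Columns are autoscaled by
default (centered, unit variance, ddof = 1), the chemometric standard; a
constant column is an error naming the peak. With a univariate response the
NIPALS weight step is closed-form (w ∝ Xᵀy), so extraction is
deterministic and the configured inner-loop `max_iter`/`tol` are inert —
they are kept for interface compatibility. Components: A = 2 by default
(A ≤ min(batches − 1, peaks) enforced); a leave-one-out Q² helper is
provided for choosing A but nothing selects it automatically.
`SSₐ = qₐ²·tₐᵀtₐ` is the response variance captured by component a and
weighs the VIP formula; Σ VIP² = P is an algebraic identity and is asserted
to 1e-8 on every fit. The implementation is cross-checked in the tests
against an SVD-based PLS1 oracle and scikit-learn's `PLSRegression`.

## BP neural network

A deliberately minimal single-hidden-layer perceptron on numpy: logistic
sigmoid everywhere, binary cross-entropy (computed in the numerically
stable softplus form), full-batch gradient descent, weights and biases
initialized from seeded uniform(−0.5, 0.5). No momentum, minibatching or
regularization — the textbook "BP network", so its behavior is exactly
auditable; analytic gradients are verified against central finite
differences (relative error < 1e-6 with the standard denominator floor).
Defaults: 8 hidden units, learning rate 1.0, 20 000 epochs — chosen so the
default 36-peak classification set trains to accuracy 1.0; gentler
schedules (e.g. lr 0.1, 2 000 epochs) demonstrably underfit it. Class A =
active = 1; a posterior of exactly 0.5 goes to class B (conservative
screening). The confusion matrix follows the rows-true/columns-predicted
convention.

Training labels: in the synthetic workflow the planted truth; on real data
the user supplies labels for literature-verified peaks and the network
classifies the rest. The pipeline takes labels as an explicit argument to
keep that decision visible.

## Synthetic-data generator

The generator emulates the data regime of a 12-batch spectrum-effect study
with 36 common peaks, 7 planted actives and a 17-peak binding set (the
actives plus 10 binding-only false positives).

Log-areas decompose as

    log area(batch i, peak j) = μⱼ + bᵢ + aᵢ·1[j active] + εᵢⱼ

* `μⱼ` — per-peak size: offsets evenly spaced over ±1.5 log units
  (contents span ~e³, majors to trace), with the actives placed among the
  larger peaks — screens of this kind nominate major constituents. The
  smallest peaks fall below the default 0.5 % content floor, so the
  low-content exclusion is exercised.
* `bᵢ ~ N(0, 0.1)` — global batch strength (overall potency).
* `aᵢ ~ N(0, 0.3)` — the **active-family effect**: the planted actives
  co-vary across batches, as constituents of one compound family do
  (shared biosynthesis and processing). This co-variation is what makes
  every active's peak track the bioactivity — it is the mechanism that
  spectrum-effect screening exploits in practice — and it makes the active
  cohort coherent in feature space.
* `εᵢⱼ ~ N(0, σⱼ)` — idiosyncratic variation, σⱼ = 0.12 for average and
  large peaks, inflated up to 6× for the smallest (near-LOD integration
  noise). These volatile trace peaks supply the large global Δmax that
  gives gray relational analysis its characteristic grade range (many
  grades near 0.9, a handful above).

Indicators are linear in the active areas plus Gaussian assay noise:
`indicator = intercept + Σⱼ βⱼ·areaⱼ + N(0, noise_sd)`. Each active has one
primary indicator (round-robin) with weight 2.0 and weak secondaries (0.3);
coefficients are scaled inversely to the peak's expected area so every
active contributes comparable signal regardless of content (potency per
unit area differs between compounds). Signs follow orientation (+ for
viability/ATP, − for LDH/ROS). Intercepts are the injured-baseline
readouts; for LDH/ROS they are set to 3× the expected magnitude of the
subtractive peak term so all readouts stay positive. `noise_sd = 120`
against noise-free indicator SDs of roughly 300–600 is the documented
"moderate noise" operating point; zero-noise runs set it to 0 explicitly.

All randomness flows from `SimConfig.seed` through numpy's PCG64
(`default_rng`); the bioactivity stream is seeded as `[seed, 1]` so panel
and fingerprints are independently reproducible. Fixed seed ⇒ byte-identical
output files (tested).

**What the generator does not emulate.** Raw chromatogram traces, baseline
drift, co-eluting/overlapping peaks, missing peaks, UV or MS dimensions,
nonlinear dose–response, correlated assay noise between indicators, and
binding false *negatives* (every planted active is in the binding set).
Passing the recovery tests therefore shows the decision logic is correct
under the stated statistical regime — not that the screen would achieve
the same precision/recall on real HPLC and cell-assay data, where peak
identity and the linearity assumption are the dominant risks.

## Recovery behavior

Under the default configuration the pipeline recovers the planted actives
exactly (precision = recall = 1) at zero assay noise, and the acceptance
suite additionally checks mean recall ≥ 6/7 and mean precision ≥ 0.7 over
20 seeded replicates at the default noise. Leave-one-out classification of
the BP network recovers all actives on the probed seeds under low noise.
These are statements about the generator's regime; margins shrink if the
active-family co-variation is reduced, and with `active_log_sd = 0`
individual actives can fall below the VIP threshold at n = 12 batches.

## Degenerate inputs and tie-breaks (summary)

Empty peak-table file → valid empty table; non-positive area → validation
error with file/line; zero-mean or constant series under mean/min–max
normalization → explicit error; Δmax = 0 → grades 1.0 + warning; constant
feature column → scaled to 0 + warning; equidistant RT ties → earlier
eluter; BP output 0.5 → inactive; thresholds are strict inequalities.
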