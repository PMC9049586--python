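# Methods

## Model

The package implements a single-compartment, deterministic mass-action
model of the conventional/novel PKC life cycle. One protein moiety pool
is tracked through twelve dynamical species — the transcript and its
polyribosome-loaded form, the naive enzyme, the PDK1 encounter complex,
the activation-loop-phosphorylated form, its mTORC2-bound form, two
autophosphorylation complexes, the mature stored form
(C·PKC·Pᴬ·Pᴴ·Pᵀ, "M"), the membrane-active form ((PKC·Pᴬ·Pᴴ·Pᵀ)ᴬ,
"A*"), the dephosphorylated-but-active form (PKCᴬ, "D"), and the HSP70
rescue complex C5. Six partners are chemostatted (polyribosome T, PDK1,
mTORC2, the activator, PHLPP, HSP70): they enter rate laws at
protocol-defined levels and are never integrated, so maturation and
rescue do not deplete them. The PHLPP concentration is folded into the
pseudo-first-order dephosphorylation constant k₁₇; transient k₁₇
blocking and fractional PHLPP blocking act through the same effective
rate, k₁₇_eff(t) = k₁₇ · (1 − b) · gate(t).

Assumptions worth making explicit:

* **One activator input.** Ca²⁺/DAG and PMA are a single clamped input;
  agonist identity is encoded purely by pulse amplitude (nM). There is
  no separate irreversibility switch — at low amplitude only a small
  fraction of M is activated and nearly all of it is rescued
  (functionally reversible activation), while a saturating amplitude
  strips the mature pool faster than rescue can operate, so activation
  becomes effectively irreversible.
* **Membrane translocation is implicit.** A* "at the membrane" and M "in
  the cytosol" are distinct species of one well-mixed compartment; no
  spatial model is attempted.
* **Rescue requires a mature partner.** R12 (M + HSP70 + D ⇌ C5 → 2M +
  HSP70) makes the rescue flux proportional to the remaining mature
  pool. This single feature produces the dose-response: when
  stimulation is strong enough to empty M, the dephosphorylated form
  has no rescue partner and the pool degrades completely.
* **Slow rescue-complex turnover.** C5 releases mature enzyme at k₂₀
  (hours scale) and barely dissociates backwards (k₁₉ ≈ 0). Material
  rescued after a pulse is therefore transiently sequestered — still
  counted in total PKC (C5 carries two moieties) but unavailable for
  activation. This is what makes sequential identical pulses
  progressively less effective (10 → 7 → 5 ng/ml drops): in a
  well-mixed competition between first-order degradation of D and
  rescue proportional to M, the *relative* loss per pulse could only
  grow as the pool shrinks, so the observed adaptation requires a
  protected reservoir.

## Units and time base

Protein species are in ng/ml, the activator in nM; bimolecular constants
carry the reciprocal unit of their partner and absorb any ng/ml↔nM
conversion. The ODEs are integrated in seconds; protocols and outputs
use minutes.

## Parameters

Fixed from literature-scale anchors:

* λ₁ = λ₃ = 0.001 s⁻¹ — degradation of the naive and of the
  dephosphorylated-active enzyme (≈12 min half-life, matching the rapid
  loss of unphosphorylated/destabilized PKCα).
* λ₄ = 8·10⁻⁵ min⁻¹ = 1.333·10⁻⁶ s⁻¹ — turnover of the mature,
  fully phosphorylated form. The per-minute reading (≈6-day half-life)
  is the one consistent with a mature enzyme that persists for days and
  with total-PKC plateaus that are flat over 300–500 min simulations; a
  per-second reading of the same digits would give a 2.4 h half-life and
  visibly decaying plateaus, contradicting both.
* λ₂ = 2·10⁻⁴ s⁻¹ — the activation-loop-phosphorylated form is
  stabilized relative to the naive enzyme (5-fold slower).
* λ₅ = 0 in the base model; the dual-degradation variant adds direct
  degradation of A* (default 2·10⁻⁴ s⁻¹ in the variant scenario).

All remaining constants are calibrated (below) and shipped frozen in
`src/pkclife/data/default_params.yaml`. The clamped levels (T, PDK1,
mTORC2, PHLPP, HSP70) are dimensionless unit levels whose magnitudes are
absorbed by their bimolecular partners.

## Calibration

`pkclife.calibrate.calibrate_defaults` is a development-time, fully
deterministic staged search. The degradation rates above stay fixed;
coarse structural choices (the activation partition k₁₅/k₁₆, the rescue
strength k₁₈) were scanned on a log grid, then one knob per quantitative
anchor was refined by log-space secant iteration:

| knob | anchor | value |
|------|--------|-------|
| k₁₂ | isolated autophosphorylation half-time ≈ 7.5 min (range 5–10) | 7.51 min |
| k₃  | post-synthesis plateau of total PKC = 73 ng/ml | 73.02 |
| k₁₇ | high-dose (0.5 nM) loss ≈ 95–96% | 95.6% |
| k₁₆ | first sequential-pulse drop = 10 ng/ml | 10.00 |
| k₂₀ | third sequential-pulse drop = 5 ng/ml | 5.00 |

with the coupled trio (k₁₇, k₁₆, k₂₀) iterated to convergence. Range
anchors are then verified: maturation half-time 16.7 min (required
10–30), lowest-dose loss 1.3% (< 2%), retention under transient k₁₇
blocking 100% (≥ 99%). The high-dose loss saturates near 95.6% once the
first-pulse drop is pinned — the same rescue flux that creates the
10 ng/ml intermediate-dose drop recovers a few percent of the pool
during a saturating pulse — so the shipped value sits at that structural
ceiling rather than at an arbitrary deeper target.

Two calibration runs from the same start are bit-identical (no
randomness anywhere in the package at runtime).

## Numerics

Within a protocol segment every effective rate is constant, so each
segment is integrated separately (LSODA with analytic Jacobian,
rtol 10⁻⁸, atol 10⁻¹²) and the integrator restarts at every pulse/window
edge; no step straddles a parameter jump. The reporting grid (default
0.5 min) always contains the protocol discontinuities and t_end exactly.
Moiety conservation with all sources/sinks zeroed holds to < 10⁻⁶
relative over the longest scenario; halving the grid and tightening rtol
tenfold changes the total-PKC series by < 10⁻⁴ relative.

Degenerate inputs: an all-zero state is stationary; a protocol without a
synthesis pulse keeps every protein species at zero; pulses of zero
amplitude are legal (flux 0); overlapping activator pulses are rejected
at protocol construction.

## Operational definitions of the observables

The measurement procedures behind the reported numbers are not defined
by the source experiments, so the package fixes them:

* **plateau** — mean over a window in which every finite-difference
  slope is below a guard (default 10⁻³ ng/ml/min; scenarios pass
  0.02–0.05 ng/ml/min to accommodate the slow λ₄ turnover of a ≈73 ng/ml
  pool, which is ≈6·10⁻³ ng/ml/min).
* **pre-activation plateau** — window 40–50 min, after maturation is
  complete and before the 50-min activator pulse.
* **half-time** — first linearly-interpolated crossing of half the
  plateau.
* **drop after a pulse** — plateau over the 10 min before pulse onset
  minus plateau over a 10-min window starting 50 min after pulse end (by
  then A* has drained and D has decayed, so the step is fully settled
  before the next event at the 170/140-min pulse spacing).
* **down-regulation** (loss/retention) — measured against a
  time-matched synthesis-only control run, final totals averaged over
  the last 10 min. Using the control rather than the pre-pulse plateau
  scalar keeps the metric independent of the basal λ₄ drift over
  multi-hour protocols; the absolute plateau and finals are reported
  alongside.
* **degree of reversal** (second-synthesis experiment) — final total
  with the extra synthesis pulse divided by the final total of a
  double-synthesis, no-activator control (restoration completeness).

## Sensitivity analysis

Strictly one-at-a-time: each parameter ×5 and ×0.1, all others at
baseline, under a low- (0.0005 nM) and a high-intensity (0.5 nM)
protocol. Effect = max over time of |Δ total PKC| normalized by the
baseline maximum; classes high ≥ 0.5, moderate ≥ 0.05, insensitive
below — thresholds are documented heuristics, not physical constants.
Under the shipped defaults the top tier is {k₃, λ₃, T, k₁} with k₁₇ at
0.45, just under the "high" cut; the fast equilibrium constants
(k₂, k₅, k₆, k₈–k₁₃) are insensitive. Compared with the reference
qualitative map, k₁₅ and k₁₇ rank one tier lower here and k₇/k₁₄ one
tier higher; with the measurement thresholds unpublished, this
comparison is reported as warnings by the test suite rather than
asserted.

## What the scenarios do and do not show

The scenario suite reproduces the *in-silico* experiment set: a
dose-response (0.0005–0.5 nM), a duration sweep at the lowest dose
(15–316.66 min), transient k₁₇ blocking during three saturating pulses,
three sequential intermediate pulses, HSP70 overexpression (1–200×),
fractional PHLPP blocking (0–100%), a second synthesis pulse at
83.33 min, and the dual-degradation variant. Passing these shows the
model reproduces the published qualitative behaviour and printed numeric
anchors under the shipped calibration; it does not validate the rate
constants against measured time courses — most are unconstrained beyond
the anchors, and other parameter sets could fit the same anchors.

## Known limitations

* Single compartment; membrane/cytosol translocation, scaffold
  interactions and isoform-specific cofactors are out of scope.
* The activator is clamped, not generated by upstream PIP₂/PLC
  signalling; transcription of PKC is not modelled.
* HSP70 is a fixed level (no feed-forward induction by phorbol esters),
  and the rescue stoichiometry treats HSP70 catalytically.
* The calibrated activation constants (k₁₅, k₁₆) are effective, not
  measured, and absorb unit conversions; their absolute magnitudes
  should not be interpreted mechanistically.
* The sensitivity classification depends on the chosen thresholds and
  effect metric; only the relative ranking is meaningful.
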