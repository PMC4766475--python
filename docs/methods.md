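# Methods

## The model

An RR record is a sequence of M beat-to-beat intervals {X_i}. The analysis
views each run of N consecutive beats as a point in an N-dimensional
Poincaré map and asks how far it sits from the *identity line*
{1, …, 1}·t, the locus of zero beat-to-beat variability. Two filtration
levels make this comparable across subjects and activity levels:

1. **Circadian filtration** — the whole record is divided by its mean,
   x_i = X_i / X̄, removing the subject's average rate (and, with it, units
   and any global rescaling of the record).
2. **Local filtration** — for each window i the order-N forward moving
   average ⟨x⟩_i = (1/N) Σ_{k=0}^{N−1} x_{i+k} is subtracted:

       Δ_{i,k} = x_{i+k} − ⟨x⟩_i,   k = 0..N−1,  i = 1..M−N+1.

   The locally normalized variant is δ_{i,k} = Δ_{i,k} / ⟨x⟩_i.

Subtracting the window mean is identical to removing the orthogonal
projection onto the identity direction u = (1, …, 1)/√N, i.e.
Δ_i = p − (p·u)u with p the normalized window; both presentations of the
definition coincide, and the test suite asserts this equivalence against
an explicit projection-residual oracle. Every Δ (and δ) row therefore sums
to zero — the *closure* property — so the field lives on a fixed
(N−1)-dimensional hyperplane and the last component is redundant. Closure
is enforced as a post-hoc assertion (tolerance 1e−12) rather than by
re-projection: the formula closes analytically, and the assertion exists
to catch implementation drift. One numerical concession is made at
ingest: an exactly constant record normalizes to exact ones, bypassing
division rounding so its field is exactly zero rather than
O(machine-epsilon) dust.

For N = 5 the truncated field is 4-dimensional and is rendered as a 3D
scatter plus a 0–1 hue code for the fourth component (hue scaling:
symmetric clip at ±max|component|, then affine to 0–1 — the color code is
specified but not its scaling, so the symmetric choice is ours). The
published figures use a view angle that collapses the main structures to
three lines; that camera is not stated numerically, so
`hf_view_projection` *derives* a deterministic rotation from the catalog
geometry (line of sight along the mean of the three canonical B1-family
directions, det = +1); a user-supplied rotation overrides it.

## Primary variability Φ_N

Averaging all M−N+1 overlapping Δ vectors undercounts variability: each
interval X_i reappears in N−1 windows and produces an improper global
compensation. Φ_N therefore averages only the stride-N subset
i = {1, 1+N, 1+2N, …}, in which each beat contributes once:

    Φ_N = scale_factor · ‖ mean_{i ∈ stride} Δ_i ‖.

Choices and their rationale:

- **scale_factor = 100** (percent-like reporting). The construction — norm
  of the strided center of mass — is fixed; the absolute scale is a
  reporting convention and is exposed in configuration.
- **Full-N norm** by default: closure makes it well defined and
  rotation-free; a `truncated=True` variant (first N−1 components) exists
  for fidelity experiments and is never larger.
- **Stride phase**: the subset starts at the first window; no averaging
  over the N possible offsets (a deliberate literal reading — offset
  averaging is a robustness experiment, not the definition).
- **M_cap**: cohort-comparable Φ values should use a fixed record length;
  the CLI exposes `--max-beats 4200` and shorter records are used whole.
- Records must satisfy M ≥ 2N so the strided subset holds at least two
  windows.

Order scans recompute Φ_N independently per order, skip invalid orders
(N < 2 or N > M/2) with a logged warning, and break argmin ties toward the
smallest N.

## The line catalog

Each arrhythmic sequence is a unit direction A in Δ space; an actual event
of that kind lies at A·t for some amplitude t, independent of heart rate.
A line is *compensated* when its components sum to zero and *terminated*
when its last component is zero. Constructions (any order N):

| family | direction (∝) | meaning |
|---|---|---|
| A1± | (N−1, N−3, …, −(N−1)), ± | linear ramp; + = accelerating rate (RR shrinking) |
| A2± | sin(2πk/N), k = 0..N−1, ± | full-period breath-coupled modulation |
| B1 | −1 at i, +1 at i+1, else 0 | premature beat then compensatory pause |
| B2 (family m) | (m, −1×m, 0), order m+2 | pause then m proportionally faster beats |
| B3_{m,i} | pause m moved to interior position i | junction of two pause-tachycardia runs |
| SHADOW_{m,i} | (−(i+1))×(m+1−i) then (m+1−i)×(i+1) | partial-overlap trace of a B2 event |

Conventions worth stating:

- **Orientation matters**: a line and its negation are distinct entries
  (acceleration vs deceleration, ectopic-pair order); B1 is fixed as
  (short, long).
- **Canonical B1 position** is the interior pair at 0-based positions
  (N−3, N−2) — (0, 0, −1, 1, 0) at N = 5; other interior positions are
  named variants. The split variant (1, 0, …, 0, −1) is constructible but
  excluded from the default signature: real records put more than two
  quiet beats around an ectopic pair, so it does not clearly appear.
- **A2 phase** starts at 0; a phase offset parameter exists because the
  zero-sum property holds for any phase over a full period.
- **B2 cross-order**: the compensated pause-tachycardia form natively
  belongs to the order-6 section even when the rest of the signature uses
  N = 5. The default signature evaluates B2 on a second, order-6 field of
  the same record; a `fragments` policy instead evaluates the two order-5
  fragment directions a sliding window traces over the canonical event.
- **Shadows** are our own geometric construction (the Δ directions of
  windows partially overlapping a pause-tachycardia run — the "shadows"
  that accompany B2 lines in real graphs); they are catalog entries only
  and are given no quantitative analysis. The catalog serializes to JSON
  so an alternative transcription of any family can be loaded without
  code change.

## Presence detection

The generalized angle between a window and a line is computed on the first
N−1 components (the line's truncated direction renormalized), is
orientation-sensitive, and a window matches when cos θ ≥ cos θ̃. Counting
follows: measure θ around each window, count matches m, report

    presence = 100 · m (N−1) / (M − N)   [percent of beats covered].

- **Tolerance default cos θ̃ = 0.98**, fully exposed in configuration.
- **Quiescence threshold** ε = 1e−6 on the truncated window norm: the
  angle of a near-zero vector is numerically meaningless, so such windows
  are non-evaluable and never matched.
- **Overlap suppression (default on)**: one isolated event yields several
  near-matching overlapping windows; since the (N−1) factor already
  converts event counts to beat coverage, m should count events, so a
  match at window i makes windows i+1..i+N−1 ineligible for that line.
  `suppress_overlap=False` gives the literal every-window count.
- **Amplitude floor** (default 0 = off) can reject noise-level alignments.
- Windows are every window start (no striding), matching the counting
  procedure's "around each beat" reading.

A known geometric property at the default tolerance: an isolated positive
deviation — an ectopic pair's compensatory pause, or the slow end of a
decelerating ramp — lies within cos θ ≈ 0.9966 of the truncated B2
direction in the order-6 field ((5,−1,−1,−1,−1)·(4,−1,−1,−1,−1)/norms =
24/√580), so such events each register one B2 match. This is a property
of the method's geometry, not an artifact; recovery tests therefore
validate each template kind on its own record and native line.

## Synthetic generator

The generator defines the study conditions for all tests:

- Baseline RR_i = mean_rr · (1 + noise_i + resp_i) with mean_rr = 0.8 s
  (75 bpm), AR(1) multiplicative noise (stationary sd `noise_sd`,
  lag-1 correlation `ar_coefficient` — the simplest model with tunable
  short-range correlation resembling sinus variability), and a sinusoidal
  respiratory modulation of amplitude `resp_amplitude` and period
  5.1 beats. The period is deliberately incommensurate with N = 5 so the
  strided subset's phase drifts; a period of exactly 5 would stride-lock
  and artificially inflate Φ_5.
- Events **overwrite** their beats with zero-sum templates scaled by an
  amplitude a (ectopic pair: (−a, +a); ramp: a·(L−1, L−3, …)/2;
  pause-tachycardia: (ma, −a×m); sinus burst: one sine period). Because
  templates are zero-sum and replace the local baseline, a noise-free
  record's covering window lands *exactly* on the catalog line, making
  recovery tests exact rather than statistical. The beat following an
  event is also quieted so terminated templates close exactly.
- Presets (per 3000 beats): `nsr_like` — ramps ≈ 1/250 beats (+) and
  1/350 (−), sinus bursts 1/500, ectopic pairs 1/1500, noise sd 0.025
  with correlation 0.8, respiratory amplitude 0.025; `hf_like` — ectopic
  pairs 1/60 at a = 0.3, pause-tachycardia 1/250, ramps 1/1500, noise sd
  0.035, correlation 0.5, respiration suppressed; `sd_like` — few
  ectopics but strong, long-correlated noise (sd 0.07, correlation 0.95):
  high Φ with modest B1. The rates plant the qualitative orderings seen
  across real conditions (ramp-dominated normal records, ectopy-dominated
  heart-failure records) without claiming their absolute presence values.

What the generator does **not** emulate: circadian nonstationarity,
heavy-tailed or bursty noise, beat-detection artifacts, atrial
fibrillation, or any coupling between events and the respiratory phase.
Passing tests therefore demonstrate the machinery's correctness and the
planted qualitative orderings, not clinical performance on real Holter
records.

## Problem sizes and numerical choices

The invariant sweeps use 1000 random log-normal series of 10–5000 beats at
orders 2–10; cohort checks use 20 records per group at 3000 beats;
recovery uses 8 events per template at amplitudes 0.05–0.4. Floats are
serialized with 12 significant digits and all randomness flows from
explicit integer seeds, making every report byte-reproducible. Degenerate
inputs fail loudly: non-positive intervals and non-monotone beat times
report the offending index, short records report the minimum length, and
order mismatches between a field and a cross-order line direct the caller
to rebuild the field rather than silently truncating.

## Limitations

- The absolute presence percentages and Φ magnitudes depend on the
  matching tolerance and the scale convention; only orderings and
  separations are asserted.
- B2's fragment policy and the B3/shadow constructions are geometric
  derivations consistent with the family definitions; alternative
  transcriptions can be injected via the catalog JSON interface.
- δ-field discrete-mode structure is represented (the local field is
  computed and plottable) but not analyzed further.
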