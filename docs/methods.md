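# Methods

## The model

The QD algorithm treats a treatment course as a set of paired measurements
(one pre-treatment and one post-treatment value per laboratory indicator
per patient) and asks, per indicator, three questions: which way did the
value move, how far on a ratio scale, and did the move head toward or away
from normal.

**Golden logarithm.** The ratio response is measured as
`L_tau = ln(max/min) / ln(phi)` with `phi = (1+sqrt(5))/2`. The base of the
logarithm is fixed at phi; since `ln(phi) = -ln(tau)` for the golden
section `tau = (sqrt(5)-1)/2`, a reading of the logarithm to base `1/tau`
is numerically identical, so the two natural constructions coincide and the
choice is not observable. `L_tau` is symmetric in its arguments (the max/min
ordering discards direction, which the A value carries separately), scale-
invariant, and zero iff nothing changed. Non-positive or non-finite lab
values are rejected with an error naming the indicator — never clamped —
because the logarithm is undefined there and a non-positive concentration
is a data error, not a measurement.

**Threshold schemes.** The magnitude value B buckets `L_tau` against a
scheme of strictly increasing cuts. Four built-ins are shipped:
cellular/molecular (0.80, 1.22), organ/tissue (0.47, 0.80), whole-body
(0.27, 0.47), and the three-cut molecular scheme (0.80, 1.22, 1.69) whose
cuts are read as health / subhealth / disease levels. The three-cut scheme
is the workflow default because all of the significance conventions in this
setting are phrased against the 1.69 disease cut (`L_tau > 1.69` ~ a
change a paired test also tends to flag). Boundaries are lower-inclusive
exactly as the defining inequalities state (`<= 0.80 -> 0`,
`<= 1.22 -> 1`, `<= 1.69 -> 2`, `> 1.69 -> 3`); no epsilon fuzzing is
applied at the cuts.

**Direction value A.** +1 when the post value is strictly smaller, -1 when
strictly larger. The exact-tie case is not covered by the defining
branches; it returns 0 so an unchanged indicator annihilates its product
and contributes nothing. (With continuous lab data, ties are measure-zero;
the choice only matters for rounded inputs.)

**Normal-range correction C.** The defining flowchart for this step is not
available in legible form; the implemented rule is the minimal signed
reading of "does the change represent improvement or deterioration":
`d(v) = 0` inside the reference interval, otherwise the absolute distance
to the nearer bound divided by that bound (a relative distance, so
open-ended intervals and disparate units behave comparably; an absent
bound is an open end). C = +1 if `d(post) < d(pre)` or both are 0, -1 if
`d(post) > d(pre)`, 0 if equally far outside. The rule handles full
overshoot (crossing the interval entirely) by distance alone. It is
isolated behind one function so alternatives can be swapped.

**Composition and the liver gates.** The per-indicator score is the
literal product A*B*C. Note the deliberate consequence: an indicator that
*worsens* while moving *away* from range has A = -1 and C = -1 and
contributes a positive product. That double-negative algebra is the stated
composition rule and is kept as such; the per-indicator breakdown (A, B,
C, L_tau, product) is always returned so it can be audited. The composite
score is the sum of all non-liver products plus a liver contribution from
the four-indicator panel (ALT, AST, total bilirubin, conjugated
bilirubin), gated by D = [sum of A == 4] (all four fell) and
E = [sum of B >= 9] (at least three fell past the disease cut; the
boundary 9 is inclusive). The combination rule for the gated contribution
is stated only as "added", so three rules are provided:

* `gated_sum` (default): `D*E*sum(A*B*C)` over the panel — a non-responder
  panel (any liver indicator rising) contributes exactly 0, matching the
  observed recovered-vs-died contrast pattern;
* `flat_bonus`: `D*E*k`, k configurable (default 12, the gated-sum
  maximum);
* `ungated_plus_bonus`: `sum(A*B*C) + D*E*k`.

Missing measurements are skipped and listed, never imputed; a patient with
an incomplete liver panel gets contribution 0 with the gates explicitly
marked undefined (None) and a warning.

**Reference intervals.** No intervals are prescribed by the scoring
definition, so the packaged registry (`data/registry.yaml`) ships standard
adult intervals for the 21-indicator ACLF panel as editable data. Interval
choice shifts only the C value, never A, B or the gates' D component.

**MELD comparator.** `9.57*ln(creatinine) + 3.78*ln(bilirubin) +
11.2*ln(INR) + 6.43`, creatinine and bilirubin in mg/dL (converted from
umol/L with the molar-mass factors 88.4 and 17.1; both unit paths are
supported and recorded). Inputs are floored at 1.0 by the usual convention
(switchable): without the floor, a sub-unity lab would subtract points,
contradicting the score's prognostic use. No creatinine cap and no
dialysis override — nothing beyond the printed formula is modelled.

## Synthetic cohorts

No patient-level data are deposited for this kind of study, so the
generator emulates the cohort's *statistical shape*: per indicator,
pre-treatment values are log-normal, moment-matched on the natural scale
to a configured mean/SD (packaged defaults are a two-arm 15 + 12 ACLF
summary; lab values are positive and right-skewed — several SDs exceed
their means — so normal marginals would produce negatives), and
post-treatment values follow `post = pre * m * exp(eps)`,
`eps ~ N(0, s^2)`, with `m` the expected post/pre ratio and `s` the
patient-level log-scale dispersion (default 0.3, a realistic
between-patient response spread for hepatic panels). Built-in profiles:
`dpmas_responder` and `conventional` take each packaged arm's post/pre
mean ratios (e.g. ALT 50.58/689.29 ~ 0.073 for the responder);
`non_responder` lowers the transaminases moderately but raises both
bilirubins (the pattern seen in patients who dropped out or died), which
closes the liver D gate by construction. Outcome labels attach per profile
(recovered / dropped out / died); five clinical-status flags (fatigue,
abdominal distension, anorexia, jaundice, lower-limb oedema) are drawn
improved / deteriorated-or-unchanged / absent with profile-dependent
probabilities. The default two-arm study mixes ~2/3 responders into the
15-patient artificial-liver arm and ~3/4 conventional-profile patients
into the 12-patient arm, approximating the observed outcome split.

What the generator does **not** emulate: inter-indicator correlation (a
`correlation` hook exists on the config but no covariance structure ships
— none is available to parameterise it), longitudinal trajectories,
dropout processes, or any link between the drawn lab values and the
outcome label beyond the profile. Consequently, passing tests demonstrate
that the scoring pipeline is algebraically and statistically sound under
the assumed marginal structure — not that the score is clinically valid on
real patients.

A parameter-recovery harness (`effect_recovery_check`) closes the loop:
the geometric-mean post/pre ratio per indicator estimates `m` with CLT
tolerance `m * exp(+/- z*s/sqrt(n))` (z = 3), which widens naturally —
and is reported, not raised — at small n.

Randomness is a single named stream: each patient index gets its own
`SeedSequence(entropy=seed, spawn_key=(crc32(arm), index))` sub-stream, so
enlarging a cohort never reshuffles the patients already drawn and the
same seed and config are byte-reproducible.

## Cohort statistics

The group-level QD value for an indicator is ambiguous between two
aggregations that genuinely differ — the mean of per-patient `L_tau`
values and the `L_tau` of the two group means — so both are computed and
reported side by side. Paired pre-vs-post tests default to the two-sided
paired t-test (Wilcoxon switchable); between-group contrasts default to
Welch's t (Mann-Whitney switchable); tests are reported per indicator with
no multiple-testing correction by default and a Benjamini-Hochberg switch.
The QD-vs-MELD association is a Pearson correlation with an OLS line; the
default MELD quantity is the improvement (pre minus post), the natural
comparator for a change score, with pre- and post-treatment MELD
selectable. Clinical-status-flag contrasts pool across treatment arms.
All-zero paired differences return p = 1 rather than an undefined-variance
error; a zero-variance score makes the correlation explicitly undefined
(flagged, NaN) rather than raising.

## Numerical and scale choices

* Test-suite and acceptance problem sizes: 10^4-point grids for the bucket
  rules, 10^4 random panels for gate soundness, n = 2000 for parameter
  recovery, 20 seeds at n = 15 per arm for profile separation — all sized
  so the full suite runs in well under a minute while keeping Monte-Carlo
  margins wide.
* CSV output uses pandas' repr-roundtrip float formatting; pipeline
  determinism is therefore byte-level, not just value-level.
* The on-disk format is comma-separated UTF-8 with a required header and
  decimal points; malformed rows are rejected with 1-based line numbers.

## Known limitations

* The C value and the base-phi reading of the golden logarithm are
  reconstructions of a procedure whose defining figures are not available
  in machine-readable form; both are isolated behind single functions and
  documented above.
* The double-negative product (worsening indicators scoring positive) is
  faithful to the stated algebra but clinically counter-intuitive; audit
  the breakdown before interpreting totals from deteriorating panels.
* Synthetic cohorts share none of the inter-lab correlation of real
  panels; effect sizes estimated on them transfer to real data only under
  the independence assumption.
* The MELD implementation is the original three-variable formula only (no
  sodium, no 3.0 revision, no dialysis handling).
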