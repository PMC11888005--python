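# Methods

## Scope and model

hearsim simulates a three-part hearing screen — otoscopy, tympanometry,
and fixed-level pure-tone screening audiometry — on virtual standardized
patients, for training and assessment. It deliberately models *screening*,
not diagnostic audiometry: tones are presented at a single screening level
and the outcome per ear is pass/refer, never a measured threshold.
Threshold-seeking procedures (Hughson–Westlake), masking, bone conduction
and speech audiometry are out of scope, as are rendered otoscopic images
(findings are categorical with an opaque `image_ref`), PDF export, and any
real authentication (the technician is a plain name field).

## Virtual patients

A base patient carries per-ear ground truth: integer thresholds in dB HL
(−10..120) on the device's audiometric set {250, 500, 1000, 2000, 4000,
8000} Hz, a tympanogram (peak presence; peak pressure −400..+200 daPa,
static compliance ≥ 0 mL when peaked; ear canal volume > 0 mL), and a
categorical otoscopic finding whose `is_normal` flag is true exactly for a
clear canal with intact membrane. Every case must carry thresholds at the
1000/2000/4000 Hz screening frequencies in both ears; this is enforced at
model validation so a roster cannot silently under-specify a screen.

The bundled roster has ten cases: one normal adult and one normal child,
plus eight pathologies chosen to span the modalities a screener must
integrate — occluding cerumen (flat trace, low canal volume, mild
conductive loss), bilateral otitis media with effusion (type B, conductive
loss), tympanic-membrane perforation (flat trace with large canal volume),
patent PE tubes (flat trace, large volume, normal hearing), bilateral
presbycusis (sensorineural, sloping), a noise notch at 4000 Hz, unilateral
sensorineural loss, and eustachian-tube dysfunction (type C). The
pathology selection is the package's own: it is representative of common
screening presentations, with each case's three modalities authored to be
internally consistent, and facilitators can replace it wholesale via an
external roster file.

Demographic randomization draws a name uniformly from a sex-tagged
100-name pool (tagging guarantees name and assigned sex never conflict),
jitters age by a uniform integer offset of up to ±10 % of the base age
(minimum ±1 year) clamped to the age band (children stay 4–17, adults
18–95), and re-renders the backstory template with `str.format` named
placeholders (`{name}`, `{age}`, `{pronoun_subject}`, …). Clinical fields
are carried by reference, unchanged; all randomization flows through a
single integer seed via `numpy.random.default_rng`.

## Response model

The subject's hand raise is Bernoulli with probability
`g + (1 − g − l)·σ((L − t)/s)` — a guess/lapse-adjusted logistic, the
standard psychometric form. `s = 0` degenerates to a step with the tie
broken toward responding (a threshold is by definition the lowest audible
level, so a tone *at* threshold is heard). Defaults are `s = g = l = 0`
(fully deterministic); the presbycusis case ships with `s = 3` dB,
`g = l = 0.02` to exercise the response inconsistency screeners meet in
practice. The magnitude is illustrative — chosen so that responses are
unreliable only within roughly ±10 dB of threshold, far from the 20 dB HL
screening level for that case's 25–65 dB HL thresholds, which keeps
scripted protocol outcomes effectively deterministic while making repeated
near-threshold presentations visibly inconsistent. Ground truth never
consults simulated draws, so grading is stable regardless.

## Protocol, ground truth and referral

Defaults: screening level 20 dB HL; required frequencies 1000/2000/4000
Hz; both ears; procedure order otoscopy → tympanometry → audiometry
enforced as a warning. The device accepts −10..90 dB HL in 5 dB steps.
An ear's audiometry refers iff any required-frequency threshold exceeds
the screening level; no rescreen-before-refer step is modeled (a
deliberate simplification — rescreen mechanics belong to the trainee's
protocol knowledge, not the device) though repeated presentations are
logged and tallied.

Tympanograms are typed from the stored parameters: no peak → B; peak below
the normative pressure minimum → C; otherwise A/As/Ad by compliance
within/below/above the normative range. Screening result is abnormal iff
type B or C or the ear canal volume leaves the age band's range; As/Ad
alone do not refer — at screening they are a depth note, not a referral
trigger. Normative defaults (pressure −150..+100 daPa, compliance 0.3..1.5
mL, ECV 0.4..1.0 mL child / 0.6..2.0 mL adult) are conventional values and
live in an external config.

The disposition map is exact over the 2×2 flag table: medical flag = any
otoscopy or tympanometry abnormality → physician; audiologic flag = any
audiometric refer → audiologist; both → both; neither → pass.

## Sessions, auditing, grading

Every trainee action appends a timestamped event; timestamps come from an
injectable clock (wall clock by default, a deterministic `ManualClock` in
tests and examples), so durations are testable. Testing duration runs from
the first exam or tone to session close; total duration from session
start. The event log plus seed is a sufficient statistic: `replay`
re-executes a log against a fresh session and reproduces every outcome,
including stochastic responses. Inline arguments to exam calls set the
selectors without logging separate selection events, so logs stay compact
and replay is exact.

The compliance auditor emits at most one finding per independent
deviation, using a suppression hierarchy: a procedure never run is one
`MISSING_PROCEDURE` (its per-ear gaps are subsumed); a procedure missing
one ear is one `EAR_NOT_TESTED` per ear (subsuming that ear's
per-frequency gaps); otherwise audiometry gaps surface per (ear,
frequency) as `MISSING_FREQUENCY` (no tone at all) or `WRONG_LEVEL` (tones
presented, none at the screening level). `OUT_OF_ORDER` is
warning-severity, on the view that order deviations are coaching points
rather than invalid sessions; `INCOMPLETE_NOTES` fires once per empty note
slot. The one-finding-per-mutation design makes audit output countable in
debriefs and is property-tested by planting single deviations in an
otherwise compliant script.

Grading scores seven equally weighted items — six per-ear results plus the
final recommendation — as exact matches against ground truth; missing
answers are wrong and flagged missing, free-text comments are displayed
but never scored (no defensible rubric for auto-scoring prose). Reports
render as loss-free JSON (round-trips through the model) or markdown.

The session store is line-delimited JSON behind a small class: append-only,
duplicate-id-checked, human-diffable, with per-student chronological
history and cohort aggregates (mean score and durations, per-item error
rates as the fraction of sessions grading each slot incorrect, sessions
per case). The JSONL choice keeps the artifact dependency-free; the class
boundary allows a database backend later.

## Validation approach and problem sizes

Formats are validated with pydantic models; the same models export JSON
Schema documents for external tooling. Tests check rule logic against
independent oracles: the referral map against brute-force enumeration of
all 64 per-ear result combinations, tympanogram typing against a separate
rule-table evaluation over a dense parameter grid (≈4700 points including
the ±1-unit boundary neighbourhoods), cohort aggregates against
hand-recounted planted-error fixtures, and the Monte-Carlo response rate
(10,000 draws) against the analytic curve. Property tests (hypothesis,
derandomized) cover psychometric monotonicity; randomization invariance is
checked over 100 seeds per case and replay fidelity over the full roster.
The whole suite uses the bundled ten-case roster and runs in a few seconds.

## Known limitations

Simulated subjects respond tone-by-tone independently; real subjects show
serial effects (fatigue, learning) the model omits. The roster's
pathology identities and normative ranges are configuration, not clinical
authority — deployments should review them against local guidelines. A
passing suite shows the engine's rules behave as specified on authored
cases; it says nothing about training efficacy with real students, which
requires a human study.
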