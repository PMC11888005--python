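# hearsim

A headless, scriptable hearing-screening simulator for training and
assessing screening technique. It is aimed at health-professions educators
and tool builders: students practice the standard three-part screen —
otoscopy, tympanometry, and fixed-level pure-tone screening audiometry — on
virtual standardized patients, and the simulator grades their results
against known ground truth, audits their procedure against the protocol,
and logs every session for individual and cohort reporting.

## The model

Each **base patient** is an authored clinical case with per-ear ground
truth: pure-tone thresholds by frequency (dB HL), tympanometry parameters
(peak pressure in daPa, static compliance and ear canal volume in mL), and
an otoscopic finding. Before each session the case is **demographically
randomized** — new name (from a 100-name sex-tagged pool), sex, slightly
jittered age, re-rendered backstory — so repeat trainees cannot memorize
answers; the 10-case roster times the 100-name pool yields 1000 distinct
identities before age variants.

Screening is fixed-level: tones at 20 dB HL at 1000, 2000 and 4000 Hz per
ear. The simulated subject raises a hand according to a psychometric
function of the presentation level *L* relative to the ear's threshold *t*:

  p(L) = g + (1 − g − l) · σ((L − t)/s)

with guess rate *g*, lapse rate *l*, and slope *s* (dB); *s* = 0 gives the
deterministic step "respond iff L ≥ t". Ground truth is derived from
thresholds, never from draws: an ear *refers* iff any required-frequency
threshold exceeds the screening level. Tympanograms are typed A/As/Ad/B/C
from peak presence, peak pressure and compliance against normative ranges;
B, C, or an out-of-range ear canal volume refer. The final disposition maps
the medical flag (any otoscopy/tympanometry abnormality) and the audiologic
flag (any audiometric refer) to pass / refer to audiologist / refer to
physician / refer to both.

Sessions run against a device state machine (ear, level, frequency
selectors; Oto/Tymp buttons; tone presentation) that appends every action
to a timestamped event log. The log plus the session seed replays exactly,
and a compliance auditor reads it to flag missed procedures, untested ears,
skipped frequencies, off-level presentations, out-of-order procedures, and
incomplete notes. Grading scores seven equally weighted items: the six
per-ear results plus the final recommendation.

## Worked example

```bash
python examples/02_scripted_screening.py
```

runs an ideal scripted screening of the child with bilateral otitis media
with effusion and prints the debrief report, including:

```
## Results — score 7/7 (1.000)

| Item | Your answer | Correct answer | Graded |
|---|---|---|---|
| Otoscopy (left) | abnormal | abnormal | correct |
...
| Audiometry (left) | refer | refer | correct |
| Final recommendation | refer_both | refer_both | correct |

## Protocol compliance

Session was fully compliant with the screening protocol.

Tone presentations: 6 (0 positive responses).
```

Score 7/7 means all six per-ear calls and the final recommendation matched
ground truth; zero positive responses out of six tones reflects the case's
30–35 dB HL conductive loss against the 20 dB HL screening level. The other
examples show roster randomization (`01`), compliance auditing of a
shortcut-taking session (`03`), and the session store with student history
and cohort summaries (`04`).

A command-line interface wraps the same library:

```bash
hearsim list-patients --reveal
hearsim run --student "Ada" --patient p01_adult_normal \
    --actions src/hearsim/data/demo_actions.json --seed 5
hearsim history --student "Ada"
hearsim cohort
```

Rosters, protocols, normative ranges, name pools and scripted sessions are
all external JSON files (`hearsim schemas` exports their JSON Schemas), so
new cases and site-specific protocols need no code changes.

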