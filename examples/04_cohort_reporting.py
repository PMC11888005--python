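"""Store several graded sessions and print student and cohort reports.

Two students each screen two cases; every session record is appended to a
JSONL store, then queried for an individual history and a cross-sectional
cohort summary (mean score, per-item error rates, sessions per case).
"""

import json
import tempfile
from pathlib import Path

from hearsim import (
    ManualClock,
    SessionStore,
    audit_session,
    build_report,
    default_name_pool,
    default_roster,
    derive_ground_truth,
    randomize_presentation,
    record_from_session,
    run_script,
    start_session,
)
from hearsim.trainee import notes_from_observations, protocol_actions

roster = default_roster()
pool = default_name_pool()
store = SessionStore(Path(tempfile.mkdtemp()) / "sessions.jsonl")

for student, case_ids in [("Student A", ["p01_adult_normal", "p09_unilateral"]),
                          ("Student B", ["p04_ome_child", "p08_noise_notch"])]:
    for i, case_id in enumerate(case_ids):
        base = next(p for p in roster if p.id == case_id)
        session = start_session(student, randomize_presentation(base, pool, seed=i),
                                seed=i, clock=ManualClock(t0=1000.0 * i))
        run_script(session, protocol_actions(), close=False)
        notes = notes_from_observations(session)
        if student == "Student B" and case_id == "p08_noise_notch":
            # plant one mistake: call the noise-notch audiogram a pass
            notes = notes.model_copy(update={
                "audiometry_left": type(notes.audiometry_left)(result="pass"),
            })
        session.save_notes(notes)
        session.close()
        report = build_report(session, derive_ground_truth(base), audit_session(session))
        store.append(record_from_session(session, report))

print("Student A history:")
for row in store.student_history("Student A"):
    print(f"  {row['base_id']}: score {row['score']:.3f}")

print("\nCohort summary:")
print(json.dumps(store.cohort_summary(), indent=2))
print("\nerror_rate.audiometry_left = 0.25: one of four stored sessions graded")
print("that slot wrong (Student B's planted mistake).")
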