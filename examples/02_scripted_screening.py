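"""Run one complete scripted screening and print the debrief report.

An ideal trainee screens the child with bilateral otitis media with
effusion: otoscopy and tympanometry on both ears, then 20 dB HL tones at
1000/2000/4000 Hz per ear. The child misses every tone (thresholds are
30-35 dB HL), the tympanograms are flat (type B), and the correct
disposition is referral to both a physician and an audiologist.
"""

from hearsim import (
    ManualClock,
    audit_session,
    build_report,
    default_name_pool,
    default_roster,
    derive_ground_truth,
    randomize_presentation,
    render_report,
    run_script,
    start_session,
)
from hearsim.trainee import notes_from_observations, protocol_actions

base = next(p for p in default_roster() if p.id == "p04_ome_child")
presentation = randomize_presentation(base, default_name_pool(), seed=42)

session = start_session("Example Student", presentation, seed=42, clock=ManualClock())
run_script(session, protocol_actions(), close=False)
session.save_notes(notes_from_observations(session))
session.close()

truth = derive_ground_truth(base)
report = build_report(session, truth, audit_session(session))
print(render_report(report, "markdown"))
print("Score 7/7 means the trainee's six per-ear results and final")
print("recommendation all matched the derived ground truth.")
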