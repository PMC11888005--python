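"""Audit a shortcut-taking session against the screening protocol.

The trainee skips the 4000 Hz tone in the right ear and presents the left-
ear tones at 30 dB HL instead of the 20 dB HL screening level. The auditor
reads the event log and reports each deviation with a machine-readable
code, plus tallies of presentations and positive responses.
"""

from hearsim import (
    audit_session,
    default_name_pool,
    default_roster,
    randomize_presentation,
    run_script,
    start_session,
)
from hearsim.trainee import notes_from_observations, protocol_actions

actions = []
for step in protocol_actions():
    if step["action"] == "present_tone":
        params = step["params"]
        if params["ear"] == "right" and params["frequency"] == 4000:
            continue  # shortcut: frequency skipped
        if params["ear"] == "left":
            params["level"] = 30  # wrong level
    actions.append(step)

base = default_roster()[0]
session = start_session("Hasty Student", randomize_presentation(base, default_name_pool(), 7), seed=7)
run_script(session, actions, close=False)
session.save_notes(notes_from_observations(session))
session.close()

result = audit_session(session)
print(f"compliant: {result.compliant}")
for finding in result.findings:
    print(f"  [{finding.severity}] {finding.code.value}: {finding.detail}")
print(f"tone presentations: {result.presentations}")
print(f"positive responses: {result.positive_responses}")
print("\nThe wrong-level tones also leave the ideal trainee unable to call the left")
print("ear, so incomplete-notes findings follow; a clean session prints compliant: True.")
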