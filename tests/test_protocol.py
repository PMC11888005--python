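"""Tympanogram typing, referral logic, ground truth and compliance audit."""

import itertools

import pytest

from hearsim import (
    FindingCode,
    NormativeRanges,
    ProtocolConfig,
    Recommendation,
    TympanogramProfile,
    TympType,
    audit_session,
    check_compliance,
    classify_tympanogram,
    derive_ground_truth,
    randomize_presentation,
    recommend,
)
from hearsim.patients import AgeBand
from hearsim.trainee import protocol_actions

from conftest import run_compliant_session


# -- tympanogram classification --------------------------------------------

@pytest.mark.parametrize(
    "profile_kw, band, expected",
    [
        (dict(peak_present=True, peak_pressure_dapa=-50, static_compliance_ml=0.8,
              ear_canal_volume_ml=1.2), "adult", (TympType.A, "normal")),
        (dict(peak_present=False, ear_canal_volume_ml=3.0), "adult", (TympType.B, "abnormal")),
        (dict(peak_present=True, peak_pressure_dapa=-250, static_compliance_ml=0.5,
              ear_canal_volume_ml=1.0), "adult", (TympType.C, "abnormal")),
        # shallow and deep peaks alone do not refer at screening
        (dict(peak_present=True, peak_pressure_dapa=-20, static_compliance_ml=0.1,
              ear_canal_volume_ml=1.0), "adult", (TympType.As, "normal")),
        (dict(peak_present=True, peak_pressure_dapa=-20, static_compliance_ml=2.0,
              ear_canal_volume_ml=1.0), "adult", (TympType.Ad, "normal")),
        # normal trace but out-of-band ear canal volume still refers
        (dict(peak_present=True, peak_pressure_dapa=-20, static_compliance_ml=0.8,
              ear_canal_volume_ml=1.5), "child", (TympType.A, "abnormal")),
    ],
)
def test_classification_examples(profile_kw, band, expected):
    profile = TympanogramProfile(**profile_kw)
    assert classify_tympanogram(profile, AgeBand(band)) == expected


def _oracle_classify(peak_present, pressure, compliance, ecv, band, norms):
    """Independent rule-table evaluation of the classification scheme."""
    if not peak_present:
        ttype = "B"
    elif pressure < norms.peak_pressure_dapa.min:
        ttype = "C"
    elif compliance < norms.static_compliance_ml.min:
        ttype = "As"
    elif compliance > norms.static_compliance_ml.max:
        ttype = "Ad"
    else:
        ttype = "A"
    ecv_range = norms.ear_canal_volume_ml[band]
    abnormal = ttype in ("B", "C") or not (ecv_range.min <= ecv <= ecv_range.max)
    return ttype, "abnormal" if abnormal else "normal"


def test_classification_matches_rule_table_on_dense_grid(norms):
    pressures = [-400, -250, -151, -150, -149, -50, 0, 100, 200]
    compliances = [0.0, 0.29, 0.3, 0.31, 0.8, 1.5, 1.51, 3.0]
    ecvs = [0.1, 0.4, 0.6, 0.9, 1.0, 1.5, 2.0, 2.1, 3.5]
    n = 0
    for band in AgeBand:
        for ecv in ecvs:
            profile = TympanogramProfile(peak_present=False, ear_canal_volume_ml=ecv)
            got = classify_tympanogram(profile, band, norms)
            want = _oracle_classify(False, None, None, ecv, band, norms)
            assert (got[0].value, got[1]) == want
            n += 1
            for pressure, compliance in itertools.product(pressures, compliances):
                profile = TympanogramProfile(
                    peak_present=True, peak_pressure_dapa=pressure,
                    static_compliance_ml=compliance, ear_canal_volume_ml=ecv,
                )
                got = classify_tympanogram(profile, band, norms)
                want = _oracle_classify(True, pressure, compliance, ecv, band, norms)
                assert (got[0].value, got[1]) == want
                n += 1
    assert n == 2 * 9 * (1 + 9 * 8)


# -- referral logic ----------------------------------------------------------

def test_recommend_exhaustive_two_by_two():
    """Brute-force every per-ear result combination against the flag map."""
    seen = {}
    for oto_l, oto_r, tymp_l, tymp_r, aud_l, aud_r in itertools.product(
        ("normal", "abnormal"), ("normal", "abnormal"),
        ("normal", "abnormal"), ("normal", "abnormal"),
        ("pass", "refer"), ("pass", "refer"),
    ):
        medical = "abnormal" in (oto_l, oto_r, tymp_l, tymp_r)
        audiologic = "refer" in (aud_l, aud_r)
        expected = {
            (False, False): Recommendation.passed,
            (False, True): Recommendation.refer_audiologist,
            (True, False): Recommendation.refer_physician,
            (True, True): Recommendation.refer_both,
        }[(medical, audiologic)]
        got = recommend(
            {"left": oto_l, "right": oto_r},
            {"left": tymp_l, "right": tymp_r},
            {"left": aud_l, "right": aud_r},
        )
        assert got == expected
        seen[(medical, audiologic)] = got
    assert len(set(seen.values())) == 4


def test_recommend_rejects_missing_or_invalid_results():
    ok = {"left": "normal", "right": "normal"}
    with pytest.raises(ValueError, match="missing"):
        recommend({"left": "normal"}, ok, {"left": "pass", "right": "pass"})
    with pytest.raises(ValueError, match="invalid"):
        recommend(ok, ok, {"left": "maybe", "right": "pass"})


# -- ground truth ------------------------------------------------------------

def test_ground_truth_examples(roster_by_id, truth_for):
    truth = truth_for(roster_by_id["p01_adult_normal"])
    assert truth.recommendation == Recommendation.passed
    assert set(truth.audiometry.values()) == {"pass"}

    truth = truth_for(roster_by_id["p09_unilateral"])
    assert truth.audiometry == {"left": "refer", "right": "pass"}
    assert truth.recommendation == Recommendation.refer_audiologist

    truth = truth_for(roster_by_id["p04_ome_child"])
    assert truth.tymp_types == {"left": TympType.B, "right": TympType.B}
    assert truth.recommendation == Recommendation.refer_both


def test_threshold_at_screening_level_passes(roster_by_id, truth_for):
    # p10's right ear has a 20 dB HL threshold at 2000 Hz: equal to the
    # screening level means the tone is heard, so the ear passes
    truth = truth_for(roster_by_id["p10_etd"])
    assert truth.audiometry["right"] == "pass"
    assert truth.recommendation == Recommendation.refer_physician


def test_truth_invariant_under_demographic_randomization(roster, name_pool, protocol, norms):
    for base in roster:
        expected = derive_ground_truth(base, protocol, norms)
        for seed in range(20):
            pres = randomize_presentation(base, name_pool, seed)
            assert derive_ground_truth(pres.base, protocol, norms) == expected


def test_custom_screening_level_changes_truth(roster_by_id, norms):
    # at a 40 dB HL cutoff the OME child's 30-35 dB thresholds all pass
    lenient = ProtocolConfig(screening_level=40)
    truth = derive_ground_truth(roster_by_id["p04_ome_child"], lenient, norms)
    assert set(truth.audiometry.values()) == {"pass"}
    assert truth.recommendation == Recommendation.refer_physician


# -- compliance audit --------------------------------------------------------

def test_full_protocol_session_is_fully_compliant(roster, name_pool, protocol):
    session = run_compliant_session(roster[0], name_pool, seed=11)
    result = audit_session(session, protocol)
    assert result.compliant
    assert result.findings == []
    assert result.positive_responses == 6  # normal adult hears all 6 tones
    assert result.presentations == {
        f"{ear}@{freq}": 1 for ear in ("left", "right") for freq in (1000, 2000, 4000)
    }
    assert result.exams == {"otoscopy": 2, "tympanometry": 2, "audiometry": 6}


def _mutations(protocol):
    """(name, action-filter, expected finding code/detail fragment)."""
    def drop(pred):
        return lambda actions: [a for a in actions if not pred(a)]

    return [
        ("omit_right_4000", drop(
            lambda a: a["action"] == "present_tone"
            and a["params"]["ear"] == "right" and a["params"]["frequency"] == 4000),
         FindingCode.MISSING_FREQUENCY, "4000 Hz in the right ear"),
        ("omit_left_otoscopy", drop(
            lambda a: a["action"] == "oto_exam" and a["params"]["ear"] == "left"),
         FindingCode.EAR_NOT_TESTED, "otoscopy not performed on the left"),
        ("omit_all_tymp", drop(lambda a: a["action"] == "tymp_exam"),
         FindingCode.MISSING_PROCEDURE, "tympanometry"),
        ("omit_all_audio", drop(lambda a: a["action"] == "present_tone"),
         FindingCode.MISSING_PROCEDURE, "audiometry"),
    ]


@pytest.mark.parametrize("name, mutate, code, fragment",
                         [pytest.param(*m, id=m[0]) for m in _mutations(None)])
def test_single_mutation_yields_exactly_one_finding(roster, name_pool, protocol, norms,
                                                    name, mutate, code, fragment):
    actions = mutate(protocol_actions(protocol))
    session = run_compliant_session(roster[0], name_pool, seed=11,
                                    protocol=protocol, norms=norms, actions=actions)
    # complete the notes independently so only the planted deviation remains
    from conftest import notes_from_truth
    session.notes = notes_from_truth(derive_ground_truth(roster[0], protocol, norms))
    result = check_compliance(session.event_log, session.notes, protocol)
    assert len(result.findings) == 1, [f.detail for f in result.findings]
    assert result.findings[0].code == code
    assert fragment in result.findings[0].detail


def test_wrong_level_detected_per_frequency_set(roster, name_pool, protocol):
    actions = protocol_actions(protocol)
    for action in actions:
        if action["action"] == "present_tone":
            action["params"]["level"] = 30
    session = run_compliant_session(roster[0], name_pool, seed=11, actions=actions)
    result = audit_session(session, protocol)
    wrong = [f for f in result.findings if f.code == FindingCode.WRONG_LEVEL]
    assert len(wrong) == 6  # one per (ear, frequency) pair, none at 20 dB HL


def test_out_of_order_is_a_single_warning(roster, name_pool, protocol):
    actions = protocol_actions(protocol)
    # move audiometry tones before the otoscopy/tympanometry exams
    tones = [a for a in actions if a["action"] == "present_tone"]
    rest = [a for a in actions if a["action"] != "present_tone"]
    session = run_compliant_session(roster[0], name_pool, seed=11, actions=tones + rest)
    result = audit_session(session, protocol)
    assert [f.code for f in result.findings] == [FindingCode.OUT_OF_ORDER]
    assert result.findings[0].severity == "warning"
    relaxed = ProtocolConfig(enforce_order=False)
    assert check_compliance(session.event_log, session.notes, relaxed).compliant


def test_incomplete_notes_flagged_per_missing_slot(roster, name_pool, protocol):
    session = run_compliant_session(roster[0], name_pool, seed=11)
    partial = session.notes.model_copy(update={"tympanometry_left": type(session.notes.tympanometry_left)()})
    result = check_compliance(session.event_log, partial, protocol)
    assert [f.code for f in result.findings] == [FindingCode.INCOMPLETE_NOTES]
    assert "tympanometry left" in result.findings[0].detail


def test_unclosed_session_cannot_be_audited(roster, name_pool, protocol):
    from hearsim import randomize_presentation, start_session

    pres = randomize_presentation(roster[0], name_pool, seed=1)
    session = start_session("S", pres, seed=1)
    with pytest.raises(ValueError, match="closed"):
        audit_session(session, protocol)
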