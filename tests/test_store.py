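"""Append-only session store, student history and cohort aggregates."""

import pytest

from hearsim import SessionStore, StoreError, audit_session, build_report, record_from_session

from conftest import run_compliant_session, notes_from_truth


@pytest.fixture()
def make_record(roster, name_pool, truth_for):
    def _make(base_idx=0, seed=11, student="Student A", record_id=None, wrong_items=()):
        base = roster[base_idx]
        session = run_compliant_session(base, name_pool, seed=seed)
        session.technician_name = student
        truth = truth_for(base)
        notes = notes_from_truth(truth)
        for item in wrong_items:
            holder = type(notes.otoscopy_left)
            if item == "final_recommendation":
                notes = notes.model_copy(update={item: "refer_both" if truth.recommendation.value != "refer_both" else "pass"})
            else:
                flipped = {"normal": "abnormal", "abnormal": "normal",
                           "pass": "refer", "refer": "pass"}[truth.result_for(item)]
                notes = notes.model_copy(update={item: holder(result=flipped)})
        session.notes = notes
        report = build_report(session, truth, audit_session(session))
        return record_from_session(session, report, record_id=record_id)

    return _make


def test_append_then_fetch_round_trips(tmp_path, make_record):
    store = SessionStore(tmp_path / "sessions.jsonl")
    record = make_record(record_id="r1")
    assert store.append(record) == "r1"
    assert store.get("r1") == record
    assert len(store) == 1


def test_duplicate_record_id_rejected(tmp_path, make_record):
    store = SessionStore(tmp_path / "sessions.jsonl")
    store.append(make_record(record_id="dup"))
    with pytest.raises(StoreError, match="dup"):
        store.append(make_record(seed=12, record_id="dup"))
    assert len(store) == 1  # failed append leaves the store untouched


def test_unwritable_store_raises_storage_error(tmp_path, make_record):
    target = tmp_path / "occupied"
    target.mkdir()  # a directory cannot be opened as a store file
    with pytest.raises(StoreError, match="session store"):
        SessionStore(target).append(make_record())


def test_student_history_filters_and_orders(tmp_path, make_record):
    store = SessionStore(tmp_path / "sessions.jsonl")
    scores = []
    for i, wrong in enumerate([(), ("audiometry_left",), ()]):
        record = make_record(seed=20 + i, student="A", record_id=f"a{i}", wrong_items=wrong)
        store.append(record)
        scores.append(record.score)
    store.append(make_record(seed=30, student="B", record_id="b0"))
    store.append(make_record(seed=31, student="B", record_id="b1"))

    history = store.student_history("A")
    assert len(history) == 3
    assert [h["score"] for h in sorted(history, key=lambda h: h["timestamp"])] == scores
    assert len(store.student_history("B")) == 2
    assert store.student_history("nobody") == []


def test_cohort_summary_matches_brute_force_recount(tmp_path, make_record):
    store = SessionStore(tmp_path / "sessions.jsonl")
    plan = [
        (0, ()), (0, ("audiometry_left",)), (1, ("otoscopy_right", "final_recommendation")),
        (2, ()), (3, ("tympanometry_left",)), (0, ()), (1, ()),
        (4, ("audiometry_left", "audiometry_right")), (2, ("final_recommendation",)), (3, ()),
    ]
    records = []
    for i, (base_idx, wrong) in enumerate(plan):
        record = make_record(base_idx=base_idx, seed=50 + i, record_id=f"r{i}", wrong_items=wrong)
        records.append(record)
        store.append(record)

    summary = store.cohort_summary()
    n = len(records)
    assert summary["n_sessions"] == n
    assert summary["mean_score"] == pytest.approx(sum(r.score for r in records) / n)

    # brute-force recount of per-item error fractions over the fixture plan
    for item, rate in summary["per_item_error_rate"].items():
        errors = sum(item in wrong for _, wrong in plan)
        assert rate == pytest.approx(errors / n)

    counts = {}
    for base_idx, _ in plan:
        counts[base_idx] = counts.get(base_idx, 0) + 1
    assert sum(summary["sessions_per_patient"].values()) == n
    assert len(summary["sessions_per_patient"]) == len(counts)


def test_singleton_cohort_equals_record_stats(tmp_path, make_record):
    store = SessionStore(tmp_path / "sessions.jsonl")
    record = make_record(wrong_items=("otoscopy_left",), record_id="only")
    store.append(record)
    summary = store.cohort_summary()
    assert summary["mean_score"] == record.score
    assert summary["per_item_error_rate"]["otoscopy_left"] == 1.0
    assert summary["per_item_error_rate"]["audiometry_left"] == 0.0
    assert summary["sessions_per_patient"] == {record.base_id: 1}


def test_empty_store_summary_errors(tmp_path):
    with pytest.raises(StoreError, match="empty"):
        SessionStore(tmp_path / "none.jsonl").cohort_summary()


def test_append_only_reads_do_not_mutate(tmp_path, make_record):
    path = tmp_path / "sessions.jsonl"
    store = SessionStore(path)
    store.append(make_record(record_id="x"))
    before = path.read_text()
    store.records()
    store.student_history("Student A")
    store.cohort_summary()
    assert path.read_text() == before


def test_export_cohort_csv(tmp_path, make_record):
    store = SessionStore(tmp_path / "sessions.jsonl")
    store.append(make_record(record_id="x"))
    out = tmp_path / "cohort.csv"
    store.export_cohort_csv(out)
    lines = out.read_text().splitlines()
    assert lines[0] == "metric,value"
    assert any(line.startswith("mean_score,") for line in lines)
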