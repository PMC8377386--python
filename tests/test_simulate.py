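"""Synthetic genus profiles, fragment sampling and evaluation statistics."""

import numpy as np
import pytest

from trimerbias import (
    ClassificationResult,
    generate_refdb_fixture,
    percent_correct,
)
from trimerbias.genetic_code import ninemer_to_trimer
from trimerbias.simulate import (
    TAXON_GROUPS,
    Fragment,
    TestSet,
    default_taxon_layout,
    evaluate,
    generate_genus_sequences,
    make_profiles,
    sample_fragments,
)


def test_default_layout_shape():
    layout = default_taxon_layout()
    assert len(layout) == 54
    groups = {spec.taxon_group for spec in layout}
    assert groups == set(TAXON_GROUPS)
    assert sum(spec.kingdom == "bacteria" for spec in layout) == 45
    assert sum(spec.kingdom == "fungi" for spec in layout) == 9


def test_fixture_capping_warns(caplog):
    with caplog.at_level("WARNING"):
        db = generate_refdb_fixture(3, ninemers_per_trimer=500, seed=4)
    assert db.n_trimers == 3
    assert any("capped" in rec.message for rec in caplog.records)


def test_profiles_deterministic(small_refdb, small_layout):
    a = make_profiles(small_refdb, small_layout, seed=2)
    b = make_profiles(small_refdb, small_layout, seed=2)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.trimer_weights, pb.trimer_weights)
        assert np.array_equal(pa.nt_weights, pb.nt_weights)


def test_generated_cds_is_coding(small_refdb, small_layout):
    profile = make_profiles(small_refdb, small_layout, seed=3)[0]
    cds, noncds = generate_genus_sequences(profile, small_refdb, n_seqs=3, mean_len=180)
    for seq in cds:
        assert len(seq) % 3 == 0
        # frame-0 translation is stop-free (chained stop-free trimers)
        for i in range(0, len(seq) - 8, 9):
            assert "*" not in ninemer_to_trimer(seq[i : i + 9])
    assert all(set(s) <= set("ACGT") for s in cds + noncds)
    # same seed regenerates the same sequences
    again, _ = generate_genus_sequences(profile, small_refdb, n_seqs=3, mean_len=180)
    assert again == cds


def test_fragment_sampling_protocol(small_refdb, small_layout):
    profiles = make_profiles(small_refdb, small_layout, seed=5)
    sources = {}
    for p in profiles:
        cds, noncds = generate_genus_sequences(p, small_refdb, n_seqs=4, mean_len=450)
        sources[p.genus_id] = {"CDS": cds, "nonCDS": noncds}
    groups = {p.genus_id: p.taxon_group for p in profiles}
    ts = sample_fragments(sources, groups, per_genus=10, seed=6)
    assert len(ts) == len(profiles) * 2 * 10
    for frag in ts:
        assert 150 <= len(frag.sequence) <= 300
        if frag.db_type == "CDS":
            assert frag.frame in (1, 2, 3)
        else:
            assert frag.frame is None
    again = sample_fragments(sources, groups, per_genus=10, seed=6)
    assert [f.sequence for f in again] == [f.sequence for f in ts]


def test_short_sources_skipped(caplog):
    sources = {"g1": {"CDS": ["ACGT" * 10]}}  # 40 nt < 150
    with caplog.at_level("WARNING"):
        ts = sample_fragments(sources, {"g1": "grp"}, per_genus=5, db_types=("CDS",))
    assert len(ts) == 0


def test_percent_correct_rounding():
    assert percent_correct(3185, 4500) == 71
    assert percent_correct(2238, 4500) == 50
    with pytest.raises(ValueError):
        percent_correct(1, 0)


def _result(query_id, answer, taxon=None, pscore=0.01, frame=1, db_call="CDS"):
    return ClassificationResult(
        query_id=query_id,
        status="ok",
        best_frame=frame,
        db_call=db_call,
        answer_genera=answer,
        taxon_call=taxon,
        pvalue_score=pscore,
        n_matches=5,
        genera=["g1", "g2"],
    )


def test_evaluate_proportions_and_errors():
    groups = {"g1": "A", "g2": "B"}
    truth = TestSet([
        Fragment("q1", "A" * 150, "g1", "A", "CDS", 1),
        Fragment("q2", "A" * 150, "g1", "A", "CDS", 2),
    ])
    results = [
        _result("q1", ["g1"]),  # correct, answer proportion 1
        _result("q2", ["g1", "g2"]),  # answer holds one correct-group genus
    ]
    report = evaluate(results, truth, groups)
    assert report.genus_pct["CDS"] == 100
    assert report.taxon_pct["CDS"] == 100
    assert report.answer_taxon_proportion_mean == pytest.approx(0.75)
    assert report.rank_position_hist[1] == 2
    assert report.frame_recovery_pct == 50
    with pytest.raises(ValueError, match="mismatch"):
        evaluate(results[:1], truth, groups)


def test_evaluate_all_correct_sd_zero():
    groups = {"g1": "A", "g2": "B"}
    truth = TestSet(
        [Fragment(f"q{i}", "A" * 150, "g1", "A", "CDS", 1) for i in range(4)]
    )
    results = [_result(f"q{i}", ["g1"]) for i in range(4)]
    report = evaluate(results, truth, groups)
    assert report.answer_taxon_proportion_mean == 1.0
    assert report.answer_taxon_proportion_sd == 0.0
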