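"""Six-frame scanning, genus scoring, ranks and the Kruskal-Wallis statistic."""

import math

import numpy as np
import pytest
from scipy import stats

from trimerbias import (
    ALLOWED_CUTOFFS,
    GenusScoreIndex,
    QueryTooShortError,
    TrimerRefDB,
    classify_trimer_usage,
    frame_genus_score,
    genus_ranks,
    kruskal_wallis_h,
    scan_frames,
)
from trimerbias.genetic_code import reverse_complement
from trimerbias.scoring import build_rank_scores
from trimerbias.usage import GenusUsageDB, UsageTables, build_genus_db


def _fake_index(biases_by_genus, ninemer="GATGATCAT"):
    """Single-9-mer genus databases with prescribed biases."""
    dbs = []
    for genus, bias in biases_by_genus.items():
        tables = UsageTables(
            aa_trimer_usage={"CCB": {"DDH": 1.0}},
            codon3_usage={"DDH": {ninemer: bias}},
            bias={ninemer: bias},
            log_bias={ninemer: math.log(bias)},
        )
        dbs.append(GenusUsageDB(genus, "CDS", tables))
    return GenusScoreIndex(dbs)


def test_scan_frames_window_counts(small_refdb):
    scans = scan_frames("GATGATCAT", small_refdb)
    assert set(scans) == {1, 2, 3, -1, -2, -3}
    assert len(scans[1].windows) == 1
    assert len(scans[2].windows) == 0
    assert len(scans[3].windows) == 0
    # 156 nt: 52 codons, 50 overlapping 3-codon windows in frame +1
    scans = scan_frames("A" * 156, small_refdb)
    assert len(scans[1].windows) == 50
    assert len(scans[2].windows) == 49


def test_scan_frames_rejects_short_query(small_refdb):
    with pytest.raises(QueryTooShortError):
        scan_frames("A" * 8, small_refdb)


def test_scan_frames_skips_ambiguous_windows(small_refdb):
    scans = scan_frames("GATGATCATNNNGATGATCAT", small_refdb)
    assert all("N" not in w[1] for s in scans.values() for w in s.windows)


def test_reverse_complement_swaps_frames(small_refdb, cohort):
    seq = cohort["train"]["g03"]["CDS"][0]
    fwd = scan_frames(seq, small_refdb)
    rev = scan_frames(reverse_complement(seq), small_refdb)
    for k in (1, 2, 3):
        assert [w[1] for w in fwd[k].windows] == [w[1] for w in rev[-k].windows]
        assert [w[1] for w in fwd[-k].windows] == [w[1] for w in rev[k].windows]


def test_frame_genus_score_mean_log():
    db = TrimerRefDB.from_pairs([("DDH", "GATGATCAT")])
    gdb = build_genus_db("gx", "CDS", [], db)  # uniform tables; bias = 1
    scans = scan_frames("GATGATCAT", db)
    score = frame_genus_score(scans[1], gdb)
    assert score.n_matches == 1
    assert score.log_score == pytest.approx(math.log(gdb.tables.bias["GATGATCAT"]))
    # duplicated matches leave the mean log unchanged
    scans2 = scan_frames("GATGATCATGATGATCATGATGATCAT", db)
    matched = [w for w in scans2[1].windows if w[2].is_full]
    assert len(matched) == 3
    score2 = frame_genus_score(scans2[1], gdb)
    assert score2.log_score == pytest.approx(score.log_score)
    # no matches: undefined score
    empty = frame_genus_score(scans[2], gdb)
    assert empty.n_matches == 0 and math.isnan(empty.log_score)


def test_equal_biases_give_uniform_norm_scores():
    db = TrimerRefDB.from_pairs([("DDH", "GATGATCAT")])
    index = _fake_index({f"g{i}": 0.2 for i in range(5)})
    result = classify_trimer_usage("GATGATCAT", db, index, cutoff=0.05)
    _, _, normv = result.frame_data[(1, "CDS")]
    assert np.allclose(normv, 1 / 5)


def test_answer_set_cutoff_rule():
    """Genera within the cutoff of the maximum normalised score are kept."""
    db = TrimerRefDB.from_pairs([("DDH", "GATGATCAT")])
    index = _fake_index({"g1": 0.60, "g2": 0.57, "g3": 0.05})
    # normalised scores are 0.492/0.467/0.041: g2 sits 0.025 below the top
    wide = classify_trimer_usage("GATGATCAT", db, index, cutoff=0.05)
    assert wide.answer_genera == ["g1", "g2"]
    narrow = classify_trimer_usage("GATGATCAT", db, index, cutoff=0.01)
    assert narrow.answer_genera == ["g1"]


def test_answer_set_monotone_in_cutoff(cohort, cohort_testset):
    clf = cohort["clf"]
    frag = next(f for f in cohort_testset if f.db_type == "CDS")
    previous = None
    for cutoff in ALLOWED_CUTOFFS:
        r = classify_trimer_usage(
            frag.sequence, cohort["refdb"], clf.cds_index_, clf.noncds_index_,
            cutoff=cutoff,
        )
        answer = set(r.answer_genera)
        if previous is not None:
            assert previous <= answer
        previous = answer


def test_invalid_cutoff_rejected(cohort):
    clf = cohort["clf"]
    with pytest.raises(ValueError, match="cutoff"):
        classify_trimer_usage(
            "GATGATCAT" * 3, cohort["refdb"], clf.cds_index_, cutoff=0.07
        )


def test_classification_statuses(cohort):
    clf = cohort["clf"]
    short = classify_trimer_usage(
        "ACGTACG", cohort["refdb"], clf.cds_index_, clf.noncds_index_
    )
    assert short.status == "too_short"
    # a query of only stop-codon windows can never match the reference
    nohit = classify_trimer_usage(
        "TAATAATAA", cohort["refdb"], clf.cds_index_, clf.noncds_index_
    )
    assert nohit.status == "unclassifiable"


def test_reverse_complement_mirrors_call(cohort, cohort_testset):
    clf = cohort["clf"]
    frag = next(f for f in cohort_testset if f.db_type == "CDS")
    fwd = classify_trimer_usage(
        frag.sequence, cohort["refdb"], clf.cds_index_, clf.noncds_index_
    )
    rev = classify_trimer_usage(
        reverse_complement(frag.sequence),
        cohort["refdb"],
        clf.cds_index_,
        clf.noncds_index_,
    )
    assert fwd.answer_genera[0] == rev.answer_genera[0]
    assert fwd.db_call == rev.db_call
    assert fwd.best_frame == -rev.best_frame


def test_genus_ranks_modes():
    values = [0.3, 0.1, 0.9, 0.5]
    ranks = genus_ranks(values)
    assert sorted(ranks) == [1, 2, 3, 4]
    assert ranks[2] == 4  # highest bias gets the top rank
    equal = genus_ranks([1.0] * 54)
    assert np.allclose(equal, 27.5)
    tie = genus_ranks([0.9, 0.9] + [0.1] * 52, method="ordinal")
    assert tie[0] == 54 and tie[1] == 53  # manifest order breaks the tie
    assert sorted(tie) == list(range(1, 55))


def test_kruskal_wallis_examples():
    # equal group mean ranks (2.5 each) give H = 0
    assert kruskal_wallis_h([1, 4, 2, 3], ["a", "a", "b", "b"]) == pytest.approx(0.0)
    assert kruskal_wallis_h([1, 2, 3, 4], ["a", "a", "b", "b"]) == pytest.approx(2.4)
    # invariant under group relabeling
    assert kruskal_wallis_h([1, 2, 3, 4], ["b", "b", "a", "a"]) == pytest.approx(2.4)
    # fully tied ranks define H = 0
    assert kruskal_wallis_h([2.5] * 4, ["a", "a", "b", "b"]) == 0.0


def test_kruskal_wallis_matches_scipy():
    rng = np.random.default_rng(9)
    values = rng.normal(size=30)
    groups = np.repeat(["a", "b", "c"], 10)
    ranks = stats.rankdata(values)
    expected = stats.kruskal(values[:10], values[10:20], values[20:]).statistic
    assert kruskal_wallis_h(ranks, groups) == pytest.approx(expected)


def test_rank_scores_center_and_degenerate(cohort):
    clf = cohort["clf"]
    cds_dbs = [clf.genus_dbs_[(g, "CDS")] for g in clf.classes_]
    groups = [cohort["groups"][g] for g in clf.classes_]
    scores = build_rank_scores(cds_dbs, groups)
    # group scores weighted by group size sum to zero per 9-mer
    for vec in list(scores.values())[:50]:
        assert sum(vec) == pytest.approx(0.0, abs=1e-9)
    # identical genera -> all-zero scores
    same = [cds_dbs[0], cds_dbs[0]]
    flat = build_rank_scores(
        [GenusUsageDB("a", "CDS", same[0].tables, std_usage=same[0].std_usage),
         GenusUsageDB("b", "CDS", same[0].tables, std_usage=same[0].std_usage)],
        ["ga", "gb"],
    )
    for vec in list(flat.values())[:20]:
        assert np.allclose(vec, 0.0)
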