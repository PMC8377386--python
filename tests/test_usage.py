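"""Usage-table construction: counting, smoothing, biases, expectations."""

import numpy as np
import pytest

from trimerbias import (
    TrimerRefDB,
    build_expected_tables,
    build_mono_tables,
    build_usage_tables,
    count_cds_ninemers,
    count_noncds_ninemers,
    load_genus_db,
    save_genus_db,
    standardized_3codon_usage,
    trimer_usage_bias,
)
from trimerbias.genetic_code import reverse_complement, synonymous_ninemers
from trimerbias.usage import build_genus_db

TINY = 1e-9  # pseudocount small enough to recover maximum-likelihood values


@pytest.fixture()
def two_window_db():
    # the 12-nt CDS AAAAAAAAAGAT has stride-3 windows AAAAAAAAA (KKK)
    # and AAAAAAGAT (KKD)
    return TrimerRefDB.from_pairs([("KKK", "AAAAAAAAA"), ("KKD", "AAAAAAGAT")])


def test_cds_counting_stride3_frame0(two_window_db):
    counts = count_cds_ninemers(["AAAAAAAAAGAT"], two_window_db)
    assert counts == {"AAAAAAAAA": 1, "AAAAAAGAT": 1}


def test_cds_counting_exclusions(two_window_db):
    assert count_cds_ninemers(["AAAAAAAA"], two_window_db) == {}  # 8 nt
    assert count_cds_ninemers(["AAAAAAANAGAT"], two_window_db) == {}  # ambiguous


def test_noncds_counting_reverse_frame():
    db = TrimerRefDB.from_pairs([("DDH", "GATGATCAT")])
    seq = reverse_complement("GATGATCAT")
    assert count_cds_ninemers([seq], db) == {}
    assert count_noncds_ninemers([seq], db) == {"GATGATCAT": 1}


def test_noncds_counting_both_strands():
    """A 9-mer stored together with its reverse complement counts twice."""
    from trimerbias.genetic_code import ninemer_to_trimer

    rc = reverse_complement("GATGATCAT")
    db = TrimerRefDB.from_pairs([("DDH", "GATGATCAT"), (ninemer_to_trimer(rc), rc)])
    counts = count_noncds_ninemers(["GATGATCAT"], db)
    assert counts == {"GATGATCAT": 1, rc: 1}


def test_usage_tables_mle_limit():
    """With a negligible pseudocount, usages equal relative frequencies."""
    pairs = [("KKK", "AAAAAAAAA"), ("KKR", "AAAAAAAGA"), ("KRK", "AAAAGAAAA")]
    db = TrimerRefDB.from_pairs(pairs)
    counts = {"AAAAAAAAA": 6, "AAAAAAAGA": 3, "AAAAGAAAA": 1}
    tables = build_usage_tables(counts, db, pseudocount=TINY)
    usage = tables.aa_trimer_usage["AAA"]
    assert usage["KKK"] == pytest.approx(0.6)
    assert usage["KKR"] == pytest.approx(0.3)
    assert usage["KRK"] == pytest.approx(0.1)
    # each trimer stores a single 9-mer, so its 3-codon usage is 1
    assert tables.codon3_usage["KKK"]["AAAAAAAAA"] == pytest.approx(1.0)
    assert trimer_usage_bias(tables, "AAAAAAAAA") == pytest.approx(0.6)


def test_usage_tables_uniform_smoothing():
    """Zero counts with pseudocount 1 give uniform usage over stored entries."""
    db = TrimerRefDB.from_pairs([("FFH", n) for n in synonymous_ninemers("FFH")])
    tables = build_usage_tables({}, db, pseudocount=1.0)
    inner = tables.codon3_usage["FFH"]
    assert len(inner) == 8  # F, F and H each have two codons
    assert all(v == pytest.approx(1 / 8) for v in inner.values())


def test_usage_tables_reject_nonpositive_pseudocount(two_window_db):
    with pytest.raises(ValueError):
        build_usage_tables({}, two_window_db, pseudocount=0.0)


def test_normalization_and_bias_invariants(small_refdb):
    """Inner tables sum to 1; biases under one char trimer sum to 1."""
    rng = np.random.default_rng(3)
    counts = {n: int(rng.integers(0, 50)) for n in small_refdb}
    tables = build_usage_tables(counts, small_refdb, pseudocount=1.0)
    for inner in tables.aa_trimer_usage.values():
        assert sum(inner.values()) == pytest.approx(1.0, abs=1e-9)
    for inner in tables.codon3_usage.values():
        assert sum(inner.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v > 0 for v in inner.values())
    for char_trimer, trimers in small_refdb.hierarchy.items():
        total = sum(
            tables.bias[n] for t, nset in trimers.items() for n in nset
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_counting_additivity(small_refdb, cohort):
    """Pooling two sequence sets equals counting their concatenation."""
    seqs = cohort["train"]["g01"]["CDS"]
    a, b = seqs[:5], seqs[5:]
    merged = count_cds_ninemers(a + b, small_refdb)
    separate = count_cds_ninemers(a, small_refdb) + count_cds_ninemers(b, small_refdb)
    assert merged == separate


def test_mono_tables_relative_frequencies():
    # K only ever coded by AAA; equal K and R counts
    seqs = ["AAACGT" * 10]  # codons AAA (K) and CGT (R), 10 each
    mono = build_mono_tables(seqs, pseudocount=TINY)
    assert mono.avg_codon_usage["K"]["AAA"] == pytest.approx(1.0)
    assert mono.avg_aa_usage["A"]["K"] == pytest.approx(0.5)
    assert mono.avg_aa_usage["A"]["R"] == pytest.approx(0.5)


def test_mono_tables_all_codons_once():
    bases = "ACGT"
    seq = "".join(a + b + c for a in bases for b in bases for c in bases)
    mono = build_mono_tables([seq], pseudocount=TINY)
    assert mono.avg_codon_usage["K"]["AAA"] == pytest.approx(0.5)  # K has 2 codons
    for family in mono.avg_codon_usage.values():
        assert sum(family.values()) == pytest.approx(1.0, abs=1e-9)
    for group in mono.avg_aa_usage.values():
        assert sum(group.values()) == pytest.approx(1.0, abs=1e-9)


def test_expected_tables_are_products(small_refdb, cohort):
    seqs = cohort["train"]["g02"]["CDS"]
    mono = build_mono_tables(seqs)
    expected = build_expected_tables(mono, small_refdb)
    from trimerbias.genetic_code import char_of, translate_codon

    trimer = sorted(small_refdb.trimers)[0]
    manual = 1.0
    for r in trimer:
        manual *= mono.avg_aa_usage[char_of(r)][r]
    assert expected.expected_trimer_usage[trimer] == pytest.approx(manual)

    ninemer = sorted(small_refdb.ninemers_of(trimer))[0]
    manual = 1.0
    for i in (0, 3, 6):
        codon = ninemer[i : i + 3]
        manual *= mono.avg_codon_usage[translate_codon(codon)][codon]
    assert expected.expected_3codon_usage[ninemer] == pytest.approx(manual)


def test_expected_3codon_usage_normalizes_over_family():
    """Product expectations sum to 1 over a full synonymous family."""
    db = TrimerRefDB.from_pairs([("WKV", n) for n in synonymous_ninemers("WKV")])
    mono = build_mono_tables(["TGGAAAGTG" * 5])
    expected = build_expected_tables(mono, db)
    total = sum(expected.expected_3codon_usage[n] for n in synonymous_ninemers("WKV"))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_standardized_usage_identity_and_enrichment():
    db = TrimerRefDB.from_pairs([("KKK", n) for n in synonymous_ninemers("KKK")])
    # no observations: standardized usage defaults to the neutral value 1
    gdb = build_genus_db("gx", "CDS", [], db, pseudocount=1.0)
    for std in gdb.std_usage.values():
        assert std == pytest.approx(1.0)
    # over-represent the AAA-AAA-AAA 9-mer beyond its mono-usage expectation
    skewed = ["AAAAAAAAA" * 10 + "AAGAAGAAG" * 2]
    gdb2 = build_genus_db("gy", "CDS", skewed, db, pseudocount=TINY)
    assert gdb2.std_usage["AAAAAAAAA"] > 1.0
    # in the small-pseudocount limit the stabilized estimator agrees with the
    # plain observed/expected ratio
    assert standardized_3codon_usage(
        gdb2.tables, gdb2.expected, "AAAAAAAAA"
    ) == pytest.approx(gdb2.std_usage["AAAAAAAAA"], rel=1e-6)


def test_genus_db_serialization_round_trip(tmp_path, small_refdb, cohort):
    gdb = cohort["clf"].genus_dbs_[("g01", "CDS")]
    path = tmp_path / "g01.CDS.tsv"
    save_genus_db(gdb, path)
    loaded = load_genus_db(path)
    assert loaded.genus_id == "g01" and loaded.db_type == "CDS"
    for ninemer, bias in gdb.tables.bias.items():
        assert loaded.tables.bias[ninemer] == pytest.approx(bias, rel=1e-9)
    assert loaded.std_usage.keys() == gdb.std_usage.keys()
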