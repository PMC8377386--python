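"""Genus-specific usage tables.

For each genus, and separately for coding (CDS) and non-coding (non-CDS)
training sequence, this module counts reference-matching 9-mers and converts
the counts into two conditional frequency tables:

* amino-acid trimer usage — frequency of each trimer among the trimers
  sharing its characteristic trimer, and
* 3-codon usage — frequency of each 9-mer among the synonymous 9-mers
  encoding the same trimer.

Their product, the *trimer usage bias*, is the genus signature the classifier
scores with.  For coding sequence the module additionally builds mono-usage
tables (per-residue codon usage within synonymous families, per-class residue
usage) and the expected tables derived from them; the ratio observed/expected
3-codon usage ("standardized 3-codon usage") feeds the rank-probability
method.

Every table is Laplace-smoothed over the *reference* support, so every
reference entry has a strictly positive usage even with zero counts.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    CHAR_MEMBERS,
    DNA_ALPHABET,
    char_of,
    ninemer_to_trimer,
    reverse_complement,
    translate_codon,
)
from .refdb import TrimerRefDB

logger = logging.getLogger(__name__)

__all__ = [
    "NinemerCounts",
    "UsageTables",
    "MonoUsageTables",
    "ExpectedUsageTables",
    "GenusUsageDB",
    "count_cds_ninemers",
    "count_noncds_ninemers",
    "build_usage_tables",
    "trimer_usage_bias",
    "build_mono_tables",
    "build_expected_tables",
    "standardized_3codon_usage",
    "build_genus_db",
    "save_genus_db",
    "load_genus_db",
]

NinemerCounts = Counter  # Codon9mer -> count, keys restricted to reference 9-mers

MIN_SEQ_LEN = 9  # shortest sequence that can host one 3-codon 9-mer


def _usable(seq: str) -> bool:
    """Exclusion rule: drop sequences shorter than 9 nt or with ambiguity."""
    return len(seq) >= MIN_SEQ_LEN and set(seq) <= DNA_ALPHABET


def _count_frame(seq: str, offset: int, db: TrimerRefDB, counts: Counter) -> None:
    flat = db.ninemers
    for i in range(offset, len(seq) - 8, 3):
        window = seq[i : i + 9]
        if window in flat:
            counts[window] += 1


def count_cds_ninemers(seqs: Iterable[str], db: TrimerRefDB) -> NinemerCounts:
    """Count reference 9-mers in coding sequences, frame 0 only, stride 3.

    Sequences shorter than 9 nt or containing a non-ACGT character are
    excluded entirely (the count of exclusions is logged).
    """
    counts: Counter = Counter()
    excluded = 0
    for seq in seqs:
        seq = seq.upper()
        if not _usable(seq):
            excluded += 1
            continue
        _count_frame(seq, 0, db, counts)
    if excluded:
        logger.info("count_cds_ninemers: excluded %d sequence(s)", excluded)
    return counts


def count_noncds_ninemers(seqs: Iterable[str], db: TrimerRefDB) -> NinemerCounts:
    """Count reference 9-mers in non-coding sequences over all six frames."""
    counts: Counter = Counter()
    excluded = 0
    for seq in seqs:
        seq = seq.upper()
        if not _usable(seq):
            excluded += 1
            continue
        rc = reverse_complement(seq)
        for offset in (0, 1, 2):
            _count_frame(seq, offset, db, counts)
            _count_frame(rc, offset, db, counts)
    if excluded:
        logger.info("count_noncds_ninemers: excluded %d sequence(s)", excluded)
    return counts


@dataclass
class UsageTables:
    """Smoothed conditional usage tables plus the derived per-9-mer bias."""

    aa_trimer_usage: dict[str, dict[str, float]]  # char trimer -> trimer -> p
    codon3_usage: dict[str, dict[str, float]]  # trimer -> 9-mer -> p
    bias: dict[str, float] = field(repr=False)  # 9-mer -> trimer usage bias
    log_bias: dict[str, float] = field(repr=False)


def build_usage_tables(
    counts: Mapping[str, int], db: TrimerRefDB, pseudocount: float = 1.0
) -> UsageTables:
    """Turn 9-mer counts into smoothed usage tables over the reference support.

    ``aa_trimer_usage(t | c)`` normalises the total count of all 9-mers under
    trimer ``t`` (plus the pseudocount) across the trimers of characteristic
    trimer ``c``; ``codon3_usage(d | t)`` normalises the count of 9-mer ``d``
    across the stored synonymous 9-mers of ``t``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    aa_usage: dict[str, dict[str, float]] = {}
    c3_usage: dict[str, dict[str, float]] = {}
    bias: dict[str, float] = {}
    log_bias: dict[str, float] = {}
    for char_trimer, trimers in db.hierarchy.items():
        trimer_totals = {
            t: sum(counts.get(d, 0) for d in ninemers) + pseudocount
            for t, ninemers in trimers.items()
        }
        denom = sum(trimer_totals.values())
        aa_usage[char_trimer] = {t: v / denom for t, v in trimer_totals.items()}
        for trimer, ninemers in trimers.items():
            smoothed = {d: counts.get(d, 0) + pseudocount for d in ninemers}
            d_denom = sum(smoothed.values())
            c3 = {d: v / d_denom for d, v in smoothed.items()}
            c3_usage[trimer] = c3
            t_usage = aa_usage[char_trimer][trimer]
            for d, u in c3.items():
                b = t_usage * u
                bias[d] = b
                log_bias[d] = math.log(b)
    return UsageTables(aa_usage, c3_usage, bias, log_bias)


def trimer_usage_bias(tables: UsageTables, ninemer: str) -> float:
    """Trimer usage bias of a reference 9-mer (trimer usage x 3-codon usage)."""
    try:
        return tables.bias[ninemer.upper()]
    except KeyError:
        raise KeyError(f"9-mer not in reference support: {ninemer!r}") from None


@dataclass
class MonoUsageTables:
    """Single-residue/-codon usage from coding sequence.

    ``avg_aa_usage`` is the frequency of each residue within its
    characteristic class (21 symbols over 12 classes); ``avg_codon_usage``
    is the frequency of each codon within its synonymous family (64 codons
    over 21 families).
    """

    avg_aa_usage: dict[str, dict[str, float]]  # char label -> residue -> p
    avg_codon_usage: dict[str, dict[str, float]]  # residue -> codon -> p


def build_mono_tables(
    seqs: Iterable[str], pseudocount: float = 1.0
) -> MonoUsageTables:
    """Count in-frame codons of coding sequences and build mono-usage tables."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    codon_counts: Counter = Counter()
    excluded = 0
    for seq in seqs:
        seq = seq.upper()
        if not _usable(seq):
            excluded += 1
            continue
        for i in range(0, len(seq) - 2, 3):
            codon_counts[seq[i : i + 3]] += 1
    if excluded:
        logger.info("build_mono_tables: excluded %d sequence(s)", excluded)

    avg_codon: dict[str, dict[str, float]] = {}
    residue_counts: dict[str, float] = {}
    for residue, codons in AA_TO_CODONS.items():
        smoothed = {c: codon_counts.get(c, 0) + pseudocount for c in codons}
        denom = sum(smoothed.values())
        avg_codon[residue] = {c: v / denom for c, v in smoothed.items()}
        residue_counts[residue] = sum(codon_counts.get(c, 0) for c in codons)

    avg_aa: dict[str, dict[str, float]] = {}
    for label, members in CHAR_MEMBERS.items():
        smoothed = {r: residue_counts[r] + pseudocount for r in members}
        denom = sum(smoothed.values())
        avg_aa[label] = {r: v / denom for r, v in smoothed.items()}
    return MonoUsageTables(avg_aa, avg_codon)


@dataclass
class ExpectedUsageTables:
    """Product-measure expectations derived from the mono-usage tables."""

    expected_trimer_usage: dict[str, float]  # trimer -> p
    expected_3codon_usage: dict[str, float]  # 9-mer -> p


def build_expected_tables(
    mono: MonoUsageTables, db: TrimerRefDB
) -> ExpectedUsageTables:
    """Expected usages as products of the three mono usages of each entry."""
    exp_trimer: dict[str, float] = {}
    exp_3codon: dict[str, float] = {}
    for trimer in db.trimers:
        p = 1.0
        for residue in trimer:
            try:
                p *= mono.avg_aa_usage[char_of(residue)][residue]
            except KeyError:
                raise KeyError(f"missing mono usage for residue {residue!r}") from None
        exp_trimer[trimer] = p
    for ninemer in db.ninemers:
        p = 1.0
        for i in (0, 3, 6):
            codon = ninemer[i : i + 3]
            residue = translate_codon(codon)
            try:
                p *= mono.avg_codon_usage[residue][codon]
            except KeyError:
                raise KeyError(f"missing mono usage for codon {codon!r}") from None
        exp_3codon[ninemer] = p
    return ExpectedUsageTables(exp_trimer, exp_3codon)


def standardized_3codon_usage(
    tables: UsageTables, expected: ExpectedUsageTables, ninemer: str
) -> float:
    """Observed 3-codon usage divided by its mono-usage expectation.

    A value of 1 means the 9-mer is used exactly as often as its individual
    codon usages predict; values above 1 indicate a codon-context effect.
    """
    ninemer = ninemer.upper()
    trimer = ninemer_to_trimer(ninemer)
    try:
        observed = tables.codon3_usage[trimer][ninemer]
        exp = expected.expected_3codon_usage[ninemer]
    except KeyError:
        raise KeyError(f"9-mer not in reference support: {ninemer!r}") from None
    return observed / exp


@dataclass
class GenusUsageDB:
    """All usage tables of one genus for one database type (CDS or nonCDS)."""

    genus_id: str
    db_type: str  # "CDS" or "nonCDS"
    tables: UsageTables
    mono: MonoUsageTables | None = None  # CDS only
    expected: ExpectedUsageTables | None = None  # CDS only
    std_usage: dict[str, float] | None = None  # 9-mer -> standardized usage
    rank_scores: dict[str, float] | None = None  # 9-mer -> rank-probability score


def build_genus_db(
    genus_id: str,
    db_type: str,
    seqs: Iterable[str],
    db: TrimerRefDB,
    pseudocount: float = 1.0,
) -> GenusUsageDB:
    """Count one genus's sequences and assemble its usage database."""
    if db_type not in ("CDS", "nonCDS"):
        raise ValueError(f"db_type must be 'CDS' or 'nonCDS', got {db_type!r}")
    seqs = list(seqs)
    if db_type == "CDS":
        counts = count_cds_ninemers(seqs, db)
    else:
        counts = count_noncds_ninemers(seqs, db)
    tables = build_usage_tables(counts, db, pseudocount)
    gdb = GenusUsageDB(genus_id, db_type, tables)
    if db_type == "CDS":
        gdb.mono = build_mono_tables(seqs, pseudocount)
        gdb.expected = build_expected_tables(gdb.mono, db)
        exp3 = gdb.expected.expected_3codon_usage
        # Stabilized standardized usage: the observed usage is re-estimated
        # with a pseudocount proportional to the mono-usage expectation
        # (renormalised over the stored family), so an unobserved 9-mer
        # defaults to a ratio of 1 instead of the uniform-smoothing artifact
        # uniform/expected, which explodes for codons the genus avoids.
        # The estimate converges to the plain observed/expected ratio as
        # counts grow.
        std: dict[str, float] = {}
        for char_trimer, trimers in db.hierarchy.items():
            for trimer, ninemers in trimers.items():
                family = sorted(ninemers)
                exp_raw = [exp3[n] for n in family]
                exp_norm = sum(exp_raw)
                exp_fam = [e / exp_norm for e in exp_raw]
                k = len(family)
                n_total = sum(counts.get(n, 0) for n in family)
                denom = n_total + pseudocount * k
                for n, e in zip(family, exp_fam):
                    observed = (counts.get(n, 0) + pseudocount * k * e) / denom
                    std[n] = observed / e
        gdb.std_usage = std
    return gdb


# -- serialization ----------------------------------------------------------

_HEADER_COLS = ["char_trimer", "trimer", "ninemer", "aa_trimer_usage", "codon3_usage", "bias"]


def save_genus_db(gdb: GenusUsageDB, path: str | Path) -> None:
    """Write one genus database as a TSV, one row per reference 9-mer."""
    rows = []
    for char_trimer, trimers in sorted(gdb.tables.aa_trimer_usage.items()):
        for trimer in sorted(trimers):
            for ninemer in sorted(gdb.tables.codon3_usage[trimer]):
                row = {
                    "char_trimer": char_trimer,
                    "trimer": trimer,
                    "ninemer": ninemer,
                    "aa_trimer_usage": gdb.tables.aa_trimer_usage[char_trimer][trimer],
                    "codon3_usage": gdb.tables.codon3_usage[trimer][ninemer],
                    "bias": gdb.tables.bias[ninemer],
                }
                if gdb.std_usage is not None:
                    row["std_usage"] = gdb.std_usage[ninemer]
                if gdb.rank_scores is not None:
                    row["rank_score"] = gdb.rank_scores[ninemer]
                rows.append(row)
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# genus_id={gdb.genus_id}\n# db_type={gdb.db_type}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def load_genus_db(path: str | Path) -> GenusUsageDB:
    """Read a genus database TSV written by :func:`save_genus_db`.

    Mono/expected tables are not serialized; the loaded object carries the
    usage tables, biases and (if present) standardized usages and rank scores.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    missing = [c for c in _HEADER_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    aa_usage: dict[str, dict[str, float]] = {}
    c3_usage: dict[str, dict[str, float]] = {}
    bias: dict[str, float] = {}
    log_bias: dict[str, float] = {}
    for row in frame.itertuples(index=False):
        aa_usage.setdefault(row.char_trimer, {})[row.trimer] = row.aa_trimer_usage
        c3_usage.setdefault(row.trimer, {})[row.ninemer] = row.codon3_usage
        bias[row.ninemer] = row.bias
        log_bias[row.ninemer] = math.log(row.bias)
    tables = UsageTables(aa_usage, c3_usage, bias, log_bias)
    gdb = GenusUsageDB(
        meta.get("genus_id", Path(path).stem),
        meta.get("db_type", "CDS"),
        tables,
    )
    if "std_usage" in frame.columns:
        gdb.std_usage = dict(zip(frame["ninemer"], frame["std_usage"]))
    if "rank_score" in frame.columns:
        gdb.rank_scores = dict(zip(frame["ninemer"], frame["rank_score"]))
    return gdb
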