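"""Synthetic reference fixtures, genus sequence generators and benchmarks.

The generator emulates the compositional signals the classifier exploits:

* a reference fixture — a random sample of stop-free amino-acid trimers with
  (a subset of) their synonymous 9-mers, standing in for the secondary-
  structure-derived reference table;
* genus profiles — hierarchically drawn codon preferences (per synonymous
  family) and trimer preferences, shared softly within a taxon group, so
  related genera have correlated 3-codon usage;
* coding sequence built by chaining reference trimers rendered through the
  genus codon preference, and non-coding sequence from a genus-specific
  order-0 nucleotide model, creating the coding/non-coding contrast;
* the fragment-sampling protocol (default 100 fragments per genus per
  database type, 150–300 bp, random start) and the evaluation statistics
  (percent correct at genus and taxon-group level, answer-set taxon
  proportions, P-value-score quartiles, rank-position histogram).

The default panel has 54 genera in 13 taxon groups (45 bacterial-like genera
in 10 groups plus 9 fungal-like in 3), matching the reference configuration
the P-value tables (s = 54) assume.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genetic_code import AA_TO_CODONS, STOP, synonymous_ninemers
from .refdb import TrimerRefDB
from .scoring import ClassificationResult
from .pvalue import log10_inverse

logger = logging.getLogger(__name__)

__all__ = [
    "TAXON_GROUPS",
    "GenusSpec",
    "GenusProfile",
    "Fragment",
    "TestSet",
    "EvaluationReport",
    "default_taxon_layout",
    "generate_refdb_fixture",
    "make_profiles",
    "generate_genus_sequences",
    "sample_fragments",
    "percent_correct",
    "evaluate",
]

#: the 13 higher-rank taxon groups of the reference panel, in canonical order
TAXON_GROUPS = (
    "Clostridia",
    "Bacilli",
    "Oscillatoriophycideae",
    "Nostocales",
    "Acidobacteriales",
    "Betaproteobacteria",
    "Deltaproteobacteria",
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Actinobacteria",
    "AMF",
    "Agaricomycotina",
    "Pezizomycotina",
)

# genera per group in the default 54-genus panel (45 bacterial + 9 fungal)
_DEFAULT_GROUP_SIZES = {
    "Clostridia": 2,
    "Bacilli": 3,
    "Oscillatoriophycideae": 3,
    "Nostocales": 3,
    "Acidobacteriales": 1,
    "Betaproteobacteria": 2,
    "Deltaproteobacteria": 4,
    "Gammaproteobacteria": 9,
    "Alphaproteobacteria": 13,
    "Actinobacteria": 5,
    "AMF": 1,
    "Agaricomycotina": 4,
    "Pezizomycotina": 4,
}

_FUNGAL_GROUPS = {"AMF", "Agaricomycotina", "Pezizomycotina"}

_STOP_FREE = [aa for aa in AA_TO_CODONS if aa != STOP]


class GenusSpec(NamedTuple):
    genus_id: str
    taxon_group: str
    kingdom: str  # "bacteria" or "fungi"


def default_taxon_layout(
    group_sizes: Mapping[str, int] | None = None,
) -> list[GenusSpec]:
    """Synthetic genus panel: genus ids with taxon-group and kingdom labels."""
    sizes = dict(group_sizes) if group_sizes is not None else dict(_DEFAULT_GROUP_SIZES)
    layout: list[GenusSpec] = []
    idx = 1
    for group, size in sizes.items():
        kingdom = "fungi" if group in _FUNGAL_GROUPS else "bacteria"
        for _ in range(size):
            layout.append(GenusSpec(f"g{idx:02d}", group, kingdom))
            idx += 1
    return layout


def generate_refdb_fixture(
    n_trimers: int,
    ninemers_per_trimer: int | None = None,
    seed: int = 0,
) -> TrimerRefDB:
    """Sample a consistent reference hierarchy.

    Draws ``n_trimers`` distinct stop-free amino-acid trimers and stores, for
    each, either all of its synonymous 9-mers (``ninemers_per_trimer=None``)
    or a random subset of that size (capped at the family size with a
    warning).
    """
    if n_trimers < 1:
        raise ValueError("n_trimers must be >= 1")
    rng = np.random.default_rng(seed)
    n_possible = len(_STOP_FREE) ** 3
    if n_trimers > n_possible:
        raise ValueError(f"at most {n_possible} stop-free trimers exist")
    chosen = rng.choice(n_possible, size=n_trimers, replace=False)
    pairs: list[tuple[str, str]] = []
    base = len(_STOP_FREE)
    for code in sorted(int(c) for c in chosen):
        trimer = (
            _STOP_FREE[code // (base * base)]
            + _STOP_FREE[(code // base) % base]
            + _STOP_FREE[code % base]
        )
        family = synonymous_ninemers(trimer)
        if ninemers_per_trimer is None or ninemers_per_trimer >= len(family):
            if ninemers_per_trimer is not None and ninemers_per_trimer > len(family):
                logger.warning(
                    "trimer %s has only %d synonymous 9-mers (requested %d); capped",
                    trimer,
                    len(family),
                    ninemers_per_trimer,
                )
            kept = family
        else:
            kept = [family[i] for i in rng.choice(len(family), size=ninemers_per_trimer, replace=False)]
        pairs.extend((trimer, n) for n in kept)
    return TrimerRefDB.from_pairs(pairs)


@dataclass
class GenusProfile:
    """Sampling parameters of one synthetic genus.

    ``trimer_weights`` is a probability vector over the reference trimers
    (the genus's trimer preference); ``codon_weights`` holds one probability
    vector per residue over its synonymous codons; ``nt_weights`` is the
    order-0 nucleotide composition of the genus's non-coding sequence.
    """

    genus_id: str
    taxon_group: str
    kingdom: str
    trimer_ids: list[str]
    trimer_weights: np.ndarray
    codon_weights: dict[str, np.ndarray]
    nt_weights: np.ndarray
    seed: int


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    return rng.dirichlet(np.maximum(alpha, 1e-3))


def make_profiles(
    refdb: TrimerRefDB,
    layout: Sequence[GenusSpec],
    seed: int = 0,
    codon_concentration: float = 0.1,
    trimer_concentration: float = 0.3,
    within_group_mass: float = 100.0,
    nt_concentration: float = 10.0,
) -> list[GenusProfile]:
    """Draw hierarchical genus profiles over a reference fixture.

    Each taxon group draws a base codon preference per synonymous family
    (Dirichlet with symmetric concentration ``codon_concentration``; small
    values give strongly skewed, well-separated preferences) and a base
    trimer preference (symmetric concentration ``trimer_concentration``).
    Each genus then draws around its group base with total concentration
    mass ``within_group_mass``, so genera of one group stay similar but not
    identical.  Non-coding composition is an independent per-genus
    Dirichlet(``nt_concentration``) over ACGT.
    """
    rng = np.random.default_rng(seed)
    trimer_ids = sorted(refdb.trimers)
    group_base: dict[str, tuple[np.ndarray, dict[str, np.ndarray]]] = {}
    for group in dict.fromkeys(spec.taxon_group for spec in layout):
        t_base = rng.dirichlet(np.full(len(trimer_ids), trimer_concentration))
        c_base = {
            aa: rng.dirichlet(np.full(len(codons), codon_concentration))
            for aa, codons in AA_TO_CODONS.items()
            if aa != STOP
        }
        group_base[group] = (t_base, c_base)
    profiles: list[GenusProfile] = []
    for i, spec in enumerate(layout):
        t_base, c_base = group_base[spec.taxon_group]
        trimer_w = _dirichlet(rng, t_base * within_group_mass)
        codon_w = {
            aa: _dirichlet(rng, base * within_group_mass)
            for aa, base in c_base.items()
        }
        nt_w = rng.dirichlet(np.full(4, nt_concentration))
        profiles.append(
            GenusProfile(
                genus_id=spec.genus_id,
                taxon_group=spec.taxon_group,
                kingdom=spec.kingdom,
                trimer_ids=trimer_ids,
                trimer_weights=trimer_w,
                codon_weights=codon_w,
                nt_weights=nt_w,
                seed=seed + i,
            )
        )
    return profiles


_NTS = np.array(list("ACGT"))


def generate_genus_sequences(
    profile: GenusProfile,
    refdb: TrimerRefDB,
    n_seqs: int = 30,
    mean_len: int = 540,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Generate one genus's coding and non-coding training sequences.

    Coding sequence chains reference trimers drawn from the genus trimer
    preference, rendering each residue through the genus codon preference
    (length is a multiple of 3 and free of internal stops).  Non-coding
    sequence is drawn i.i.d. from the genus nucleotide composition.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    n_trimers_per_seq = max(2, round(mean_len / 9))
    trimer_ids = profile.trimer_ids
    cds: list[str] = []
    for _ in range(n_seqs):
        picks = rng.choice(len(trimer_ids), size=n_trimers_per_seq, p=profile.trimer_weights)
        codons: list[str] = []
        for t_idx in picks:
            for residue in trimer_ids[int(t_idx)]:
                weights = profile.codon_weights[residue]
                codons.append(AA_TO_CODONS[residue][int(rng.choice(len(weights), p=weights))])
        cds.append("".join(codons))
    noncds = [
        "".join(rng.choice(_NTS, size=mean_len, p=profile.nt_weights))
        for _ in range(n_seqs)
    ]
    return cds, noncds


@dataclass(frozen=True)
class Fragment:
    query_id: str
    sequence: str
    genus_id: str
    taxon_group: str
    db_type: str  # "CDS" or "nonCDS"
    frame: int | None  # true coding frame for CDS fragments


@dataclass
class TestSet:
    __test__ = False  # not a pytest collection target

    fragments: list[Fragment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_id": f.query_id,
                    "genus_id": f.genus_id,
                    "taxon_group": f.taxon_group,
                    "db_type": f.db_type,
                    "frame": "" if f.frame is None else f.frame,
                }
                for f in self.fragments
            ]
        )


def sample_fragments(
    seqs_by_genus: Mapping[str, Mapping[str, Sequence[str]]],
    genus_groups: Mapping[str, str],
    per_genus: int = 100,
    len_range: tuple[int, int] = (150, 300),
    seed: int = 0,
    db_types: Sequence[str] = ("CDS", "nonCDS"),
) -> TestSet:
    """Sample read-length fragments from genus sequence sets.

    For each genus and database type, ``per_genus`` fragments are cut from
    randomly chosen source sequences at a uniform random start, with length
    uniform in ``len_range`` (clipped at the sequence end).  Source sequences
    shorter than the minimum length are skipped with a warning.  For coding
    fragments the true reading frame (+1..+3) implied by the cut position is
    recorded.
    """
    lo, hi = len_range
    if lo > hi or lo < 9:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    fragments: list[Fragment] = []
    for genus_id in seqs_by_genus:
        group = genus_groups[genus_id]
        for db_type in db_types:
            sources = [s.upper() for s in seqs_by_genus[genus_id].get(db_type, [])]
            usable = [s for s in sources if len(s) >= lo]
            if len(usable) < len(sources):
                logger.warning(
                    "genus %s %s: skipped %d source sequence(s) shorter than %d nt",
                    genus_id,
                    db_type,
                    len(sources) - len(usable),
                    lo,
                )
            if not usable:
                continue
            for k in range(per_genus):
                seq = usable[int(rng.integers(len(usable)))]
                start = int(rng.integers(0, len(seq) - lo + 1))
                max_len = min(hi, len(seq) - start)
                length = int(rng.integers(lo, max_len + 1))
                frag_seq = seq[start : start + length]
                frame = ((3 - start % 3) % 3) + 1 if db_type == "CDS" else None
                fragments.append(
                    Fragment(
                        query_id=f"{genus_id}_{db_type}_{k:04d}",
                        sequence=frag_seq,
                        genus_id=genus_id,
                        taxon_group=group,
                        db_type=db_type,
                        frame=frame,
                    )
                )
    return TestSet(fragments)


def percent_correct(n_correct: int, n_total: int) -> int:
    """Mean percentage of correct predictions, rounded to integer percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100 * n_correct / n_total)


@dataclass
class EvaluationReport:
    """Benchmark statistics over a classified test set."""

    n_queries: int
    n_classified: int
    per_genus_correct: dict[tuple[str, str], tuple[int, int]]
    genus_pct: dict[str, int]  # db_type -> % correct at genus level
    taxon_pct: dict[str, int]  # db_type -> % correct at taxon-group level
    db_call_pct: dict[str, int]  # db_type -> % CDS/non-CDS call correct
    frame_recovery_pct: int | None
    answer_taxon_proportion_mean: float
    answer_taxon_proportion_sd: float
    quartiles: pd.DataFrame
    rank_position_hist: Counter

    def to_text(self) -> str:
        lines = [
            f"queries: {self.n_queries} ({self.n_classified} classified)",
        ]
        for db_type in sorted(self.genus_pct):
            lines.append(
                f"{db_type}: genus {self.genus_pct[db_type]}% correct, "
                f"taxon group {self.taxon_pct[db_type]}% correct, "
                f"db-type call {self.db_call_pct[db_type]}% correct"
            )
        if self.frame_recovery_pct is not None:
            lines.append(f"frame recovery (CDS): {self.frame_recovery_pct}%")
        lines.append(
            "answer-set correct-taxon proportion: "
            f"{self.answer_taxon_proportion_mean:.2f} "
            f"+/- {self.answer_taxon_proportion_sd:.2f}"
        )
        lines.append("quartiles of log10(1/|P value score|):")
        lines.append(self.quartiles.to_string(index=False))
        lines.append(
            "rank position of first correct-group genus: "
            + ", ".join(
                f"{k}: {v}" for k, v in sorted(self.rank_position_hist.items())
            )
        )
        return "\n".join(lines)


def evaluate(
    results: Iterable[ClassificationResult],
    truth: TestSet,
    genus_groups: Mapping[str, str],
) -> EvaluationReport:
    """Score predictions against a test set's truth labels.

    Percentages are rounded to integer percent.  The quartile table splits
    classified queries into quartiles of log10(1/|P value score|) and reports
    the mean and SD of the correct-prediction indicator per quartile.
    """
    truth_by_id = {f.query_id: f for f in truth}
    results = list(results)
    ids = {r.query_id for r in results}
    missing = set(truth_by_id) - ids
    extra = ids - set(truth_by_id)
    if missing or extra:
        raise ValueError(
            f"prediction/truth ID mismatch: {len(missing)} missing, {len(extra)} extra"
        )

    per_genus: dict[tuple[str, str], list[int]] = {}
    genus_counts: dict[str, list[int]] = {}
    taxon_counts: dict[str, list[int]] = {}
    call_counts: dict[str, list[int]] = {}
    frame_hits: list[int] = []
    proportions: list[float] = []
    quartile_rows: list[tuple[float, int]] = []
    rank_hist: Counter = Counter()
    n_classified = 0

    for r in results:
        frag = truth_by_id[r.query_id]
        key = (frag.genus_id, frag.db_type)
        bucket = per_genus.setdefault(key, [0, 0])
        bucket[1] += 1
        if r.status != "ok":
            continue
        n_classified += 1
        best_genus = r.answer_genera[0] if r.answer_genera else None
        genus_ok = int(best_genus == frag.genus_id)
        bucket[0] += genus_ok
        genus_counts.setdefault(frag.db_type, [0, 0])
        genus_counts[frag.db_type][0] += genus_ok
        genus_counts[frag.db_type][1] += 1
        if r.taxon_call is not None:
            pred_group = r.taxon_call
        elif best_genus is not None:
            pred_group = genus_groups.get(best_genus)
        else:
            pred_group = None
        taxon_ok = int(pred_group == frag.taxon_group)
        taxon_counts.setdefault(frag.db_type, [0, 0])
        taxon_counts[frag.db_type][0] += taxon_ok
        taxon_counts[frag.db_type][1] += 1
        if r.db_call is not None:
            call_counts.setdefault(frag.db_type, [0, 0])
            call_counts[frag.db_type][0] += int(r.db_call == frag.db_type)
            call_counts[frag.db_type][1] += 1
        if frag.db_type == "CDS" and frag.frame is not None and r.best_frame is not None:
            frame_hits.append(int(r.best_frame == frag.frame))
        if r.answer_genera:
            groups = [genus_groups.get(g) for g in r.answer_genera]
            proportions.append(
                sum(g == frag.taxon_group for g in groups) / len(groups)
            )
            hit_rank = next(
                (i + 1 for i, g in enumerate(groups) if g == frag.taxon_group), None
            )
            rank_hist[hit_rank if hit_rank is not None else 0] += 1
        if r.pvalue_score is not None and r.pvalue_score != 0:
            quartile_rows.append((log10_inverse(r.pvalue_score), genus_ok))

    def _pct(counts: dict[str, list[int]]) -> dict[str, int]:
        return {k: percent_correct(v[0], v[1]) for k, v in counts.items()}

    quartile_rows.sort()
    if quartile_rows:
        chunks = np.array_split(np.array(quartile_rows), 4)
        qrows = []
        for i, chunk in enumerate(c for c in chunks if len(c)):
            scores, correct = chunk[:, 0], chunk[:, 1]
            qrows.append(
                {
                    "quartile": i + 1,
                    "score_min": scores.min(),
                    "score_max": scores.max(),
                    "n": len(chunk),
                    "mean_correct": correct.mean(),
                    "sd_correct": correct.std(ddof=0),
                }
            )
        quartiles = pd.DataFrame(qrows)
    else:
        quartiles = pd.DataFrame(
            columns=["quartile", "score_min", "score_max", "n", "mean_correct", "sd_correct"]
        )

    prop_arr = np.array(proportions) if proportions else np.array([math.nan])
    return EvaluationReport(
        n_queries=len(results),
        n_classified=n_classified,
        per_genus_correct={k: (v[0], v[1]) for k, v in per_genus.items()},
        genus_pct=_pct(genus_counts),
        taxon_pct=_pct(taxon_counts),
        db_call_pct=_pct(call_counts),
        frame_recovery_pct=(
            percent_correct(sum(frame_hits), len(frame_hits)) if frame_hits else None
        ),
        answer_taxon_proportion_mean=float(np.nanmean(prop_arr)),
        answer_taxon_proportion_sd=float(np.nanstd(prop_arr)),
        quartiles=quartiles,
        rank_position_hist=rank_hist,
    )
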