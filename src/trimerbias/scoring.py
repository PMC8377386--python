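"""Six-frame query scanning and the two classification methods.

A query is scanned in all six reading frames (three forward offsets, three on
the reverse complement) with 9-nt windows at stride 3.  Windows fully matching
the reference hierarchy retrieve, from every genus database, the trimer usage
bias of the matched 9-mer.  Per (frame, database type) the genus score is the
mean natural-log bias over the matches; within a frame the scores are
normalised over the genera so they sum to 1 and are comparable across frames.

Two classifiers are provided:

* trimer-usage method — argmax of the normalised score over (genus, frame,
  CDS/non-CDS), with an answer set of genera whose scores sit within a fixed
  cutoff of the maximum, plus a signed rank-sum P-value score;
* rank-probability method — per-9-mer Kruskal–Wallis rank scores over the 13
  taxon groups (built from bias and standardized 3-codon usage rankings),
  summed over a query's matched 9-mers; CDS queries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .genetic_code import DNA_ALPHABET, reverse_complement
from .pvalue import PValueDatabase, pvalue_score
from .refdb import MatchResult, TrimerRefDB
from .usage import GenusUsageDB

logger = logging.getLogger(__name__)

__all__ = [
    "FRAME_IDS",
    "ALLOWED_CUTOFFS",
    "DEFAULT_CUTOFF",
    "QueryTooShortError",
    "FrameScan",
    "GenusFrameScore",
    "ClassificationResult",
    "GenusScoreIndex",
    "scan_frames",
    "frame_genus_score",
    "classify_trimer_usage",
    "genus_ranks",
    "kruskal_wallis_h",
    "build_rank_scores",
    "classify_rank_probability",
]

#: reading frames: +1..+3 = forward offsets 0..2, -1..-3 = reverse complement
FRAME_IDS = (1, 2, 3, -1, -2, -3)

#: the six user-selectable score-difference cutoffs for the answer set
ALLOWED_CUTOFFS = (0.01, 0.05, 0.1, 0.15, 0.2, 0.3)
DEFAULT_CUTOFF = 0.05

MIN_QUERY_LEN = 9


class QueryTooShortError(ValueError):
    """Query cannot host a single 3-codon 9-mer (length < 9 nt)."""


@dataclass
class FrameScan:
    """Ordered 9-nt windows of one reading frame with their match results."""

    frame_id: int
    windows: list[tuple[int, str, MatchResult]]

    @property
    def matched_ninemers(self) -> list[str]:
        return [n for _, n, m in self.windows if m.is_full]


def scan_frames(seq: str, db: TrimerRefDB) -> dict[int, FrameScan]:
    """Scan a query in all six reading frames.

    Windows are 9 nt at stride 3 within each frame; windows containing a
    non-ACGT character are skipped.  Offsets are relative to the scanned
    strand (the reverse complement for negative frames).
    """
    seq = seq.upper()
    if len(seq) < MIN_QUERY_LEN:
        raise QueryTooShortError(
            f"query of {len(seq)} nt cannot host a 9-nt window"
        )
    rc = reverse_complement(seq)
    scans: dict[int, FrameScan] = {}
    for frame_id in FRAME_IDS:
        strand = seq if frame_id > 0 else rc
        offset = abs(frame_id) - 1
        windows: list[tuple[int, str, MatchResult]] = []
        for i in range(offset, len(strand) - 8, 3):
            window = strand[i : i + 9]
            if not set(window) <= DNA_ALPHABET:
                continue
            windows.append((i, window, db.match(window)))
        scans[frame_id] = FrameScan(frame_id, windows)
    return scans


@dataclass
class GenusFrameScore:
    """Score of one genus database in one reading frame."""

    genus_id: str
    db_type: str
    frame_id: int
    n_matches: int
    log_score: float  # mean natural-log trimer usage bias over the matches
    norm_score: float = float("nan")  # normalised over genera within the frame


def frame_genus_score(scan: FrameScan, gdb: GenusUsageDB) -> GenusFrameScore:
    """Mean log trimer-usage bias of one genus over a frame's full matches.

    With zero matches the score is undefined (NaN) and the frame is excluded
    from classification.  The normalised score is filled in later, once all
    genera of the frame are scored.
    """
    matches = scan.matched_ninemers
    if not matches:
        return GenusFrameScore(gdb.genus_id, gdb.db_type, scan.frame_id, 0, float("nan"))
    log_bias = gdb.tables.log_bias
    mean_log = sum(log_bias[n] for n in matches) / len(matches)
    return GenusFrameScore(
        gdb.genus_id, gdb.db_type, scan.frame_id, len(matches), mean_log
    )


class GenusScoreIndex:
    """Log-bias vectors over the genus panel, keyed by reference 9-mer.

    Packs one database type's 54 (or however many) genus databases into
    per-9-mer numpy vectors so a frame can be scored for all genera at once.
    Genus order follows the manifest and is the tie-breaking order.
    """

    def __init__(self, dbs: list[GenusUsageDB]):
        if not dbs:
            raise ValueError("need at least one genus database")
        db_types = {g.db_type for g in dbs}
        if len(db_types) != 1:
            raise ValueError(f"mixed db_types in index: {db_types}")
        self.db_type = dbs[0].db_type
        self.genera = [g.genus_id for g in dbs]
        ninemers = sorted(dbs[0].tables.log_bias)
        for g in dbs[1:]:
            if sorted(g.tables.log_bias) != ninemers:
                raise ValueError(
                    f"genus {g.genus_id} was built against a different reference"
                )
        self.log_bias: dict[str, np.ndarray] = {
            n: np.array([g.tables.log_bias[n] for g in dbs]) for n in ninemers
        }

    def __len__(self) -> int:
        return len(self.genera)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


@dataclass
class ClassificationResult:
    """Outcome of classifying one query."""

    query_id: str
    status: str  # "ok", "unclassifiable" or "too_short"
    best_frame: int | None = None
    db_call: str | None = None  # "CDS" or "nonCDS"
    answer_genera: list[str] = field(default_factory=list)
    taxon_call: str | None = None
    taxon_totals: dict[str, float] | None = None
    pvalue_score: float | None = None
    n_matches: int = 0
    genera: list[str] = field(default_factory=list)
    #: (frame_id, db_type) -> (n_matches, mean-log vector, normalised vector)
    frame_data: dict[tuple[int, str], tuple[int, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )
    scans: dict[int, FrameScan] | None = field(default=None, repr=False)

    def iter_genus_frame_scores(self):
        """Expand the packed per-frame vectors into GenusFrameScore records."""
        for (frame_id, db_type), (n, logv, normv) in sorted(
            self.frame_data.items(), key=lambda kv: (kv[0][1], -kv[0][0])
        ):
            for i, genus in enumerate(self.genera):
                yield GenusFrameScore(
                    genus, db_type, frame_id, n, float(logv[i]), float(normv[i])
                )


def _frame_vectors(
    scans: dict[int, FrameScan], index: GenusScoreIndex
) -> dict[tuple[int, str], tuple[int, np.ndarray, np.ndarray]]:
    out = {}
    for frame_id, scan in scans.items():
        matched = [n for n in scan.matched_ninemers if n in index.log_bias]
        if not matched:
            continue
        logv = np.mean([index.log_bias[n] for n in matched], axis=0)
        out[(frame_id, index.db_type)] = (len(matched), logv, _softmax(logv))
    return out


def classify_trimer_usage(
    seq: str,
    db: TrimerRefDB,
    cds_index: GenusScoreIndex,
    noncds_index: GenusScoreIndex | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    pvalues: PValueDatabase | None = None,
    query_id: str = "",
) -> ClassificationResult:
    """Classify one query by the trimer-usage probability method.

    The prediction is the argmax of the normalised score over (genus, frame,
    database type); the answer set contains every genus of the winning frame
    and database type whose normalised score differs from the maximum by less
    than ``cutoff`` (one of the six allowed values).  When a P-value table
    collection is supplied, the signed rank-sum P-value score of the winning
    genus in the winning frame is attached.
    """
    if cutoff not in ALLOWED_CUTOFFS:
        raise ValueError(f"cutoff must be one of {ALLOWED_CUTOFFS}, got {cutoff}")
    if noncds_index is not None and noncds_index.genera != cds_index.genera:
        raise ValueError("CDS and non-CDS indices list different genus panels")
    genera = cds_index.genera
    try:
        scans = scan_frames(seq, db)
    except QueryTooShortError:
        return ClassificationResult(query_id, "too_short", genera=genera)

    frame_data = dict(_frame_vectors(scans, cds_index))
    if noncds_index is not None:
        frame_data.update(_frame_vectors(scans, noncds_index))
    if not frame_data:
        return ClassificationResult(
            query_id, "unclassifiable", genera=genera, scans=scans
        )

    # argmax over (genus, frame, db_type); ties broken by manifest order,
    # then CDS before non-CDS, then frame order
    best_key = None
    best_genus_idx = None
    best_norm = -np.inf
    order = {(f, t): k for k, (f, t) in enumerate(
        (f, t) for t in ("CDS", "nonCDS") for f in FRAME_IDS
    )}
    for key in sorted(frame_data, key=lambda k: order[k]):
        _, _, normv = frame_data[key]
        idx = int(np.argmax(normv))  # first (manifest-order) maximum
        if normv[idx] > best_norm:
            best_norm = float(normv[idx])
            best_key = key
            best_genus_idx = idx

    frame_id, db_type = best_key
    n_matches, _, normv = frame_data[best_key]
    keep = np.flatnonzero(best_norm - normv < cutoff)
    keep = keep[np.argsort(-normv[keep], kind="stable")]
    answer = [genera[i] for i in keep]

    result = ClassificationResult(
        query_id=query_id,
        status="ok",
        best_frame=frame_id,
        db_call=db_type,
        answer_genera=answer,
        n_matches=n_matches,
        genera=genera,
        frame_data=frame_data,
        scans=scans,
    )
    if pvalues is not None:
        index = cds_index if db_type == "CDS" else noncds_index
        rank_sum = _genus_rank_sum(scans[frame_id], index, best_genus_idx)
        table = pvalues.table(n_matches)
        result.pvalue_score = pvalue_score(rank_sum, table).value
    return result


def _genus_rank_sum(
    scan: FrameScan, index: GenusScoreIndex, genus_idx: int
) -> int:
    """Sum over matched 9-mers of the focal genus's ordinal rank (1..s)."""
    total = 0
    for ninemer in scan.matched_ninemers:
        vec = index.log_bias.get(ninemer)
        if vec is None:
            continue
        ranks = genus_ranks(vec, method="ordinal")
        total += int(ranks[genus_idx])
    return total


def genus_ranks(biases, method: str = "average") -> np.ndarray:
    """Rank the genus panel by bias, ascending (highest bias -> rank s).

    ``average`` assigns tied values their average rank (used by the rank-
    probability method); ``ordinal`` breaks ties by manifest order, the
    earlier genus receiving the higher rank, so rank sums stay integral for
    the P-value tables.
    """
    biases = np.asarray(biases, dtype=float)
    if method == "average":
        return rankdata(biases, method="average")
    if method == "ordinal":
        n = len(biases)
        order = sorted(range(n), key=lambda i: (biases[i], -i))
        ranks = np.empty(n, dtype=float)
        for rank0, i in enumerate(order):
            ranks[i] = rank0 + 1
        return ranks
    raise ValueError(f"unknown ranking method: {method!r}")


def kruskal_wallis_h(ranks, groups) -> float:
    """Kruskal–Wallis H statistic from precomputed ranks, tie-corrected.

    ``ranks`` are the 1..N ranks of the pooled sample; ``groups`` assigns each
    observation to a group.  H = 12/(N(N+1)) * sum_g n_g (rbar_g - (N+1)/2)^2,
    divided by 1 - sum(t^3 - t)/(N^3 - N) over tie multiplicities; when every
    value is tied H is defined as 0.
    """
    ranks = np.asarray(ranks, dtype=float)
    groups = np.asarray(groups)
    if ranks.shape != groups.shape:
        raise ValueError("ranks and groups must have equal length")
    n_total = len(ranks)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    grand_mean = (n_total + 1) / 2.0
    h = 0.0
    for g in np.unique(groups):
        idx = groups == g
        h += idx.sum() * (ranks[idx].mean() - grand_mean) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(ranks, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    if correction <= 0:
        return 0.0
    return h / correction


def build_rank_scores(
    cds_dbs: list[GenusUsageDB], taxon_groups: list[str]
) -> dict[str, np.ndarray]:
    """Per-9-mer rank-probability scores for every genus.

    For each reference 9-mer the genus panel is ranked twice — by trimer
    usage bias and by standardized 3-codon usage (average ranks for ties).
    Each ranking yields a Kruskal–Wallis H over the taxon groups and centered
    group mean ranks; a genus scores H * (rbar_group - (N+1)/2) / N, averaged
    over the two rankings.  Genera of one taxon group share the value, and
    the group scores (weighted by group size) sum to zero per ranking.
    """
    if len(cds_dbs) != len(taxon_groups):
        raise ValueError("one taxon group per genus database required")
    for g in cds_dbs:
        if g.std_usage is None:
            raise ValueError(
                f"genus {g.genus_id} lacks standardized usages (CDS build required)"
            )
    groups = np.asarray(taxon_groups)
    n = len(cds_dbs)
    center = (n + 1) / 2.0
    ninemers = sorted(cds_dbs[0].tables.bias)
    unique_groups = np.unique(groups)
    group_masks = {g: groups == g for g in unique_groups}
    scores: dict[str, np.ndarray] = {}
    for ninemer in ninemers:
        bias_vec = np.array([g.tables.bias[ninemer] for g in cds_dbs])
        std_vec = np.array([g.std_usage[ninemer] for g in cds_dbs])
        total = np.zeros(n)
        for vec in (bias_vec, std_vec):
            ranks = genus_ranks(vec, method="average")
            h = kruskal_wallis_h(ranks, groups)
            for g, mask in group_masks.items():
                total[mask] += h * (ranks[mask].mean() - center) / n
        scores[ninemer] = total / 2.0
    return scores


def classify_rank_probability(
    seq: str,
    db: TrimerRefDB,
    cds_index: GenusScoreIndex,
    rank_scores: dict[str, np.ndarray],
    taxon_groups: list[str],
    query_id: str = "",
) -> ClassificationResult:
    """Classify a (presumed coding) query into one of the taxon groups.

    The reading frame is chosen as in the trimer-usage method restricted to
    the CDS databases; the per-group total is the sum over the frame's
    matched 9-mers of the group's rank-probability score, and the prediction
    is the argmax group.
    """
    if len(taxon_groups) != len(cds_index):
        raise ValueError("one taxon group per genus required")
    try:
        scans = scan_frames(seq, db)
    except QueryTooShortError:
        return ClassificationResult(query_id, "too_short", genera=cds_index.genera)
    frame_data = _frame_vectors(scans, cds_index)
    if not frame_data:
        return ClassificationResult(
            query_id, "unclassifiable", genera=cds_index.genera, scans=scans
        )
    best_key = max(
        sorted(frame_data, key=lambda k: FRAME_IDS.index(k[0])),
        key=lambda k: frame_data[k][2].max(),
    )
    frame_id, _ = best_key
    matched = scans[frame_id].matched_ninemers
    totals_vec = np.zeros(len(cds_index))
    for ninemer in matched:
        totals_vec += rank_scores[ninemer]
    groups = np.asarray(taxon_groups)
    # genera of one group share the value; report one total per group
    seen: dict[str, float] = {}
    for g in groups:
        if g not in seen:
            seen[g] = float(totals_vec[groups == g][0])
    taxon_call = max(seen, key=lambda g: seen[g])
    return ClassificationResult(
        query_id=query_id,
        status="ok",
        best_frame=frame_id,
        db_call="CDS",
        taxon_call=taxon_call,
        taxon_totals=seen,
        n_matches=len(matched),
        genera=cds_index.genera,
        frame_data=dict(frame_data),
        scans=scans,
    )
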