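"""Detail and summary writers for classification results.

The detail file is a tall TSV with one record per row:

* ``frame`` rows — one per (query, reading frame), with the match count
  (frames without matches are flagged ``no_match``);
* ``match`` rows — each matched window's offset, 9-mer, amino-acid trimer
  and characteristic trimer;
* ``score`` rows — per (query, frame, database type, genus): the within-
  frame rank (higher = better), mean-log score, normalised score and signed
  rank-sum P-value score.

The summary file has one row per query with the predicted outcome.  It is
derivable from the detail file alone; :func:`read_detail_scores` parses the
score rows back for round-trip checks.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .pvalue import PValueDatabase, pvalue_score
from .scoring import FRAME_IDS, ClassificationResult, genus_ranks

__all__ = ["write_detail", "write_summary", "read_detail_scores"]

_DETAIL_COLS = [
    "record",
    "query_id",
    "frame",
    "db_type",
    "offset",
    "ninemer",
    "trimer",
    "char_trimer",
    "genus",
    "rank",
    "n_matches",
    "log_score",
    "norm_score",
    "pvalue_score",
]


def _fmt_frame(frame_id: int) -> str:
    return f"{frame_id:+d}"


def _frame_pvalues(
    result: ClassificationResult,
    frame_id: int,
    db_type: str,
    pvalues: PValueDatabase | None,
    indices: dict | None,
) -> np.ndarray | None:
    """Signed P-value score per genus from its rank sum in one frame.

    Needs the per-9-mer bias vectors, so a score index for the database type
    must be supplied; otherwise the column is left empty.
    """
    if pvalues is None or result.scans is None or not indices:
        return None
    index = indices.get(db_type)
    if index is None:
        return None
    key = (frame_id, db_type)
    if key not in result.frame_data:
        return None
    n_matches, _, _ = result.frame_data[key]
    if n_matches == 0:
        return None
    sums = np.zeros(len(result.genera), dtype=int)
    for ninemer in result.scans[frame_id].matched_ninemers:
        vec = index.log_bias.get(ninemer)
        if vec is not None:
            sums += genus_ranks(vec, method="ordinal").astype(int)
    table = pvalues.table(n_matches)
    out = np.empty(len(sums))
    for i, s in enumerate(sums):
        out[i] = pvalue_score(int(s), table).value
    return out


def write_detail(
    results: Iterable[ClassificationResult],
    path: str | Path,
    pvalues: PValueDatabase | None = None,
    indices: dict | None = None,
) -> None:
    """Write the per-frame detail TSV for a batch of results."""
    rows: list[dict] = []
    for r in results:
        frames = FRAME_IDS
        for frame_id in frames:
            scan = r.scans.get(frame_id) if r.scans else None
            matched = [w for w in scan.windows if w[2].is_full] if scan else []
            rows.append(
                {
                    "record": "frame",
                    "query_id": r.query_id,
                    "frame": _fmt_frame(frame_id),
                    "n_matches": len(matched),
                    "db_type": "." if matched else "no_match",
                }
            )
            for offset, ninemer, match in matched:
                rows.append(
                    {
                        "record": "match",
                        "query_id": r.query_id,
                        "frame": _fmt_frame(frame_id),
                        "offset": offset,
                        "ninemer": ninemer,
                        "trimer": match.trimer,
                        "char_trimer": match.char_trimer,
                    }
                )
            for db_type in ("CDS", "nonCDS"):
                key = (frame_id, db_type)
                if key not in r.frame_data:
                    continue
                n_matches, logv, normv = r.frame_data[key]
                pvals = _frame_pvalues(r, frame_id, db_type, pvalues, indices)
                ranks = genus_ranks(normv, method="ordinal").astype(int)
                order = np.argsort(-ranks)
                for i in order:
                    rows.append(
                        {
                            "record": "score",
                            "query_id": r.query_id,
                            "frame": _fmt_frame(frame_id),
                            "db_type": db_type,
                            "genus": r.genera[i],
                            "rank": int(ranks[i]),
                            "n_matches": n_matches,
                            "log_score": float(logv[i]),
                            "norm_score": float(normv[i]),
                            "pvalue_score": (
                                float(pvals[i]) if pvals is not None else ""
                            ),
                        }
                    )
    frame = pd.DataFrame(rows, columns=_DETAIL_COLS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_detail_scores(path: str | Path) -> pd.DataFrame:
    """Parse the score rows of a detail file back into a DataFrame."""
    frame = pd.read_csv(path, sep="\t", dtype={"frame": str})
    return frame[frame["record"] == "score"].reset_index(drop=True)


def write_summary(
    results: Iterable[ClassificationResult], path: str | Path
) -> None:
    """Write the one-row-per-query summary TSV."""
    rows = []
    for r in results:
        rows.append(
            {
                "query_id": r.query_id,
                "status": r.status,
                "db_call": r.db_call or "",
                "best_frame": _fmt_frame(r.best_frame) if r.best_frame else "",
                "answer_genera": ";".join(r.answer_genera),
                "taxon_call": r.taxon_call or "",
                "pvalue_score": (
                    f"{r.pvalue_score:.10g}"
                    if r.pvalue_score is not None and math.isfinite(r.pvalue_score)
                    else ""
                ),
                "n_matches": r.n_matches,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
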