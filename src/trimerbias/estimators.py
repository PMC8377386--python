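"""Scikit-learn style estimators wrapping the two classification methods.

``X`` is a sequence of DNA strings.  For fitting, ``y`` gives the genus label
of each training sequence; the ``db_type`` fit parameter marks each sequence
as coding ("CDS") or non-coding ("nonCDS").  Prediction runs the six-frame
scan and scoring against the fitted genus panel.

Both estimators satisfy the usual contract — ``get_params``/``set_params``,
``fit`` returning ``self``, fitted attributes carrying a trailing underscore,
``classes_``, and compatibility with :func:`sklearn.base.clone` — so they can
sit inside sklearn model-selection utilities, keeping in mind that ``X`` is a
list of strings rather than a numeric matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .pvalue import PValueDatabase
from .refdb import TrimerRefDB
from .scoring import (
    DEFAULT_CUTOFF,
    GenusScoreIndex,
    build_rank_scores,
    classify_rank_probability,
    classify_trimer_usage,
)
from .usage import build_genus_db

__all__ = ["TrimerUsageClassifier", "RankProbabilityClassifier"]


def _validate_inputs(X, y, db_type):
    X = list(X)
    if y is None:
        raise ValueError("y (genus labels) is required")
    y = np.asarray(y, dtype=object)
    if len(X) != len(y):
        raise ValueError(f"X and y have different lengths: {len(X)} vs {len(y)}")
    if not all(isinstance(s, str) for s in X):
        raise TypeError("X must be a sequence of DNA strings")
    if db_type is None:
        db_type = np.full(len(X), "CDS", dtype=object)
    else:
        db_type = np.asarray(db_type, dtype=object)
        if len(db_type) != len(X):
            raise ValueError("db_type must have one entry per sequence")
        bad = set(db_type) - {"CDS", "nonCDS"}
        if bad:
            raise ValueError(f"db_type entries must be 'CDS' or 'nonCDS', got {bad}")
    return X, y, db_type


class TrimerUsageClassifier(ClassifierMixin, BaseEstimator):
    """Genus-level classifier scoring trimer usage bias over six frames.

    Parameters
    ----------
    refdb:
        The trimer reference hierarchy the genus databases are counted
        against.
    cutoff:
        Score-difference cutoff for the answer set; one of the six allowed
        values (default 0.05).  Lower cutoffs admit fewer genera.
    pseudocount:
        Laplace smoothing mass added to every reference entry when building
        usage tables.
    with_pvalues:
        Attach the signed rank-sum P-value score to each prediction.

    Attributes
    ----------
    classes_ : ndarray of genus labels, in first-seen (manifest) order.
    cds_index_, noncds_index_ : packed per-9-mer log-bias vectors.
    genus_dbs_ : dict (genus, db_type) -> GenusUsageDB.
    """

    def __init__(
        self,
        refdb: TrimerRefDB | None = None,
        cutoff: float = DEFAULT_CUTOFF,
        pseudocount: float = 1.0,
        with_pvalues: bool = True,
    ):
        self.refdb = refdb
        self.cutoff = cutoff
        self.pseudocount = pseudocount
        self.with_pvalues = with_pvalues

    def fit(self, X, y, db_type=None):
        """Build the per-genus CDS and non-CDS usage databases.

        Genera missing training sequence of one type fall back to the
        smoothed (uniform) tables for that type.
        """
        if self.refdb is None:
            raise ValueError("refdb is required to fit")
        X, y, db_type = _validate_inputs(X, y, db_type)
        genera = list(dict.fromkeys(y))
        self.classes_ = np.asarray(genera, dtype=object)
        self.genus_dbs_ = {}
        cds_dbs, noncds_dbs = [], []
        for genus in genera:
            mask = y == genus
            for dtype, bucket in (("CDS", cds_dbs), ("nonCDS", noncds_dbs)):
                seqs = [s for s, m, t in zip(X, mask, db_type) if m and t == dtype]
                gdb = build_genus_db(genus, dtype, seqs, self.refdb, self.pseudocount)
                self.genus_dbs_[(genus, dtype)] = gdb
                bucket.append(gdb)
        self.cds_index_ = GenusScoreIndex(cds_dbs)
        self.noncds_index_ = GenusScoreIndex(noncds_dbs)
        self.pvalues_ = (
            PValueDatabase(s=len(genera)) if self.with_pvalues else None
        )
        return self

    def predict_result(self, X):
        """Full :class:`ClassificationResult` per query."""
        check_is_fitted(self, "cds_index_")
        X = list(X)
        return [
            classify_trimer_usage(
                seq,
                self.refdb,
                self.cds_index_,
                self.noncds_index_,
                cutoff=self.cutoff,
                pvalues=self.pvalues_,
                query_id=str(i),
            )
            for i, seq in enumerate(X)
        ]

    def predict(self, X):
        """Best genus per query (None where unclassifiable)."""
        return np.array(
            [
                r.answer_genera[0] if r.status == "ok" and r.answer_genera else None
                for r in self.predict_result(X)
            ],
            dtype=object,
        )


class RankProbabilityClassifier(ClassifierMixin, BaseEstimator):
    """Taxon-group classifier from Kruskal–Wallis rank scores (CDS only).

    Parameters
    ----------
    refdb:
        Trimer reference hierarchy.
    taxon_map:
        dict genus label -> taxon group; every fitted genus must appear.
    pseudocount:
        Laplace smoothing mass for the usage and mono-usage tables.

    Attributes
    ----------
    classes_ : ndarray of taxon-group labels.
    rank_scores_ : dict 9-mer -> per-genus score vector.
    """

    def __init__(
        self,
        refdb: TrimerRefDB | None = None,
        taxon_map: dict | None = None,
        pseudocount: float = 1.0,
    ):
        self.refdb = refdb
        self.taxon_map = taxon_map
        self.pseudocount = pseudocount

    def fit(self, X, y, db_type=None):
        """Build per-genus CDS databases and the per-9-mer rank scores.

        Non-CDS rows in ``db_type`` are ignored (the method applies to
        coding sequence only).
        """
        if self.refdb is None:
            raise ValueError("refdb is required to fit")
        if self.taxon_map is None:
            raise ValueError("taxon_map (genus -> taxon group) is required")
        X, y, db_type = _validate_inputs(X, y, db_type)
        keep = db_type == "CDS"
        X = [s for s, k in zip(X, keep) if k]
        y = y[keep]
        genera = list(dict.fromkeys(y))
        missing = [g for g in genera if g not in self.taxon_map]
        if missing:
            raise ValueError(f"taxon_map lacks entries for genera: {missing}")
        self.genera_ = genera
        self.taxon_groups_ = [self.taxon_map[g] for g in genera]
        self.classes_ = np.asarray(
            list(dict.fromkeys(self.taxon_groups_)), dtype=object
        )
        cds_dbs = []
        for genus in genera:
            seqs = [s for s, g in zip(X, y) if g == genus]
            cds_dbs.append(
                build_genus_db(genus, "CDS", seqs, self.refdb, self.pseudocount)
            )
        self.cds_index_ = GenusScoreIndex(cds_dbs)
        self.rank_scores_ = build_rank_scores(cds_dbs, self.taxon_groups_)
        for gdb in cds_dbs:
            idx = genera.index(gdb.genus_id)
            gdb.rank_scores = {
                n: float(vec[idx]) for n, vec in self.rank_scores_.items()
            }
        self.cds_dbs_ = cds_dbs
        return self

    def predict_result(self, X):
        check_is_fitted(self, "rank_scores_")
        return [
            classify_rank_probability(
                seq,
                self.refdb,
                self.cds_index_,
                self.rank_scores_,
                self.taxon_groups_,
                query_id=str(i),
            )
            for i, seq in enumerate(list(X))
        ]

    def predict(self, X):
        """Taxon-group call per query (None where unclassifiable)."""
        return np.array(
            [
                r.taxon_call if r.status == "ok" else None
                for r in self.predict_result(X)
            ],
            dtype=object,
        )
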