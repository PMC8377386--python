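"""Shared fixtures: a small reference fixture and a fitted 6-genus cohort."""

import numpy as np
import pytest

from trimerbias import (
    TrimerUsageClassifier,
    generate_refdb_fixture,
)
from trimerbias.simulate import (
    default_taxon_layout,
    generate_genus_sequences,
    make_profiles,
    sample_fragments,
)


@pytest.fixture(scope="session")
def small_refdb():
    return generate_refdb_fixture(n_trimers=60, seed=11)


@pytest.fixture(scope="session")
def small_layout():
    # first six genera of the default panel: 3 taxon groups
    return default_taxon_layout()[:6]


@pytest.fixture(scope="session")
def cohort(small_refdb, small_layout):
    """Profiles, training data and a fitted trimer-usage classifier."""
    profiles = make_profiles(small_refdb, small_layout, seed=17)
    X, y, db_type = [], [], []
    train = {}
    for p in profiles:
        cds, noncds = generate_genus_sequences(p, small_refdb, n_seqs=15, mean_len=450)
        train[p.genus_id] = {"CDS": cds, "nonCDS": noncds}
        X += cds + noncds
        y += [p.genus_id] * (len(cds) + len(noncds))
        db_type += ["CDS"] * len(cds) + ["nonCDS"] * len(noncds)
    clf = TrimerUsageClassifier(refdb=small_refdb).fit(X, y, db_type=db_type)
    groups = {p.genus_id: p.taxon_group for p in profiles}
    return {
        "refdb": small_refdb,
        "profiles": profiles,
        "train": train,
        "clf": clf,
        "groups": groups,
        "X": X,
        "y": np.asarray(y, dtype=object),
        "db_type": np.asarray(db_type, dtype=object),
    }


@pytest.fixture(scope="session")
def cohort_testset(cohort):
    """Held-out fragments from fresh sequences of the cohort genera."""
    holdout = {}
    for p in cohort["profiles"]:
        cds, noncds = generate_genus_sequences(
            p, cohort["refdb"], n_seqs=4, mean_len=450, seed=p.seed + 5_000
        )
        holdout[p.genus_id] = {"CDS": cds, "nonCDS": noncds}
    return sample_fragments(holdout, cohort["groups"], per_genus=8, seed=23)
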