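"""Shared fixtures: hand-built corpora and synthetic easy-regime worlds.

The "easy regime" is a world whose location-indicative vocabularies are
disjoint and frequently emitted, so a competent classifier exceeds 90%
accuracy — failures there indicate plumbing bugs, not statistical noise.
"""

from __future__ import annotations

import warnings

import pytest

from injloc import (GeneratorConfig, ModelSpec, SplitSpec, split_train_test)
from injloc.harness import FAMILIES, run_model_grid
from injloc.pipeline import (FeatureSettings, build_feature_bundles,
                             prepare_world, tokenize_records)
from injloc.records import partition_by_missingness

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


def easy_config(n_records: int = 1200, seed: int = 42) -> GeneratorConfig:
    return GeneratorConfig(n_records=n_records, years=(2000, 2004),
                           p_location_token=0.5, seed=seed)


@pytest.fixture(scope="session")
def easy_world():
    """(records, truth) from an easy-regime world, exclusions applied and
    locations recoded."""
    return prepare_world(easy_config())


@pytest.fixture(scope="session")
def easy_split(easy_world):
    """missing / train / test record sets plus token lists."""
    rs, truth = easy_world
    missing, nonmissing = partition_by_missingness(rs)
    train, test = split_train_test(nonmissing, SplitSpec(seed=5))
    return {
        "records": rs,
        "truth": truth,
        "missing": missing,
        "train": train,
        "test": test,
        "tok_missing": tokenize_records(missing),
        "tok_train": tokenize_records(train),
        "tok_test": tokenize_records(test),
    }


@pytest.fixture(scope="session")
def easy_bundles(easy_split):
    """All six (scope × construction) feature bundles on the easy world."""
    s = easy_split
    settings = FeatureSettings(min_count=5, embedding_dim=16,
                               embedding_epochs=10)
    return build_feature_bundles(
        s["tok_missing"], s["tok_train"], s["tok_test"],
        list(s["missing"].records["record_id"]),
        list(s["train"].records["record_id"]),
        list(s["test"].records["record_id"]),
        settings, seed=9)


@pytest.fixture(scope="session")
def grid_result(easy_split, easy_bundles):
    """24-cell model grid (4 families × 6 feature sets) on the easy world."""
    specs = [ModelSpec(f, seed=3) for f in FAMILIES]
    return run_model_grid(
        {lbl: (b.train, b.test) for lbl, b in easy_bundles.items()},
        list(easy_split["train"].records["location4"]),
        list(easy_split["test"].records["location4"]),
        specs)


@pytest.fixture()
def toy_corpus():
    """The 3-document corpus used for hand-checked TF-IDF values."""
    return [["A", "B"], ["A", "C"], ["A", "B", "B"]]
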