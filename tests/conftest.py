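import numpy as np
import pytest

from salimet.containers import FeatureMatrix, SampleMetadata
from salimet.simulate import (
    MetaboliteSpec,
    SimulationConfig,
    default_metabolite_specs,
    generate_feature_table,
)


@pytest.fixture(scope="session")
def specs31():
    return default_metabolite_specs()


@pytest.fixture(scope="session")
def strong_dataset():
    """Strong-signal regime: study group sizes, effect multiplier 2."""
    return generate_feature_table(
        cfg=SimulationConfig(effect_multiplier=2.0, seed=11)
    )


@pytest.fixture(scope="session")
def study_dataset():
    """Printed-moments regime (kappa=1), study group sizes."""
    return generate_feature_table(cfg=SimulationConfig(seed=0))


@pytest.fixture
def low_cv_specs():
    """Six well-separated metabolites with coefficient of variation ~0.2,
    so zero-censoring is negligible and exact rank-test paths are exercised."""
    rng = np.random.default_rng(42)
    specs = []
    for i in range(6):
        base = 100.0 * (i + 1)
        specs.append(
            MetaboliteSpec(
                name=f"met{i}",
                mean_B=base * 1.4, sd_B=base * 0.2,
                mean_AT=base, sd_AT=base * 0.2,
                mean_HI=base * 0.8, sd_HI=base * 0.2,
            )
        )
    return specs


def paired_subset(ds):
    """The B/AT samples of a dataset, plus their subject vector."""
    groups = ds.metadata.group_of(ds.features.sample_ids)
    ids = [s for s, g in zip(ds.features.sample_ids, groups) if g in ("B", "AT")]
    fm = ds.features.subset(ids)
    subj = ds.metadata.subjects
    subjects = np.asarray([subj[s] for s in ids], dtype=object)
    return fm, subjects


@pytest.fixture
def tiny_fm_md():
    """4 paired subjects x 3 features, deterministic values."""
    rng = np.random.default_rng(5)
    n_pairs = 4
    ids, records = [], []
    for i in range(n_pairs):
        s = f"S{i}"
        ids += [f"{s}_B", f"{s}_AT"]
        records += [
            {"sample_id": f"{s}_B", "subject_id": s, "group": "B"},
            {"sample_id": f"{s}_AT", "subject_id": s, "group": "AT"},
        ]
    X = rng.normal(10, 2, size=(2 * n_pairs, 3))
    return (
        FeatureMatrix(X, ids, ["f1", "f2", "f3"]),
        SampleMetadata.from_records(records),
    )
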