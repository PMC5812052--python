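import numpy as np
import pytest

from longinterval.core_data import CountTable, FeatureSeries, SampleMetadata


@pytest.fixture
def small_table() -> CountTable:
    counts = np.array([[10.0, 20.0, 5.0, 9.0],
                       [0.0, 3.0, 7.0, 1.0],
                       [2.0, 2.0, 2.0, 2.0]])
    return CountTable(counts, ["otu1", "otu2", "otu3"],
                      ["s1", "s2", "s3", "s4"])


@pytest.fixture
def small_meta() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", "subjA1", "A", 0.0),
        SampleMetadata("s2", "subjA2", "A", 1.0),
        SampleMetadata("s3", "subjB1", "B", 0.0),
        SampleMetadata("s4", "subjB2", "B", 1.0),
    ]


def make_series(times, counts, groups, subjects=None,
                feature_id="f") -> FeatureSeries:
    times = np.asarray(times, dtype=float)
    if subjects is None:
        subjects = [f"{g}{i}" for i, g in enumerate(groups)]
    return FeatureSeries(feature_id, times,
                         np.asarray(groups, dtype=object),
                         np.asarray(subjects, dtype=object),
                         np.asarray(counts, dtype=float))


def longitudinal_series(rng, mu_of_t, n_subjects=10, times=None, group="A",
                        noise="poisson", alpha=5.0):
    """One group's longitudinal draws around a known mean curve."""
    times = np.arange(21.0) if times is None else np.asarray(times, float)
    t_all, y_all, subj = [], [], []
    for i in range(n_subjects):
        mu = mu_of_t(times)
        if noise == "poisson":
            y = rng.poisson(mu)
        else:
            p = alpha / (alpha + mu)
            y = rng.negative_binomial(alpha, p)
        t_all.append(times)
        y_all.append(y)
        subj.extend([f"{group}{i:02d}"] * len(times))
    t = np.concatenate(t_all)
    y = np.concatenate(y_all)
    return make_series(t, y, [group] * len(t), subj)
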