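import numpy as np
import pytest

import cardiocoupling as cc


def small_config(**overrides) -> cc.SyntheticCohortConfig:
    defaults = dict(
        n_per_group={"severe": 4, "mild-moderate": 4, "cpnca": 4},
        n_beats=120,
        seed=0,
    )
    defaults.update(overrides)
    return cc.SyntheticCohortConfig(**defaults)


def rho_config(rho: float, **overrides) -> cc.SyntheticCohortConfig:
    """Config whose 'severe' group carries an arbitrary coupling strength."""
    return small_config(
        coupling_rho={"severe": rho, "mild-moderate": 0.5, "cpnca": 0.8},
        **overrides)


def rri_sti_pair(rho: float, seed: int, n_beats: int = 300) -> cc.SeriesPair:
    """Z-normalized RRI-STI pair at a given coupling strength."""
    cfg = rho_config(rho, n_beats=n_beats)
    s = cc.gen_interval_series(cfg, "severe", seed=seed)
    return cc.SeriesPair("RRI", "STI",
                         cc.znormalize(s.rri), cc.znormalize(s.sti))


def random_pair(rng: np.random.Generator, n: int) -> cc.SeriesPair:
    return cc.SeriesPair("RRI", "STI",
                         cc.znormalize(rng.normal(size=n)),
                         cc.znormalize(rng.normal(size=n)))


@pytest.fixture(scope="session")
def power_cohort_features():
    """Entropy-feature matrix for a 3-group cohort whose extreme groups
    differ in coupling strength by 0.6 (n=60/group, 300 beats)."""
    cfg = cc.SyntheticCohortConfig(
        n_per_group={"severe": 60, "mild-moderate": 60, "cpnca": 60},
        coupling_rho={"severe": 0.2, "mild-moderate": 0.5, "cpnca": 0.8},
        seed=7,
    )
    cohort = cc.gen_cohort(cfg)
    return cc.extract_cohort_features(cohort.subjects, families=("entropy",))


@pytest.fixture
def valid_subject_series() -> cc.IntervalSeriesSet:
    return cc.gen_interval_series(small_config(n_beats=200), "cpnca", seed=11)
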