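import numpy as np
import pytest

from rdrbc import TrialData, build_design, example_layout_trial
from rdrbc.simulate import SyntheticConfig, generate_trial


def small_config(**over):
    """Small J=3 covered-layout study used throughout the pipeline tests."""
    kw = dict(
        n_ref=40,
        n_act=40,
        n_visits=3,
        mu=np.array([[-1.0, -2.0, -3.0], [-2.0, -4.0, -6.0]]),
        sigma=np.sqrt(np.array([4.0, 5.0, 6.0]))[:, None]
        * (0.5 ** np.abs(np.subtract.outer(np.arange(3), np.arange(3))))
        * np.sqrt(np.array([4.0, 5.0, 6.0]))[None, :],
        baseline_mean=18.0,
        baseline_sd=5.0,
        baseline_effect=-0.2,
        dev_hazard=np.array([[0.12, 0.12], [0.12, 0.12]]),
        stop_prob=(0.4, 0.4),
        truth="j2r",
    )
    kw.update(over)
    return SyntheticConfig(**kw)


def covered_trial(seed0: int = 0, **over):
    """A realisation where every deviation stratum has observed
    off-treatment data (no holes), found by scanning seeds."""
    cfg = small_config(**over)
    for seed in range(seed0, seed0 + 50):
        data, truth = generate_trial(cfg, seed=seed)
        design = build_design(data, "J2R", "historic", check=False)
        if not design.never_observed:
            return data, truth
    raise RuntimeError("no fully covered realisation found")


@pytest.fixture(scope="session")
def covered_small():
    return covered_trial()


@pytest.fixture(scope="session")
def example_covered():
    return example_layout_trial("covered", seed=0)


@pytest.fixture(scope="session")
def mmrm_big():
    """Large MAR-truth trial plus its repeated-measures fit (shared by the
    recovery tests)."""
    from rdrbc import mmrm_reference_fit

    cfg = SyntheticConfig(n_ref=500, n_act=500, truth="mar")
    data, truth = generate_trial(cfg, seed=3)
    return data, truth, mmrm_reference_fit(data)


def simple_two_visit_trial(
    n_on0=50, n_off0=15, n_miss0=15, n_on1=40, n_off1=20, n_miss1=20,
    mu2=(0.0, 1.0), gamma=(0.0, 0.0), seed=11,
):
    """Two-visit trial emulating the one-visit analytic setting at visit 2.

    Visit 1 is fully observed on treatment with mean 0; visit-2 groups have
    means mu2[t] on treatment and mu2[0] + gamma[t] off treatment, unit
    variance, and no cross-visit correlation in the generator.
    """
    rng = np.random.default_rng(seed)
    arm, dev, last, y2mean = [], [], [], []
    for t, (n_on, n_off, n_miss) in enumerate(
        [(n_on0, n_off0, n_miss0), (n_on1, n_off1, n_miss1)]
    ):
        arm += [t] * (n_on + n_off + n_miss)
        dev += [2] * n_on + [1] * (n_off + n_miss)
        last += [2] * (n_on + n_off) + [1] * n_miss
        y2mean += [mu2[t]] * n_on + [mu2[0] + gamma[t]] * (n_off + n_miss)
    n = len(arm)
    y = np.column_stack(
        [rng.standard_normal(n), np.array(y2mean) + rng.standard_normal(n)]
    )
    last = np.array(last)
    y[last == 1, 1] = np.nan
    return TrialData(
        ids=np.array([f"P{i}" for i in range(n)], dtype=object),
        arm=np.array(arm),
        baseline=np.zeros(n),
        y=y,
        dev_visit=np.array(dev),
        last_visit=last,
    )
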