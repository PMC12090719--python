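import numpy as np
import pytest

import spo0areg as s


@pytest.fixture(scope="session")
def truth() -> s.GroundTruth:
    return s.GroundTruth(seed=0)


@pytest.fixture(scope="session")
def signal(truth) -> s.Signal0AP:
    return truth.signal()


@pytest.fixture(scope="session")
def kk_params(truth) -> s.ScenarioParams:
    return truth.scenario_params()


@pytest.fixture(scope="session")
def clean_panel(truth):
    """Noise-free single-replicate activity panel (model means)."""
    return s.gen_activity_panel(truth, noise_cv=0.0, replicates=1)


@pytest.fixture(scope="session")
def noisy_panel(truth):
    """Default study conditions: 5% CV, 3 replicates."""
    return s.gen_activity_panel(truth)


@pytest.fixture(scope="session")
def emsa_data(truth):
    return s.gen_emsa_dataset(truth)


@pytest.fixture(scope="session")
def fast_fit_kwargs(truth):
    """Reduced optimizer budget for in-test scenario fits."""
    return dict(
        kh_vitro=dict(truth.kh_vitro),
        n=4,
        restarts=2,
        de_maxiter=25,
        de_popsize=5,
        als_iters=8,
    )


def random_scenario_params(rng: np.random.Generator, scenario: str) -> s.ScenarioParams:
    """Random valid ScenarioParams draw for property tests."""
    kh = {b: float(rng.uniform(0.05, 1.5)) for b in s.BOXES}
    eps = {p: float(rng.uniform(-4, 2)) for p in s.PAIRS}
    binding = s.BindingParams(n=int(rng.integers(1, 5)), kh=kh, eps=eps)
    a, rho, eta, vms = {}, {}, {}, {}
    for i, p in enumerate(("Pv", "Ps")):
        ctl = scenario[i]
        a[p] = rng.uniform(0.5, 200.0, size=len(s.TIME_GRID))
        if ctl == "K":
            rho[p] = {c: float(rng.uniform(0.0, 3.0)) for c in s.CONFIGS}
            rho[p]["000"] = 1.0
        else:
            a[p] = rng.uniform(0.05, 20.0, size=len(s.TIME_GRID))  # R(t)
            eta[p] = {b: float(rng.uniform(-3, 3)) for b in s.BOXES}
            vms[p] = float(rng.uniform(1.0, 300.0))
    return s.ScenarioParams(
        scenario=scenario, binding=binding, a=a, rho=rho, eta=eta, vmax_scale=vms
    )
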