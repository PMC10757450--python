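import numpy as np
import pytest

from stopsignal.cohort import CohortConfig, ExGauss, ParticipantParams


@pytest.fixture(scope="session")
def config():
    return CohortConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_params(
    rt_mean_sst=492.3,
    rt_mean_go=306.5,
    ssrt=221.9,
    mt_go=509.7,
    mt_ns=443.8,
    sigma=60.0,
    tau=90.0,
    sigma_go=40.0,
    tau_go=60.0,
    mt_sigma=60.0,
    lapse_go=0.0,
    lapse_ns=0.0,
    group="HC",
    treatment="NA",
    pid="P00",
):
    """Hand-built observer with known generative values (HC-like defaults)."""
    return ParticipantParams(
        participant_id=pid,
        group=group,
        treatment=treatment,
        go_only_rt=ExGauss(mu=rt_mean_go - tau_go, sigma=sigma_go, tau=tau_go),
        sst_rt=ExGauss(mu=rt_mean_sst - tau, sigma=sigma, tau=tau),
        ssrt_true=ssrt,
        mt_mu_go_only=mt_go,
        mt_mu_no_stop=mt_ns,
        mt_sigma=mt_sigma,
        lapse_go_only=lapse_go,
        lapse_no_stop=lapse_ns,
    )


@pytest.fixture
def hc_params():
    return make_params()
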