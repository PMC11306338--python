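import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mtgrowth import KineticParams, Trace, constant_profile, simulate_run

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def avrami_trace():
    """Factory for noiseless constant-temperature Avrami traces.

    ``od(t) = od_inf * (1 - exp(-(t/tau)**b)) + baseline`` sampled on a
    regular grid — the closed-form reference curve for every feature test.
    """

    def make(b=2.0, tau=20.0, od_inf=1.5, baseline=0.0, dt=0.01, t_end=None,
             run_id="avrami"):
        t_end = 10.0 * tau if t_end is None else t_end
        t = np.arange(0.0, t_end + 0.5 * dt, dt)
        od = od_inf * (1.0 - np.exp(-np.power(t / tau, b))) + baseline
        return Trace(times=t, od=od, run_id=run_id)

    return make


@pytest.fixture
def simulated_trace():
    """One clean synthetic run at constant temperature (noiseless default)."""

    def make(b_true=2.2, tau_ref=60.0, noise_sd=0.0, temp=34.9, seed=0,
             times=None):
        params = KineticParams(b_true=b_true, tau_ref=tau_ref, noise_sd=noise_sd,
                               cv_tau=0.0, cv_od=0.0, artifact_rate=0.0)
        run = simulate_run(params, constant_profile(temp), times=times, seed=seed)
        return run.to_trace()

    return make
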