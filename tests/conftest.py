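import numpy as np
import pytest

from seapump.attenuation import SeasonalAttenuation
from seapump.integrate import RunConfig, run_to_cycle
from seapump.model_core import make_grid


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(4, 2)


@pytest.fixture(scope="session")
def mid_grid():
    return make_grid(8, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def column_martin_run():
    """Long no-circulation column run with constant b = 1.388.

    Shared by the integrate oracle test and the acceptance criterion; the
    run is expensive (~20 s) so it is computed once per session.
    """
    cfg = RunConfig(
        n_lat=4, n_lon=1, transport_scheme="off", n_years_max=120,
        convergence_tol=1e-12,
        attenuation=SeasonalAttenuation(b_ref=1.388, delta_b=0.0),
    )
    return run_to_cycle(cfg)


@pytest.fixture(scope="session")
def smoke_suite():
    """Reference + four seasonal-phase runs on the hemisphere-symmetric
    smoke grid with circulation on.  Shared by the directional tests."""
    from seapump.diagnostics import global_metrics
    from seapump.experiments import smoke_config

    runs = {}
    labels = [("ref", SeasonalAttenuation(b_ref=1.388, delta_b=0.0))]
    labels += [(f"theta{t:g}", SeasonalAttenuation.from_fraction(frac=0.6, theta=t))
               for t in (0.0, 3.0, 6.0, 9.0)]
    for label, att in labels:
        out = run_to_cycle(smoke_config(attenuation=att, label=label))
        runs[label] = (out, global_metrics(out))
    return runs
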