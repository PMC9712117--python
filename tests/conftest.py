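import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from varvesst.io import SliceInfo, SpotTable

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def build_table(gs, i372=None, i373=None, sn372=None, sn373=None, depth_mm=None,
                x_um=None, ca=None, fe=None, ti=None, si=None, slice_id="A",
                slice_len_mm=50.0, slice_width_mm=4.0, offset_cm=480.0,
                delta_gs=None):
    """Construct a single-slice SpotTable from plain arrays with defaults."""
    gs = np.asarray(gs, float)
    n = len(gs)

    def arr(x, default):
        return np.full(n, default, float) if x is None else np.asarray(x, float)

    df = pd.DataFrame({
        "spot_id": np.arange(n),
        "slice_id": slice_id,
        "x_um": arr(x_um, 200.0),
        "y_um": 0.0,
        "depth_mm": arr(depth_mm, 1.0) if depth_mm is None else np.asarray(depth_mm, float),
        "gs": gs,
        "ca": arr(ca, 50.0), "fe": arr(fe, 50.0),
        "ti": arr(ti, 50.0), "si": arr(si, 50.0),
        "i372": arr(i372, 700.0), "i373": arr(i373, 300.0),
        "sn372": arr(sn372, 10.0), "sn373": arr(sn373, 10.0),
    })
    if delta_gs is not None:
        df["delta_gs"] = np.asarray(delta_gs, float)
        df["background"] = False
    slices = {slice_id: SliceInfo(offset_cm, slice_len_mm, slice_width_mm)}
    return SpotTable(df, slices)


@pytest.fixture
def table_factory():
    return build_table


@pytest.fixture(scope="session")
def small_scenario():
    """80-yr record across the sedimentation-rate transition, narrow slices."""
    from varvesst.simulate import ScenarioConfig

    return ScenarioConfig(age_start=11.70, age_end=11.62, slice_width_mm=1.0,
                          seed=42)


@pytest.fixture(scope="session")
def small_run(small_scenario):
    from varvesst.simulate import simulate_dataset, simulate_truth

    truth = simulate_truth(small_scenario)
    spots = simulate_dataset(truth, seed=small_scenario.seed + 1)
    return truth, spots


@pytest.fixture(scope="session")
def step_scenario():
    """200-yr record with the default 0.8 -> 1.8 degC seasonality step inside."""
    from varvesst.simulate import ScenarioConfig

    return ScenarioConfig(age_start=11.74, age_end=11.54, slice_width_mm=2.0,
                          seed=5)
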