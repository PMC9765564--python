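import numpy as np
import pandas as pd
import pytest

import swimtrack as st


@pytest.fixture(scope="session")
def profiles():
    return st.load_default_profiles()


@pytest.fixture(scope="session")
def strains(profiles):
    return profiles[0]


@pytest.fixture(scope="session")
def envs(profiles):
    return profiles[1]


@pytest.fixture(scope="session")
def wt(strains):
    return strains["wt"]


@pytest.fixture(scope="session")
def motab(strains):
    return strains["d_motAB"]


@pytest.fixture(scope="session")
def motcd(strains):
    return strains["d_motCD"]


@pytest.fixture(scope="session")
def double_mutant(strains):
    return strains["d_motAB_motCD"]


@pytest.fixture(scope="session")
def bulk(envs):
    return envs["bulk"]


@pytest.fixture(scope="session")
def agar25(envs):
    return envs["agar_0.25"]


def constant_speed_trajectory(track_id, speed, duration=5.0, dt=0.05,
                              heading=0.0, origin=(0.0, 0.0)):
    """Straight constant-speed trajectory table."""
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    x = origin[0] + speed * t * np.cos(heading)
    y = origin[1] + speed * t * np.sin(heading)
    return pd.DataFrame(
        {"track_id": track_id, "frame": np.arange(n + 1), "t_s": t,
         "x_um": x, "y_um": y}
    )


@pytest.fixture
def make_constant_trajectory():
    return constant_speed_trajectory
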