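import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_clim  # noqa: E402,F401

from parkclim import core_io, models, synthetic  # noqa: E402


@pytest.fixture(scope="session")
def default_system():
    """The default 50-park study system at a fixed seed, fully simulated."""
    gens = synthetic.make_default_system(seed=42)
    visits, temps = synthetic.simulate_system(gens)
    clims = core_io.build_climatologies(visits, temps, [g.park_id for g in gens])
    return {"gens": gens, "visits": visits, "temps": temps, "clims": clims}


@pytest.fixture(scope="session")
def default_park_fits(default_system):
    return {
        p: models.fit_park_models(c) for p, c in default_system["clims"].items()
    }


@pytest.fixture
def linear_park_clim():
    """Visits an exact linear function of a 12-month temperature cycle."""
    t = 10 + 12 * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12)
    return make_clim("LIN", 1000 + 50 * t, t)
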