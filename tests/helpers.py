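import numpy as np

from parkclim import core_io


def make_clim(park_id, mean_visits, mean_temp, n_years=10):
    """Climatology straight from arrays (se/counts filled in trivially)."""
    mv = np.asarray(mean_visits, float)
    mt = np.asarray(mean_temp, float)
    return core_io.ParkClimatology(
        park_id, mv, np.zeros(12), np.full(12, n_years), mt, np.full(12, n_years)
    )
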