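import numpy as np
import pytest

import muecho as m


@pytest.fixture(scope="session")
def geometry() -> m.MuscleGeometry:
    return m.MuscleGeometry()


@pytest.fixture(scope="session")
def population(geometry) -> list[m.MotorUnit]:
    return m.generate_population(geometry, 200, seed=1)


@pytest.fixture(scope="session")
def single_mu_pipeline(geometry):
    """Noise-free single-MU end-to-end run at a small problem size.

    2.5 s at 256 fps is ample for the noise-free case (the movie is exactly
    rank one) and keeps the suite fast.
    """
    fps, duration = 256.0, 2.5
    twitch = m.make_twitch_profile(fps)
    mu = m.generate_population(geometry, 1, seed=104)[0]
    fp = m.generate_firing_pattern(mu, duration, seed=4)
    tvs = m.condition_tvs(m.simulate_tvs([mu], [fp], geometry, twitch, duration))
    decomps = m.decompose_all(tvs, seed=0)
    ident = m.identify_mu(fp, decomps, geometry, min_sta_spikes=15)
    return {
        "mu": mu,
        "fp": fp,
        "twitch": twitch,
        "duration": duration,
        "tvs": tvs,
        "decomps": decomps,
        "ident": ident,
    }
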