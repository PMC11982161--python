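import numpy as np
import pytest

from speechcoord import DyadSeries, SpeechSeries, StudySimConfig, simulate_study, study_measures


def make_dyad(a, b, dyad_id="d0", task="introduction") -> DyadSeries:
    return DyadSeries(
        SpeechSeries(np.asarray(a, dtype=np.int8), dyad_id, "p1", task),
        SpeechSeries(np.asarray(b, dtype=np.int8), dyad_id, "p2", task),
    )


def random_dyad(rng, n=None, p=0.5, q=0.5) -> DyadSeries:
    n = n if n is not None else int(rng.integers(4, 65))
    return make_dyad(
        (rng.random(n) < p).astype(np.int8), (rng.random(n) < q).astype(np.int8)
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study reused across tests."""
    cfg = StudySimConfig(n_dyads=8, seed=11)
    data = simulate_study(cfg)
    measures = study_measures(data)
    return cfg, data, measures
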