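import numpy as np
import pandas as pd
import pytest

from sabm.panel import SchoolPanel


def make_panel(
    wave1,
    wave2,
    behavior1,
    behavior2,
    covariates=None,
    responded=None,
    school_id="s1",
):
    """Construct a small SchoolPanel from plain lists/arrays."""
    wave1 = np.asarray(wave1)
    n = wave1.shape[0]
    ids = [f"a{i}" for i in range(n)]
    if covariates is None:
        covariates = pd.DataFrame(index=pd.Index(ids, name="actor_id"))
    else:
        covariates = covariates.set_axis(pd.Index(ids, name="actor_id"))
    if responded is None:
        responded = np.ones(n, dtype=bool)
    return SchoolPanel(
        school_id=school_id,
        actor_ids=ids,
        wave1=wave1,
        wave2=np.asarray(wave2),
        behavior1=np.asarray(behavior1),
        behavior2=np.asarray(behavior2),
        covariates=covariates,
        responded_wave2=np.asarray(responded, dtype=bool),
    )


@pytest.fixture
def tiny_panel():
    """Four actors, a little bit of everything: stable, formed and
    dissolved ties, one behavior change."""
    w1 = [[0, 1, 0, 0],
          [1, 0, 1, 0],
          [0, 0, 0, 1],
          [0, 0, 0, 0]]
    w2 = [[0, 1, 1, 0],
          [1, 0, 0, 0],
          [0, 0, 0, 1],
          [0, 0, 0, 0]]
    cov = pd.DataFrame(
        {
            "age": [14.0, 15.0, 16.0, 15.5],
            "male": [1, 0, 1, 0],
            "minority": [0, 1, 0, 0],
            "race": ["white", "black", "white", "asian"],
            "parent_drinking": [1, 2, 1, 3],
            "family_bonding": [4, 5, 3, 4],
        }
    )
    return make_panel(w1, w2, [1, 2, 3, 1], [1, 3, 3, 1], covariates=cov)


@pytest.fixture
def random_panel_factory():
    """Random small panels with all covariates present."""

    def factory(n=12, seed=0, p_tie=0.2, p_nonresponse=0.0):
        rng = np.random.default_rng(seed)
        w1 = (rng.random((n, n)) < p_tie).astype(np.int8)
        w2 = (rng.random((n, n)) < p_tie).astype(np.int8)
        np.fill_diagonal(w1, 0)
        np.fill_diagonal(w2, 0)
        cov = pd.DataFrame(
            {
                "age": np.round(rng.uniform(12, 18, n), 2),
                "male": rng.integers(0, 2, n),
                "minority": rng.integers(0, 2, n),
                "race": rng.choice(["white", "black", "hispanic"], n),
                "parent_drinking": rng.integers(1, 6, n),
                "family_bonding": rng.integers(1, 6, n),
            }
        )
        responded = rng.random(n) >= p_nonresponse
        return make_panel(
            w1, w2, rng.integers(1, 7, n), rng.integers(1, 7, n),
            covariates=cov, responded=responded,
        )

    return factory
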