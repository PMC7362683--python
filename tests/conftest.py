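"""Shared fixtures and independent oracles."""

import numpy as np
import pytest
from hypothesis import settings

import aldlca as a

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return a.mhas_schedule()


@pytest.fixture(scope="session")
def small_pop():
    """Desk-scale synthetic population used by most integration tests."""
    cfg = a.SyntheticConfig(n_baseline=1500, n_refresh=400, seed=11)
    return a.generate_population(cfg)


@pytest.fixture(scope="session")
def small_ald(small_pop, schedule):
    return a.group_cohorts(a.rearrange(small_pop.panel, schedule))


@pytest.fixture(scope="session")
def small_model(small_ald):
    return a.fit(small_ald, 3, n_starts=5, seed=3)


def make_complete_ald(values: np.ndarray) -> a.ALDMatrix:
    """Complete-data ALD matrix from an (n_persons, n_items) 0/1 array,
    one time point."""
    values = np.asarray(values, dtype=np.uint8)[:, :, None]
    n = values.shape[0]
    return a.ALDMatrix(
        values=values,
        observed=np.ones_like(values, dtype=bool),
        person_id=np.arange(1, n + 1),
        cohort=np.ones(n, dtype=int),
    )


def grid_oracle_loglik_2class_2item(data: np.ndarray) -> float:
    """Independent grid-search maximizer of the 2-class, 2-item mixture
    log-likelihood over its 5 free parameters (pi, a1, a2, b1, b2).

    Coarse 0.05 grid over the open unit cube, then two local refinements
    down to step 0.001 around the incumbent.  Never calls the EM code.
    """
    data = np.asarray(data, dtype=int)
    counts = {}
    for x1, x2 in data[:, :2]:
        counts[(int(x1), int(x2))] = counts.get((int(x1), int(x2)), 0) + 1

    def evaluate(axes):
        pi, a1, a2, b1, b2 = np.meshgrid(*axes, indexing="ij", sparse=True)
        ll = 0.0
        for (x1, x2), n in counts.items():
            pa = (a1 if x1 else 1 - a1) * (a2 if x2 else 1 - a2)
            pb = (b1 if x1 else 1 - b1) * (b2 if x2 else 1 - b2)
            ll = ll + n * np.log(pi * pa + (1 - pi) * pb)
        idx = np.unravel_index(np.argmax(ll), ll.shape)
        return float(ll[idx]), [float(ax[i]) for ax, i in zip(axes, idx)]

    axes = [np.arange(0.025, 1.0, 0.05)] * 5
    best_ll, best = evaluate(axes)
    for step, half in ((0.01, 0.06), (0.001, 0.012)):
        axes = [
            np.clip(np.arange(c - half, c + half + step / 2, step), 1e-4, 1 - 1e-4)
            for c in best
        ]
        best_ll, best = evaluate(axes)
    return best_ll
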