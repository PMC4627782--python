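import numpy as np
import pytest

from rsnlong import GroundTruth, make_calendar, simulate_sessions
from rsnlong.gica import volume_to_data_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study_calendar():
    """The study's weekly calendar: 158 observed sessions across 185 weeks."""
    return make_calendar(185, 158, seed=1)


@pytest.fixture(scope="session")
def toy_study():
    """Small noiseless multi-session study with 3 known spatial sources."""
    cal = make_calendar(5, 5, seed=0)
    return simulate_sessions(
        cal, n_sources=3, dims=(10, 10, 6), n_frames=40, snr=np.inf, seed=0
    )


@pytest.fixture(scope="session")
def toy_study_noisy():
    cal = make_calendar(6, 6, seed=0)
    return simulate_sessions(
        cal, n_sources=3, dims=(10, 10, 6), n_frames=40, snr=10.0, seed=0
    )


@pytest.fixture(scope="session")
def toy_data_matrices(toy_study_noisy):
    return [
        volume_to_data_matrix(v, toy_study_noisy.mask)
        for v in toy_study_noisy.sessions
    ]


def matched_abs_corr(true_rows: np.ndarray, est_rows: np.ndarray) -> np.ndarray:
    """|Pearson r| of each true row with its greedily assigned estimate."""
    from scipy.optimize import linear_sum_assignment

    tz = (true_rows - true_rows.mean(1, keepdims=True)) / true_rows.std(1, keepdims=True)
    ez = (est_rows - est_rows.mean(1, keepdims=True)) / est_rows.std(1, keepdims=True)
    c = np.abs(tz @ ez.T / true_rows.shape[1])
    ri, ci = linear_sum_assignment(-c)
    return c[ri, ci]


@pytest.fixture
def white_noise_series(study_calendar):
    def _make(seed: int, sd: float = 1.0):
        from rsnlong import simulate_outcome_series

        return simulate_outcome_series(
            study_calendar, GroundTruth(noise_sd=sd, seed=seed)
        )

    return _make
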