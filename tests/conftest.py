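import numpy as np
import pytest

from leptindrive.containers import DAYS_PER_MONTH, DietSchedule, WeightSeries
from leptindrive.model import ModelParams, weight_closed_form


@pytest.fixture
def subject_a_params() -> ModelParams:
    """Parameter set of the first reference subject (printed estimates)."""
    return ModelParams(D=2586.0, alpha=0.303, beta=3.68e-3, gamma=40.1,
                       delta=0.405, eta=0.303 * 3.68e-3 / 40.1, Q0=2571.0,
                       epsilons=(1.00e-7,), W_ref=157.0)


@pytest.fixture
def wellposed_truth() -> ModelParams:
    """A generating parameter set whose trajectory is curved enough over an
    80-month record that the identifiable triple (plateau, amplitude, eps)
    is numerically well determined."""
    return ModelParams(D=2601.3, delta=0.35, eta=5e-4, Q0=2500.0,
                       epsilons=(2.5e-6,))


@pytest.fixture
def wellposed_series(wellposed_truth) -> WeightSeries:
    months = np.arange(81.0)
    w = weight_closed_form(months * DAYS_PER_MONTH, wellposed_truth)
    return WeightSeries(months, w)


@pytest.fixture
def toy_schedule() -> DietSchedule:
    return DietSchedule.from_pairs([(3, 5), (10, 12)])
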