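import numpy as np
import pytest

from teleflux.turnover import TurnoverObservables, params_from_observables


@pytest.fixture(scope="session")
def standard_observables() -> TurnoverObservables:
    """The standard long-lived turnover model (protein 27 h, mRNA 9 h,
    means 1000/17, promoter mean ON/OFF 0.1/2.6 h)."""
    return TurnoverObservables(
        mean_protein=1000.0,
        mean_mrna=17.0,
        protein_half_life=27.0,
        mrna_half_life=9.0,
        t_on=0.1,
        t_off=2.6,
    )


@pytest.fixture(scope="session")
def standard_params(standard_observables):
    return params_from_observables(standard_observables)


@pytest.fixture(scope="session")
def short_lived_slow_switching():
    """Short-lived protein/mRNA (0.4/1.0 h) with slow promoter switching
    (mean ON 16 h, OFF 24 h): the large-rare-fluctuation regime."""
    return params_from_observables(
        TurnoverObservables(
            mean_protein=1000.0,
            mean_mrna=17.0,
            protein_half_life=0.4,
            mrna_half_life=1.0,
            t_on=16.0,
            t_off=24.0,
        )
    )


def empirical_se_of_var(x: np.ndarray) -> float:
    """Standard error of the sample variance (moment-based, no normality)."""
    n = len(x)
    m4 = np.mean((x - x.mean()) ** 4)
    return float(np.sqrt(max(m4 - x.var() ** 2, 0.0) / n))
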