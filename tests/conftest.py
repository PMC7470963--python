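import numpy as np
import pytest

from brudecay import analyze_condition, simulate_cohort, simulate_experiment


@pytest.fixture(scope="session")
def cohort50():
    """Small reproducible cohort shared by read-level and pipeline tests."""
    return simulate_cohort(50, seed=7)


@pytest.fixture(scope="session")
def cohort500():
    """Default-scale cohort for recovery statistics."""
    return simulate_cohort(500, seed=1)


@pytest.fixture(scope="session")
def fitted500(cohort500):
    """Both conditions of the default cohort fitted at depth 1e6."""
    libs, man = simulate_experiment(cohort500, depth=1e6, seed=1)
    rest = analyze_condition(libs, man, "resting")
    act = analyze_condition(libs, man, "activated")
    return cohort500, rest, act


def make_timecourse(times, x, iri=None, x_ee=None, x_ei=None, gene_id="g", condition="resting"):
    from brudecay.normalize import TimeCourse

    times = np.asarray(times, dtype=float)
    n = times.size
    return TimeCourse(
        gene_id=gene_id,
        condition=condition,
        times=times,
        x=np.asarray(x, dtype=float),
        iri=np.asarray(iri if iri is not None else np.zeros(n), dtype=float),
        x_ee=np.asarray(x_ee if x_ee is not None else np.zeros(n), dtype=float),
        x_ei=np.asarray(x_ei if x_ei is not None else np.zeros(n), dtype=float),
    )
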