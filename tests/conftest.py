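"""Shared fixtures: the expensive solver runs are session-scoped."""

import warnings

import pytest

from reboa_hemo.config import default_scenario
from reboa_hemo.pipeline import run_scenario


@pytest.fixture(scope="session")
def phase_runs():
    """All four physiologic phases on the coarse grid, three cycles each.

    Three cycles are enough for the cycle-mean and wall-shear orderings
    compared by the study-level tests; the full periodicity loop is
    exercised separately by the baseline run fixture.
    """
    out = {}
    for phase in ("baseline", "hemorrhage", "f_reboa", "p_reboa"):
        cfg = default_scenario(phase)
        cfg.numerics.max_cycles = 3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[phase] = run_scenario(cfg)
    return out


@pytest.fixture(scope="session")
def baseline_periodic_run():
    """Baseline scenario advanced to cycle-to-cycle periodicity (or the
    cycle cap), used for residual and conservation checks."""
    cfg = default_scenario("baseline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scenario(cfg)


@pytest.fixture(scope="session")
def baseline_calibration():
    """Distal-pressure calibration of the baseline scenario against a
    synthetic reference recording (cohort seed 42, 10 cycles)."""
    from reboa_hemo.validation import baseline_calibration_max_error

    err, history = baseline_calibration_max_error(cohort_seed=42,
                                                  n_cycles=10, tol=0.05)
    return err, history
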