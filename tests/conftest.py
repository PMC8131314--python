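import numpy as np
import pytest

import emadyn as ed


@pytest.fixture(scope="session")
def design():
    """Nominal protocol design: 08:00-22:59 waking window, 3-hour interval,
    5 prompts/day, 42 days."""
    return ed.StudyDesign(subject_id="t001")


@pytest.fixture(scope="session")
def null_dgp_2var():
    return ed.null_dgp(("fatigue", "worry"))


@pytest.fixture(scope="session")
def dataset_full(design, null_dgp_2var):
    """Fully answered two-variable white-noise dataset."""
    return ed.simulate_subject(design, null_dgp_2var, seed=101)


@pytest.fixture(scope="session")
def dataset_default(design):
    """Default DGP with decaying compliance applied."""
    dgp = ed.default_dgp()
    full = ed.simulate_subject(design, dgp, seed=11)
    return ed.apply_missingness(full, dgp, seed=12)


def toy_adjusted(values_by_var, per_day=4):
    """Build AdjustedSeries by hand on a small complete grid (values given
    as dict name -> 1-D array; length must be a multiple of per_day)."""
    out = []
    for name, vals in values_by_var.items():
        vals = np.asarray(vals, dtype=float)
        n = len(vals)
        assert n % per_day == 0
        out.append(
            ed.AdjustedSeries(
                variable=name,
                residual=vals,
                removed_trend=np.zeros(n),
                removed_slot=np.zeros(n),
                removed_weekend=np.zeros(n),
                slot_effects={},
                weekend_offset=0.0,
                residual_sd=float(np.std(vals, ddof=1)),
                day_index=np.arange(n) // per_day,
                slot_of_day=np.arange(n) % per_day,
                per_day_count=per_day,
            )
        )
    return out
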