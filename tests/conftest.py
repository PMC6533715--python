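import numpy as np
import pytest

from esilung import CohortSpec, cohort_table, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort (57/58/79, seed 1) with fitted scores.

    Session-scoped: generating and scoring 194 curves takes on the order of
    a minute, and several end-to-end checks share it.
    """
    records = generate_cohort(CohortSpec(seed=1))
    return records, cohort_table(records)


@pytest.fixture(scope="session")
def small_cohort():
    """Small unfitted cohort for structural checks."""
    records = generate_cohort(CohortSpec(n_ne=8, n_me=8, n_se=10, seed=3,
                                         fit_curves=False))
    return records, cohort_table(records)


@pytest.fixture()
def triangle_curve():
    """Flow rises linearly to PEF=8 L/s at V=0.8 L, falls linearly to 0 at
    V=4.8 L: the descending limb normalizes to the identity q(u) = u."""
    from esilung import MEFVCurve

    v_up = np.linspace(0.0, 0.8, 9)[:-1]
    v_dn = np.linspace(0.8, 4.8, 41)
    v = np.concatenate([v_up, v_dn])
    f = np.where(v <= 0.8, 8.0 * v / 0.8, 8.0 * (4.8 - v) / 4.0)
    return MEFVCurve(volume_l=v, flow_l_s=f)
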