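import numpy as np
import pandas as pd
import pytest

import riskstand as rs


@pytest.fixture(scope="session")
def two_factor_frame() -> pd.DataFrame:
    """Small deterministic two-centre table with two factors and a known
    event pattern (rates vary by cell so fits are well behaved)."""
    rng = np.random.default_rng(1234)
    rows = []
    rates = {("old", "F"): 0.55, ("old", "M"): 0.45, ("young", "F"): 0.25, ("young", "M"): 0.15}
    for centre, n in (("alpha", 300), ("beta", 260)):
        for i in range(n):
            age = "old" if rng.random() < (0.6 if centre == "alpha" else 0.4) else "young"
            sex = "F" if rng.random() < 0.5 else "M"
            event = int(rng.random() < rates[(age, sex)])
            rows.append((centre, event, age, sex))
    return pd.DataFrame(rows, columns=["centre", "event", "age_band", "sex"])


@pytest.fixture(scope="session")
def two_factor_cohort(two_factor_frame) -> rs.Cohort:
    spec = rs.CovariateSpec(factors=("age_band", "sex"))
    return rs.cohort_from_frame(two_factor_frame, spec)


@pytest.fixture(scope="session")
def multicentre_cohort() -> rs.Cohort:
    """Nine centres at emergency-admission scale (~2000 patients, ~5-6%
    event rate), with a continuous age covariate."""
    return rs.generate_cohort(rs.make_multicentre_spec(seed=20240117))


@pytest.fixture(scope="session")
def multicentre_pipeline(multicentre_cohort):
    """Fitted model, risks, K=10 equal-observed-events scheme and
    patient-proportion weights for the nine-centre cohort."""
    cohort = multicentre_cohort
    model = rs.fit_risk_model(
        cohort, rs.ModelSpec(factors=("severity",), continuous=("age",))
    )
    risks = model.predict(cohort)
    scheme = rs.build_risk_categories(risks, cohort.events, K=10)
    weights = rs.category_weights(scheme, risks, cohort.events)
    return cohort, model, risks, scheme, weights
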