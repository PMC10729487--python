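import numpy as np
import pytest

import adbrainage as ab


def attach_bag(table, harmonized=False):
    """Calibrate on NC rows and append a measured-BAG column."""
    if harmonized:
        from adbrainage.pipeline import apply_site_eligibility
        table = apply_site_eligibility(table)
    model = ab.fit_calibration(table[table["group"] == "NC"])
    corrected = ab.apply_calibration(model,
                                     table["raw_predicted_age"].to_numpy())
    out = table.copy()
    if harmonized:
        from adbrainage.pipeline import _encode_harmonization_covariates
        cov = _encode_harmonization_covariates(
            out, ["age", "sex", "education", "group", "eyo", "apoe4",
                  "variant"])
        bm = ab.fit_combat(corrected, out["site_id"], cov)
        corrected = ab.apply_combat(bm, corrected, out["site_id"], cov)
    out["bag"] = ab.compute_bag(corrected, out["age"].to_numpy())
    return out


@pytest.fixture(scope="session")
def default_cohort():
    return ab.generate_cohort(ab.CohortSpec(), seed=1234)


@pytest.fixture(scope="session")
def cohort_with_bag(default_cohort):
    return attach_bag(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
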