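import numpy as np
import pandas as pd
import pytest

from hargmr import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest synthetic cohort reused by read-only tests."""
    return generate_cohort(CohortParams(n_participants=1200, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170425)


def summary_frame(rsids, eas, oas, betas, ses, n=10_000, eaf=None):
    """Build a summary-statistics table by hand for harmonization tests."""
    from scipy import stats

    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": eas,
            "other_allele": oas,
            "beta": betas,
            "se": ses,
            "pvalue": 2 * stats.norm.sf(np.abs(betas / ses)),
            "n": n,
        }
    )
    if eaf is not None:
        df["eaf"] = eaf
    return df
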