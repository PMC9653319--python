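import numpy as np
import pandas as pd
import pytest

from rgcest import DEFAULT_PROFILES, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """A reference-sized synthetic cohort: 25 subjects, 50 eyes."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    """200 subjects (400 eyes) for estimation-accuracy checks."""
    config = SyntheticConfig(
        n_subjects={"healthy": 120, "GS": 40, "PPG": 40}, seed=7
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def table1_cohort() -> pd.DataFrame:
    """Zero-variance cohort pinned exactly at the reference group means."""
    rows = []
    sid = 0
    for group, n in (("healthy", 15), ("GS", 5), ("PPG", 5)):
        p = DEFAULT_PROFILES[group]
        for _ in range(n):
            sid += 1
            for eye in ("OD", "OS"):
                rows.append(
                    {
                        "subject_id": f"S{sid:03d}",
                        "eye": eye,
                        "group": group,
                        "age_years": p.mean("age_years"),
                        "iop_mmhg": p.mean("iop_mmhg"),
                        "md_db": p.mean("md_db"),
                        "arnflt_um": p.mean("arnflt_um"),
                        "mag_uv": p.mean("mag_uv"),
                        "magd_uv": p.mean("magd_uv"),
                        "ergc_csfi": p.mean("ergc_csfi"),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
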