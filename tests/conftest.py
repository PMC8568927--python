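import numpy as np
import pandas as pd
import pytest

import clonetrace as ct
from clonetrace.filtering import apply_strict_filters
from clonetrace.signature_bank import synthetic_signature_bank


@pytest.fixture(scope="session")
def bank():
    return synthetic_signature_bank()


@pytest.fixture(scope="session")
def patient1_clean():
    """Noise-free Patient-1-architecture cohort (6 primaries, C seeds
    G-K through a 667-SNV trunk)."""
    return ct.simulate_cohort(ct.patient1_config(seed=11, noise=False))


@pytest.fixture(scope="session")
def patient1_strict(patient1_clean):
    return {s: apply_strict_filters(df)[0] for s, df in patient1_clean.calls.items()}


@pytest.fixture(scope="session")
def contamination_cohort():
    """Donor A leaks 66 trace variants into metastasis C (noise on)."""
    return ct.simulate_cohort(ct.contamination_config(seed=11))


def strict_all(cohort):
    return {s: apply_strict_filters(df)[0] for s, df in cohort.calls.items()}


def clean_calls(n=4, chrom="chr1", start=1000):
    """A small table of calls that pass every strict rule."""
    rows = []
    for i in range(n):
        rows.append(
            {
                "chrom": chrom,
                "pos": start + 100 * i,
                "ref": "C",
                "alt": "T",
                "vaf": 0.4,
                "depth": 40,
                "alt_fwd": 8,
                "alt_rev": 8,
                "in_normal": False,
                "normal_depth": 35,
                "caller_set": "mutect,varscan",
                "context": "ACA",
            }
        )
    return pd.DataFrame(rows)
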