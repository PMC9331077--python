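import numpy as np
import pandas as pd
import pytest

import duplexmut as dm
from duplexmut.channels import CHANNELS_96


@pytest.fixture(scope="session")
def default_cohort() -> dm.SyntheticCohort:
    """One default-configuration cohort shared by read-only tests."""
    return dm.generate_cohort(dm.default_bap_config(seed=11))


@pytest.fixture(scope="session")
def unique_mutations(default_cohort):
    unique, _ = dm.deduplicate(default_cohort.mutations)
    return unique


@pytest.fixture(scope="session")
def tiny_panel():
    """Two short targets with fixed sequences for I/O and CpG tests."""
    return [
        dm.PanelTarget(
            name="t1", chrom="chrA", start=100, end=148,
            region_class="genic", chromatin="euchromatin",
            sequence="TTCGAATTCGAAACGTACGTACGTTTTTAAAACCCCGGGGTTTTAAAA",
        ),
        dm.PanelTarget(
            name="t2", chrom="chrB", start=500, end=548,
            region_class="intergenic", chromatin="heterochromatin",
            sequence="ACGTACGTACGTAAAATTTTCCCCGGGGACGTACGTACGTAAAATTTT",
        ),
    ]


@pytest.fixture
def per_sample_percent():
    """Per-sample 96-channel percentages from a cohort's deduplicated SNVs."""

    def _build(cohort: dm.SyntheticCohort) -> pd.DataFrame:
        unique, _ = dm.deduplicate(cohort.mutations)
        return dm.percent_spectra(dm.per_sample_channel_counts(unique))

    return _build
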