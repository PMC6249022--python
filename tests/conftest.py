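import numpy as np
import pandas as pd
import pytest

import sigassoc as sa


@pytest.fixture(scope="session")
def toy_sig():
    """Three sparse synthetic signatures with partially overlapping support."""
    return sa.toy_signature_matrix(n_signatures=3, seed=1)


@pytest.fixture(scope="session")
def mixed_cohort():
    """A small mixed cohort (linked + null drivers) with fitted exposures.

    Session-scoped because several suites reuse it; everything downstream
    of the fixed seed is deterministic.
    """
    config = sa.preset_config("mixed", n_types=2, n_samples=300, seed=3)
    catalogs, calls, truth = sa.simulate_cohort(config, master_seed=3)
    exposures = sa.fit_cohort_exposures(catalogs, config.signature_matrix)
    return config, catalogs, calls, truth, exposures


def mutation_frame(rows):
    """Build a records DataFrame from (sample, patient, type, chrom, pos,
    ref, alt, class, context) tuples, with blanks for annotation columns."""
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "patient_id", "cancer_type", "chrom", "pos",
            "ref", "alt", "variant_class", "context3",
        ],
    )
    for col in ("gene", "protein_change", "coding_change"):
        df[col] = ""
    df["pon_filtered"] = False
    return df


@pytest.fixture
def simple_records():
    return mutation_frame(
        [
            ("s1", "p1", "UCEC", "chr1", 100, "C", "T", "other", "ACA"),
            ("s1", "p1", "UCEC", "chr1", 200, "C", "T", "other", "ACA"),
            ("s1", "p1", "UCEC", "chr1", 300, "C", "T", "missense", "TCA"),
            ("s2", "p2", "UCEC", "chr2", 50, "A", "AT", "indel", ""),
        ]
    )
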