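"""Driver-curation cascade: recurrence, annotation paths, call matrix."""

import numpy as np
import pandas as pd
import pytest

import sigassoc as sa
from sigassoc.channels import canonical_channel
from sigassoc.drivers import driver_key, drivers_to_frame, frame_to_drivers

from conftest import mutation_frame


def cohort_of(n_per_type):
    """sample_id -> cancer_type Series, samples named <type>_<i>."""
    pairs = [
        (f"{t}_{i}", t) for t, n in n_per_type.items() for i in range(n)
    ]
    return pd.Series({s: t for s, t in pairs}, name="cancer_type")


def records_for(identity_samples):
    """Records from {(chrom,pos,ref,alt,gene,vclass,ctx): [sample ids]}."""
    rows = []
    for (chrom, pos, ref, alt, gene, vclass, ctx), samples in identity_samples.items():
        for s in samples:
            rows.append((s, f"pat_{s}", s.split("_")[0], chrom, pos, ref, alt, vclass, ctx))
    df = mutation_frame(rows)
    df["gene"] = [
        gene
        for (chrom, pos, ref, alt, gene, vclass, ctx), samples in identity_samples.items()
        for _ in samples
    ]
    return df


class TestRecurrentCandidates:
    def test_fraction_threshold_is_strict(self):
        cohort = cohort_of({"A": 100})
        recs = records_for(
            {
                ("1", 10, "C", "T", "G1", "missense", "ACA"): [f"A_{i}" for i in range(4)],
                ("1", 20, "C", "T", "G2", "missense", "ACA"): [f"A_{i}" for i in range(3)],
            }
        )
        out = sa.recurrent_candidates(recs, cohort, min_fraction=0.035)
        assert out == {driver_key("1", 10, "C", "T")}  # 4% > 3.5%; 3% is not

    def test_non_coding_classes_never_qualify(self):
        cohort = cohort_of({"A": 10})
        recs = records_for(
            {("1", 10, "C", "T", "G1", "other", "ACA"): [f"A_{i}" for i in range(9)]}
        )
        assert sa.recurrent_candidates(recs, cohort) == set()

    def test_recurrence_in_any_single_type_suffices(self):
        cohort = cohort_of({"A": 100, "B": 100})
        recs = records_for(
            {
                ("1", 10, "C", "T", "G1", "missense", "ACA"):
                    [f"A_{i}" for i in range(10)],  # 10% in A, absent in B
            }
        )
        assert len(sa.recurrent_candidates(recs, cohort)) == 1

    def test_matches_hand_enumeration_on_three_types(self):
        cohort = cohort_of({"A": 50, "B": 40, "C": 60})
        spec = {
            ("1", 1, "C", "T", "G1", "missense", "ACA"):
                [f"A_{i}" for i in range(2)],            # 4% in A -> keep
            ("1", 2, "C", "A", "G2", "stop_gain", "ACA"):
                [f"B_{i}" for i in range(1)],            # 2.5% in B -> drop
            ("1", 3, "C", "G", "G3", "missense", "ACA"):
                [f"C_{i}" for i in range(3)],            # 5% in C -> keep
        }
        out = sa.recurrent_candidates(records_for(spec), cohort)
        assert out == {driver_key("1", 1, "C", "T"), driver_key("1", 3, "C", "G")}


def toy_cascade_setup():
    """Ten identities exercising every branch of the cascade."""
    cohort = cohort_of({"A": 100})
    samples = lambda n: [f"A_{i}" for i in range(n)]  # noqa: E731
    spec = {
        # path A: recurrent (12%), CGC gene, deep, CGI-designated -> kept
        ("1", 1, "C", "T", "CGC1", "missense", "ACA"): samples(12),
        # path A but not CGI-designated -> dropped
        ("1", 2, "C", "T", "CGC1", "missense", "ACA"): samples(12),
        # path A gene not in CGC; IntOGen count 4 (< 5) -> dropped
        ("1", 3, "C", "T", "OTHER", "missense", "ACA"): samples(12),
        # path B: IntOGen 5, deep (11 > 10), CGI -> kept
        ("1", 4, "C", "T", "OTHER", "missense", "ACA"): samples(11),
        # path B boundary: exactly 10 cohort samples (not > 10) -> dropped
        ("1", 5, "C", "T", "OTHER", "missense", "ACA"): samples(10),
        # indel: would pass B otherwise -> dropped
        ("1", 6, "C", "CT", "CGC1", "indel", ""): samples(20),
        # splice: would pass A otherwise -> dropped
        ("1", 7, "C", "T", "CGC1", "splice", "ACA"): samples(20),
        # path A boundary: recurrent but only 10 cohort samples -> dropped
        ("1", 8, "C", "T", "CGC2", "missense", "ACA"): samples(10),
        # passes both paths -> kept once (dedup)
        ("1", 9, "C", "T", "CGC2", "stop_gain", "TCA"): samples(15),
        # not recurrent, no IntOGen entry -> dropped
        ("1", 10, "C", "T", "CGC1", "missense", "ACA"): samples(2),
    }
    records = records_for(spec)
    resources = sa.AnnotationResources(
        cgc_genes={"CGC1", "CGC2"},
        intogen_counts={
            driver_key("1", 3, "C", "T"): 4,
            driver_key("1", 4, "C", "T"): 5,
            driver_key("1", 5, "C", "T"): 9,
            driver_key("1", 6, "C", "CT"): 50,
            driver_key("1", 9, "C", "T"): 8,
        },
        cgi_drivers={
            driver_key("1", 1, "C", "T"),
            driver_key("1", 3, "C", "T"),
            driver_key("1", 4, "C", "T"),
            driver_key("1", 5, "C", "T"),
            driver_key("1", 6, "C", "CT"),
            driver_key("1", 7, "C", "T"),
            driver_key("1", 8, "C", "T"),
            driver_key("1", 9, "C", "T"),
        },
    )
    return records, resources, cohort


class TestCascadeFilter:
    def test_matches_hand_enumeration(self):
        records, resources, cohort = toy_cascade_setup()
        candidates = sa.recurrent_candidates(records, cohort)
        final = sa.cascade_filter(records, candidates, resources, cohort)
        assert {d.key for d in final} == {
            driver_key("1", 1, "C", "T"),
            driver_key("1", 4, "C", "T"),
            driver_key("1", 9, "C", "T"),
        }

    def test_channels_come_from_canonical_contexts(self):
        records, resources, cohort = toy_cascade_setup()
        candidates = sa.recurrent_candidates(records, cohort)
        for d in sa.cascade_filter(records, candidates, resources, cohort):
            ctx = "ACA" if d.pos != 9 else "TCA"
            assert d.channel == canonical_channel(d.ref, d.alt, ctx)

    def test_monotone_in_thresholds(self):
        records, resources, cohort = toy_cascade_setup()
        candidates = sa.recurrent_candidates(records, cohort)
        base = {
            d.key
            for d in sa.cascade_filter(records, candidates, resources, cohort)
        }
        for kwargs in (
            {"min_cohort_samples": 12},
            {"min_intogen": 6},
        ):
            tighter = {
                d.key
                for d in sa.cascade_filter(
                    records, candidates, resources, cohort, **kwargs
                )
            }
            assert tighter <= base
        fewer_candidates = sa.recurrent_candidates(records, cohort, min_fraction=0.13)
        assert fewer_candidates <= candidates

    def test_invariant_to_record_order(self):
        records, resources, cohort = toy_cascade_setup()
        candidates = sa.recurrent_candidates(records, cohort)
        shuffled = records.sample(frac=1, random_state=9)
        a = [d.key for d in sa.cascade_filter(records, candidates, resources, cohort)]
        b = [d.key for d in sa.cascade_filter(shuffled, candidates, resources, cohort)]
        assert a == b


class TestCallMatrix:
    def test_duplicate_records_collapse_to_one(self):
        cohort = cohort_of({"A": 3})
        recs = records_for(
            {("1", 1, "C", "T", "G", "missense", "ACA"): ["A_0", "A_0", "A_1"]}
        )
        drivers = [sa.DriverMutation("G", "1", 1, "C", "T", channel="A[C>T]A")]
        mat = sa.build_call_matrix(recs, drivers, cohort)
        assert mat.to_numpy().tolist() == [[1], [1], [0]]

    def test_absent_driver_gives_zero_column(self):
        cohort = cohort_of({"A": 2})
        recs = records_for({})
        drivers = [sa.DriverMutation("G", "1", 1, "C", "T", channel="A[C>T]A")]
        mat = sa.build_call_matrix(recs, drivers, cohort)
        assert (mat.to_numpy() == 0).all()

    def test_synthetic_column_sums_match_generator_truth(self, mixed_cohort):
        _, catalogs, calls, truth, _ = mixed_cohort
        sums = calls.sum(axis=0)
        for _, row in truth.driver_truth.iterrows():
            assert sums[row["driver"]] == row["n_mutant"]


def test_driver_frame_round_trip():
    drivers = [
        sa.DriverMutation("G1", "1", 1, "C", "T", "c.1C>T", "p.P1S", "A[C>T]A"),
        sa.DriverMutation("G2", "2", 5, "T", "A", channel="C[T>A]G"),
    ]
    back = frame_to_drivers(drivers_to_frame(drivers))
    assert back == drivers
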