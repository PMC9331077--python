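"""Mutation-frequency estimation, deduplication, contrasts, corrections."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import duplexmut as dm
from duplexmut.mf import (
    fit_binomial_dose_model,
    gc_group_test,
    holm_sidak,
    per_animal_counts,
)


def rec(sample, pos, ref="C", alt="A", mult=1, target="t1", chrom="chrA"):
    return dm.MutationRecord(sample, target, chrom, pos, ref, alt, mult)


class TestDeduplicate:
    def test_identical_records_collapse(self):
        muts = [rec("s1", 101)] * 3 + [rec("s1", 102)]
        unique, extra = dm.deduplicate(muts)
        assert len(unique) == 2
        assert extra == 2

    def test_no_cross_sample_collapsing(self):
        unique, extra = dm.deduplicate([rec("s1", 101), rec("s2", 101)])
        assert len(unique) == 2 and extra == 0

    def test_multiplicity_counts_as_clonal_extra(self):
        unique, extra = dm.deduplicate([rec("s1", 101, mult=5)])
        assert len(unique) == 1 and extra == 4


class TestComputeMf:
    def _simple_inputs(self, n_mut=5, bp=10_000_000):
        muts = [rec("s1", 100 + i) for i in range(n_mut)]
        depths = dm.DepthTable({("s1", "t1"): bp})
        meta = [dm.SampleMeta("s1", 0.0)]
        return muts, depths, meta

    def test_basic_arithmetic(self):
        muts, depths, meta = self._simple_inputs()
        (est,) = dm.compute_mf(muts, depths, meta, groupby="cohort")
        assert est.mf == pytest.approx(5e-7)
        assert est.n_mutations == 5

    def test_clone_inclusive_mf(self):
        muts = [rec("s1", 100, mult=1), rec("s1", 101, mult=3)]
        depths = dm.DepthTable({("s1", "t1"): 10_000_000})
        meta = [dm.SampleMeta("s1", 0.0)]
        (est,) = dm.compute_mf(muts, depths, meta, groupby="cohort")
        assert est.mf == pytest.approx(2e-7)
        assert est.mf_clonal == pytest.approx(4e-7)

    def test_zero_depth_group_rejected(self):
        muts, _, meta = self._simple_inputs()
        depths = dm.DepthTable({("s1", "t1"): 0})
        with pytest.raises(ValueError, match="zero duplex bp"):
            dm.compute_mf(muts, depths, meta, groupby="cohort")

    def test_oracle_recount_small_cohorts(self):
        """Grouped MF matches a brute-force recount on <=100-mutation cohorts."""
        cfg = dataclasses.replace(
            dm.default_bap_config(seed=21), depth_mean=6e6  # ~140x shallower
        )
        cohort = dm.generate_cohort(cfg)
        unique, _ = dm.deduplicate(cohort.mutations)
        assert len(unique) <= 100
        dose_of = {m.sample_id: m.dose for m in cohort.metadata}
        for scope in ("dose", "sample", "target"):
            estimates = dm.compute_mf(unique, cohort.depths, cohort.metadata, groupby=scope)
            for est in estimates:
                # independent recount straight from the raw records
                if scope == "dose":
                    in_group = lambda m: f"{dose_of[m.sample_id]:g}" == est.scope
                    bp = sum(
                        cohort.depths.get(s.sample_id, t.name)
                        for s in cohort.metadata
                        if f"{s.dose:g}" == est.scope
                        for t in cohort.panel
                    )
                elif scope == "sample":
                    in_group = lambda m: m.sample_id == est.scope
                    bp = cohort.depths.sample_total(est.scope)
                else:
                    in_group = lambda m: m.target == est.scope
                    bp = sum(
                        cohort.depths.get(s.sample_id, est.scope) for s in cohort.metadata
                    )
                n = sum(1 for m in unique if in_group(m))
                assert est.n_mutations == n
                assert est.mf == pytest.approx(n / bp, rel=1e-12)

    def test_cohort_mf_is_depth_weighted_mean_of_samples(self, default_cohort, unique_mutations):
        (cohort_est,) = dm.compute_mf(
            unique_mutations, default_cohort.depths, default_cohort.metadata, "cohort"
        )
        per_sample = dm.compute_mf(
            unique_mutations, default_cohort.depths, default_cohort.metadata, "sample"
        )
        weighted = sum(e.mf * e.duplex_bp for e in per_sample) / sum(
            e.duplex_bp for e in per_sample
        )
        assert cohort_est.mf == pytest.approx(weighted, rel=1e-12)


class TestRatios:
    @pytest.mark.parametrize(
        "mf_dose,mf_control,expected",
        [(3.3e-7, 1.3e-7, 2.54), (6.8e-7, 1.3e-7, 5.23), (1.0e-7, 1.0e-7, 1.0)],
    )
    def test_fold_change(self, mf_dose, mf_control, expected):
        assert dm.fold_change(mf_dose, mf_control) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "ref,red,expected",
        [(1.35e-7, 1.04e-7, 22.96), (8.8e-7, 5.1e-7, 42.05), (2e-7, 2e-7, 0.0)],
    )
    def test_percent_reduction(self, ref, red, expected):
        assert dm.percent_reduction(ref, red) == pytest.approx(expected, abs=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            dm.fold_change(1e-7, 0.0)
        with pytest.raises(ValueError):
            dm.percent_reduction(0.0, 1e-7)


class TestHolmSidak:
    def test_worked_example(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=20))
    def test_monotone_and_dominating(self, ps):
        adj = holm_sidak(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestDoseModel:
    def test_symmetric_groups_give_null_contrast(self):
        counts = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "dose": [0.0, 0.0, 10.0, 10.0],
                "stratum": ["all"] * 4,
                "n_mutations": [50, 50, 50, 50],
                "duplex_bp": [10**8] * 4,
            }
        )
        (c,) = fit_binomial_dose_model(counts)
        assert c.estimate == pytest.approx(0.0, abs=1e-10)
        assert c.p_raw == pytest.approx(1.0)
        assert c.p_adjusted >= c.p_raw - 1e-15

    def test_zero_count_group_handled(self, caplog):
        import logging

        counts = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "dose": [0.0, 0.0, 10.0, 10.0],
                "stratum": ["all"] * 4,
                "n_mutations": [0, 0, 40, 60],
                "duplex_bp": [10**8] * 4,
            }
        )
        with caplog.at_level(logging.WARNING):
            (c,) = fit_binomial_dose_model(counts)
        assert "continuity" in caplog.text
        assert c.p_raw < 1e-4  # still detects the obvious difference

    def test_default_cohort_doses_all_significant(self):
        """Every exposed dose separates from control at adjusted p < 0.001
        on default synthetic cohorts (effect sizes 2.5x and larger)."""
        for seed in (31, 32, 33):
            cohort = dm.generate_cohort(dm.default_bap_config(seed=seed))
            unique, _ = dm.deduplicate(cohort.mutations)
            counts = per_animal_counts(unique, cohort.depths, cohort.metadata, cohort.panel)
            contrasts = fit_binomial_dose_model(counts)
            assert len(contrasts) == 3
            assert all(c.p_adjusted < 0.001 for c in contrasts)


class TestGcGroupTest:
    def _uniform_panel_cohort(self, seed, het_boost_high_gc=False):
        """Cohort on a panel with no region/chromatin structure except an
        optional 2x multiplier wired onto the high-GC targets."""
        panel = dm.default_panel()
        flat = []
        median_gc = float(np.median([t.gc_fraction for t in panel]))
        for t in panel:
            chromatin = (
                "heterochromatin"
                if het_boost_high_gc and t.gc_fraction > median_gc
                else "euchromatin"
            )
            flat.append(
                dataclasses.replace(t, region_class="intergenic", chromatin=chromatin)
            )
        cfg = dataclasses.replace(
            dm.default_bap_config(seed=seed),
            panel=flat,
            genic_reduction=0.0,
            heterochromatin_multiplier=2.0 if het_boost_high_gc else 1.0,
        )
        cohort = dm.generate_cohort(cfg)
        unique, _ = dm.deduplicate(cohort.mutations)
        counts = per_animal_counts(
            unique, cohort.depths, cohort.metadata, cohort.panel, stratify_by="target"
        )
        return counts, flat, median_gc

    def test_no_gc_effect_gives_null(self):
        counts, panel, median_gc = self._uniform_panel_cohort(seed=41)
        chi2, p = gc_group_test(counts, panel, gc_threshold=median_gc)
        assert p > 0.01

    def test_detects_doubled_mf_in_high_gc_group(self):
        for seed in (51, 52, 53):
            counts, panel, median_gc = self._uniform_panel_cohort(
                seed=seed, het_boost_high_gc=True
            )
            chi2, p = gc_group_test(counts, panel, gc_threshold=median_gc)
            assert p < 0.05

    def test_explicit_threshold_grouping(self):
        counts, panel, _ = self._uniform_panel_cohort(seed=61)
        # the 42.9% split is expressible directly as a threshold argument
        chi2, p = gc_group_test(counts, panel, gc_threshold=0.429)
        assert 0.0 <= p <= 1.0

    def test_single_group_rejected(self):
        counts, panel, _ = self._uniform_panel_cohort(seed=71)
        with pytest.raises(ValueError, match="one GC group"):
            gc_group_test(counts, panel, gc_threshold=0.99)
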