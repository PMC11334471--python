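"""Diversity metrics, composition summaries and their invariants."""

import numpy as np
import pandas as pd
import pytest

from backslop import community_metrics as cm
from backslop.io_formats import CommunityProfile, Lineage, StepRecord


def make_profile(counts: dict, genera: dict | None = None, phyla: dict | None = None,
                 sample_id="s1") -> CommunityProfile:
    genera = genera or {}
    phyla = phyla or {}
    taxonomy = {
        asv: (phyla.get(asv, "Bacillota"), genera.get(asv, "Lactococcus"), "sp.")
        for asv in counts
    }
    return CommunityProfile(sample_id, counts, taxonomy)


class TestAlphaDiversity:
    def test_relative_abundance_sums_to_one(self):
        rel = cm.relative_abundance(make_profile({"a": 30, "b": 70}))
        assert rel["a"] == pytest.approx(0.3)
        assert rel.sum() == pytest.approx(1.0, abs=1e-12)

    def test_richness_counts_support_only(self):
        s = pd.Series({"a": 2.0, "b": 0.0, "c": 1.0})
        assert cm.richness(s) == 2

    @pytest.mark.parametrize("n", [1, 4, 10])
    def test_shannon_uniform_closed_form(self, n):
        p = make_profile({f"a{i}": 5 for i in range(n)})
        assert cm.shannon(p) == pytest.approx(np.log(n), abs=1e-12)

    def test_shannon_example_and_base_change(self):
        s = pd.Series({"a": 0.5, "b": 0.25, "c": 0.25})
        assert cm.shannon(s) == pytest.approx(1.0397, abs=1e-4)
        assert cm.shannon(s, base=2) == pytest.approx(1.5, abs=1e-12)

    def test_single_taxon_entropy_zero(self):
        assert cm.shannon(make_profile({"a": 5})) == 0.0

    def test_matches_scikit_bio(self):
        from skbio.diversity.alpha import shannon as skbio_shannon

        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 50, size=8)
            counts[0] += 1
            s = pd.Series(counts, index=[f"a{i}" for i in range(8)], dtype=float)
            assert cm.shannon(s) == pytest.approx(
                float(skbio_shannon(counts, base=np.e)), abs=1e-10)


class TestBrayCurtis:
    def test_identical_profiles(self):
        p = make_profile({"a": 3, "b": 7})
        assert cm.bray_curtis(p, p) == 0.0

    def test_disjoint_supports(self):
        p = make_profile({"a": 3})
        q = make_profile({"b": 7})
        assert cm.bray_curtis(p, q) == pytest.approx(1.0)

    def test_formula_example(self):
        p = pd.Series({"a": 0.6, "b": 0.4})
        q = pd.Series({"a": 0.4, "b": 0.6})
        assert cm.bray_curtis(p, q) == pytest.approx(0.2, abs=1e-12)

    def test_formula_oracle_and_skbio_on_random_pairs(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.random(12)
            b = rng.random(12)
            a[rng.random(12) < 0.3] = 0
            b[rng.random(12) < 0.3] = 0
            a[0] += 0.1
            b[1] += 0.1
            pa, pb = a / a.sum(), b / b.sum()
            expected = np.abs(pa - pb).sum() / (pa + pb).sum()
            idx = [f"t{i}" for i in range(12)]
            got = cm.bray_curtis(pd.Series(a, index=idx), pd.Series(b, index=idx))
            assert got == pytest.approx(expected, abs=1e-12)
            skbio_bc = float(beta_diversity("braycurtis", np.vstack([pa, pb]),
                                            ids=["p", "q"])[0, 1])
            assert got == pytest.approx(skbio_bc, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = pd.Series(rng.random(6) + 1e-9, index=list("abcdef"))
            b = pd.Series(rng.random(6) + 1e-9, index=list("abcdef"))
            d1, d2 = cm.bray_curtis(a, b), cm.bray_curtis(b, a)
            assert d1 == pytest.approx(d2, abs=1e-15)
            assert 0.0 <= d1 <= 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        idx = [f"t{i}" for i in range(8)]
        a = pd.Series(rng.random(8), index=idx)
        b = pd.Series(rng.random(8), index=idx)
        perm = rng.permutation(idx)
        assert cm.bray_curtis(a, b) == pytest.approx(
            cm.bray_curtis(a[perm], b[perm]), abs=1e-15)


class TestAdjacentSeries:
    def _steps(self, comps):
        return {step: make_profile(c, sample_id=step) for step, c in comps.items()}

    def test_bc_series_sum(self):
        profs = self._steps({
            "F2": {"a": 97, "b": 3}, "F3": {"a": 94, "b": 6},
            "F4": {"a": 96, "b": 4}, "F5": {"a": 92, "b": 8}, "F6": {"a": 95, "b": 5},
        })
        pairs, total = cm.adjacent_series(profs, "braycurtis")
        assert [p for p, _ in pairs] == ["F2-F3", "F3-F4", "F4-F5", "F5-F6"]
        assert total == pytest.approx(sum(v for _, v in pairs), abs=1e-15)

    def test_shannon_fluctuation_uses_absolute_differences(self):
        profs = self._steps({"F2": {"a": 1, "b": 1}, "F3": {"a": 1},
                             "F4": {"a": 1, "b": 1}})
        pairs, total = cm.adjacent_series(profs, "shannon", steps=("F2", "F3", "F4"))
        assert total == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_missing_step_omits_pairs(self):
        profs = self._steps({"F2": {"a": 1}, "F3": {"a": 1}, "F5": {"a": 1},
                             "F6": {"a": 1}})
        pairs, _ = cm.adjacent_series(profs, "braycurtis")
        assert [p for p, _ in pairs] == ["F2-F3", "F5-F6"]

    def test_identical_profiles_zero_sum(self):
        profs = self._steps({s: {"a": 3, "b": 1} for s in ("F2", "F3", "F4")})
        _, total = cm.adjacent_series(profs, "braycurtis")
        assert total == 0.0


class TestAggregateMinorGenera:
    def _lineage(self, comps_by_step, genera):
        lin = Lineage("M1")
        for step, counts in comps_by_step.items():
            lin.steps[step] = StepRecord(step, profile=make_profile(
                counts, genera, sample_id=f"M1_{step}"))
        return lin

    def test_genus_below_threshold_everywhere_pooled(self):
        genera = {"a": "Lactococcus", "b": "Rare"}
        lin = self._lineage({"F2": {"a": 96, "b": 4}, "F3": {"a": 96, "b": 4}}, genera)
        table = cm.aggregate_minor_genera(lin, 0.05)
        assert "Rare" not in table.index
        assert table.loc["Other", "F2"] == pytest.approx(0.04)

    def test_series_max_rule_keeps_genus_everywhere(self):
        genera = {"a": "Lactococcus", "b": "Lactobacillus"}
        lin = self._lineage({"F2": {"a": 98, "b": 2}, "F5": {"a": 40, "b": 60}}, genera)
        table = cm.aggregate_minor_genera(lin, 0.05)
        assert table.loc["Lactobacillus", "F2"] == pytest.approx(0.02)
        assert table.loc["Lactobacillus", "F5"] == pytest.approx(0.60)

    def test_columns_sum_to_one_and_partition(self):
        rng = np.random.default_rng(11)
        genera = {f"a{i}": g for i, g in enumerate(
            ["Lactococcus", "Lactobacillus", "Rare1", "Rare2", "Streptococcus"])}
        comps = {s: {a: float(c) for a, c in
                     zip(genera, rng.integers(1, 100, len(genera)))}
                 for s in ("F2", "F3", "F4")}
        lin = self._lineage(comps, genera)
        table = cm.aggregate_minor_genera(lin, 0.05)
        assert np.allclose(table.sum(axis=0), 1.0, atol=1e-9)

    def test_all_major_means_other_is_zero(self):
        genera = {"a": "Lactococcus", "b": "Lactobacillus"}
        lin = self._lineage({"F2": {"a": 50, "b": 50}}, genera)
        table = cm.aggregate_minor_genera(lin, 0.05)
        assert table.loc["Other", "F2"] == 0.0
        assert table["F2"].sum() == pytest.approx(1.0)


class TestLabFractionAndDominance:
    def test_pure_lactococcus(self):
        p = make_profile({"a": 10}, {"a": "Lactococcus"})
        assert cm.lab_fraction(p) == pytest.approx(1.0)
        assert cm.dominant_taxon(p) == "Lactococcus"

    def test_mixed_lab_nonlab(self):
        p = make_profile({"a": 50, "b": 50},
                         {"a": "Pseudomonas", "b": "Streptococcus"},
                         {"a": "Pseudomonadota"})
        assert cm.lab_fraction(p) == pytest.approx(0.5)

    def test_sensu_lato_split_genera_count_as_lab(self):
        p = make_profile({"a": 40, "b": 30, "c": 30},
                         {"a": "Escherichia", "b": "Lactococcus",
                          "c": "Lacticaseibacillus"},
                         {"a": "Pseudomonadota"})
        assert cm.lab_fraction(p) == pytest.approx(0.6)
        assert cm.lab_fraction(p) + 0.4 == pytest.approx(1.0, abs=1e-12)

    def test_dominance_threshold_is_strict(self):
        p = make_profile({"a": 45, "b": 40, "c": 15},
                         {"a": "Lactococcus", "b": "Streptococcus", "c": "Weissella"})
        assert cm.dominant_taxon(p) == "none"
        p63 = make_profile({"a": 63, "b": 37},
                           {"a": "Lactiplantibacillus", "b": "Lactococcus"})
        assert cm.dominant_taxon(p63) == "Lactobacillus sensu lato"

    def test_pseudomonadota_dominance(self):
        p = make_profile({"a": 80, "b": 20},
                         {"a": "Escherichia", "b": "Lactococcus"},
                         {"a": "Pseudomonadota"})
        assert cm.dominant_taxon(p) == "Pseudomonadota"

    def test_other_lab_category(self):
        p = make_profile({"a": 70, "b": 30},
                         {"a": "Leuconostoc", "b": "Lactococcus"})
        assert cm.dominant_taxon(p) == "other-LAB"


class TestDynamicsSummary:
    def test_summary_fields_consistent(self, small_cohort):
        lin_sim = small_cohort.lineages[0]
        lin = Lineage(lin_sim.lineage_id)
        for step, rec in lin_sim.steps.items():
            lin.steps[step] = StepRecord(step, profile=rec.profile)
        s = cm.build_dynamics_summary(lin)
        assert s.bc_sum == pytest.approx(sum(v for _, v in s.bc_adjacent), abs=1e-12)
        assert s.shannon_fluct_sum >= 0 and s.richness_fluct_sum >= 0
        assert all(0 <= v <= 1 for v in s.lab_fraction_series.values())
        assert all(0 <= v <= 1 for _, v in s.bc_adjacent)
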