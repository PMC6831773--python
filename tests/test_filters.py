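"""The labeling filter cascade: gates, bootstrap CIs, uptake fractions."""

import numpy as np
import pytest

import sipshift as s
from sipshift.density import ShiftRecord
from sipshift.filters import (
    DEFAULT_REFERENCE_GENERA,
    LabelCallSet,
    bootstrap_genus_ci,
    filter1_shifted,
    filter2_both_assays,
    filter3_genus_ci,
    filter4_reference_max,
    filter5_both_assays_again,
    fractional_uptake,
    genus_uptake,
)
from sipshift.model import Assay, TaxonomyMap, Treatment


def rec(otu, shift, assay=Assay.DNA, treatment=Treatment.NH4):
    return ShiftRecord(
        otu_id=otu,
        treatment=treatment,
        assay=assay,
        mean_bd_12c=1.70,
        mean_bd_13c=1.70 + shift,
        shift=shift,
        n_fractions_12c=5,
        n_fractions_13c=5,
        estimator="WEIGHTED_MEAN",
    )


def tax(mapping):
    return TaxonomyMap({o: f"k__Bacteria; g__{g}" for o, g in mapping.items()})


def call_set(otus, assay=Assay.DNA, treatment=Treatment.NH4, stage="F1", **kw):
    return LabelCallSet(
        treatment=treatment, assay=assay, stage=stage, otu_ids=frozenset(otus), **kw
    )


class TestFilter1:
    def test_sign_rule(self):
        shifts = [rec("neg", -0.002), rec("pos", 0.015), rec("zero", 0.0)]
        out = filter1_shifted(shifts)[(Treatment.NH4, Assay.DNA)]
        assert out.otu_ids == {"pos"}
        assert out.removed_at == {"neg": "F1", "zero": "F1"}

    def test_min_shift_threshold(self):
        shifts = [rec("small", 0.002), rec("big", 0.02)]
        out = filter1_shifted(shifts, min_shift=0.005)[(Treatment.NH4, Assay.DNA)]
        assert out.otu_ids == {"big"}

    def test_recall_of_labeled_otus_on_default_simulation(
        self, default_dataset, default_shifts
    ):
        labeled_truth = {
            t.otu_id
            for t in default_dataset.taxa
            if t.atom_fraction.get(Treatment.NH4, 0) >= 0.25
        }
        f1 = filter1_shifted(default_shifts)[(Treatment.NH4, Assay.DNA)]
        recall = len(f1.otu_ids & labeled_truth) / len(labeled_truth)
        assert recall >= 0.95


class TestBothAssayFilters:
    def test_genus_labeled_in_one_assay_removed_everywhere(self):
        taxonomy = tax({"a": "G1", "b": "G1", "c": "G2", "d": "G2"})
        dna = call_set({"a", "c"})
        rna = call_set({"d"}, assay=Assay.RNA)
        f2_dna, f2_rna = filter2_both_assays(dna, rna, taxonomy)
        # G1 only in DNA -> dropped; G2 labeled in both -> kept
        assert f2_dna.otu_ids == {"c"}
        assert f2_rna.otu_ids == {"d"}

    def test_matches_set_comprehension_oracle_on_random_inputs(self):
        rng = np.random.default_rng(17)
        otus = [f"o{i}" for i in range(30)]
        for _ in range(200):
            genus_of = {o: f"G{rng.integers(5)}" for o in otus}
            taxonomy = tax(genus_of)
            dna_set = {o for o in otus if rng.random() < 0.4}
            rna_set = {o for o in otus if rng.random() < 0.4}
            f2_dna, f2_rna = filter2_both_assays(
                call_set(dna_set), call_set(rna_set, assay=Assay.RNA), taxonomy
            )
            shared = {genus_of[o] for o in dna_set} & {genus_of[o] for o in rna_set}
            assert f2_dna.otu_ids == {o for o in dna_set if genus_of[o] in shared}
            assert f2_rna.otu_ids == {o for o in rna_set if genus_of[o] in shared}

    def test_filter5_mirrors_filter2(self):
        taxonomy = tax({"a": "G1", "b": "G2"})
        f4_dna = call_set({"a", "b"}, stage="F4")
        f4_rna = call_set({"a"}, assay=Assay.RNA, stage="F4")
        f5_dna, f5_rna = filter5_both_assays_again(f4_dna, f4_rna, taxonomy)
        assert f5_dna.otu_ids == {"a"}
        assert f5_rna.otu_ids == {"a"}

    def test_mismatched_treatments_rejected(self):
        with pytest.raises(ValueError, match="same treatment"):
            filter2_both_assays(
                call_set({"a"}),
                call_set({"a"}, assay=Assay.RNA, treatment=Treatment.NO2),
                tax({"a": "G1"}),
            )


class TestFilter3:
    def run_f3(self, shifts_by_otu, genus_of, f2_otus=None, **kw):
        dna_shifts = [rec(o, v) for o, v in shifts_by_otu.items()]
        rna_shifts = [rec(o, v, assay=Assay.RNA) for o, v in shifts_by_otu.items()]
        pos = {o for o, v in shifts_by_otu.items() if v > 0}
        f2 = frozenset(f2_otus if f2_otus is not None else pos)
        return filter3_genus_ci(
            call_set(f2, stage="F2"),
            call_set(f2, assay=Assay.RNA, stage="F2"),
            dna_shifts + rna_shifts,
            tax(genus_of),
            seed=kw.pop("seed", 4),
            **kw,
        )

    def test_constant_shift_genus_fully_retained(self):
        f3_dna, f3_rna, cis = self.run_f3(
            {"a": 0.03, "b": 0.03, "c": 0.03}, {o: "G1" for o in "abc"}
        )
        assert f3_dna.otu_ids == {"a", "b", "c"}
        for ci in cis:
            assert ci.lo == pytest.approx(0.03) and ci.hi == pytest.approx(0.03)

    def test_symmetric_genus_straddles_zero_and_drops(self):
        f3_dna, f3_rna, cis = self.run_f3(
            {"a": -0.01, "b": 0.01}, {"a": "G1", "b": "G1"}
        )
        assert f3_dna.otu_ids == set()
        assert all(not ci.significant for ci in cis)

    def test_singleton_genus_degenerate_ci(self):
        f3_dna, _f3_rna, cis = self.run_f3({"a": 0.02}, {"a": "G1"})
        assert f3_dna.otu_ids == {"a"}
        assert all(ci.degenerate for ci in cis)

    def test_deterministic_given_seed(self):
        shifts = {f"o{i}": v for i, v in enumerate(np.random.default_rng(2).normal(0.01, 0.01, 12))}
        genus_of = {o: "G1" for o in shifts}
        a = self.run_f3(shifts, genus_of, seed=11)
        b = self.run_f3(shifts, genus_of, seed=11)
        assert a[0].otu_ids == b[0].otu_ids
        assert [(c.lo, c.hi) for c in a[2]] == [(c.lo, c.hi) for c in b[2]]

    def test_labeled_genus_kept_null_genus_dropped(self):
        rng = np.random.default_rng(0)
        kept = dropped = 0
        n_runs = 100
        for _ in range(n_runs):
            shifts = {}
            genus_of = {}
            for i in range(10):
                shifts[f"lab{i}"] = float(rng.normal(0.03, 0.005))
                genus_of[f"lab{i}"] = "Labeled"
                shifts[f"nul{i}"] = float(rng.normal(0.0, 0.005))
                genus_of[f"nul{i}"] = "Null"
            f3_dna, _f3_rna, _cis = self.run_f3(
                shifts, genus_of, seed=int(rng.integers(2**31))
            )
            genera = {genus_of[o] for o in f3_dna.otu_ids}
            kept += "Labeled" in genera
            dropped += "Null" not in genera
        assert kept >= 0.95 * n_runs
        assert dropped >= 0.95 * n_runs

    def test_retain_mode_above_lower_drops_sub_ci_members(self):
        shifts = {"a": 0.03, "b": 0.031, "c": 0.029, "d": 0.001}
        genus_of = {o: "G1" for o in shifts}
        f3_dna, _f3_rna, cis = self.run_f3(
            shifts, genus_of, retain_mode="above_lower"
        )
        ci = next(c for c in cis if c.assay is Assay.DNA)
        assert "d" not in f3_dna.otu_ids
        assert all(shifts[o] >= ci.lo for o in f3_dna.otu_ids)

    def test_bootstrap_ci_converges_to_analytic_percentiles(self):
        # with many OTUs the percentile CI approaches the normal-theory
        # percentile of the mean: m +/- z_{0.95} * sd / sqrt(n)
        rng = np.random.default_rng(3)
        shifts = rng.normal(0.02, 0.006, size=40)
        lo, hi = bootstrap_genus_ci(shifts, 10_000, np.random.default_rng(8))
        se = shifts.std(ddof=0) / np.sqrt(len(shifts))
        assert lo == pytest.approx(shifts.mean() - 1.6449 * se, abs=0.0005)
        assert hi == pytest.approx(shifts.mean() + 1.6449 * se, abs=0.0005)


class TestFilter4:
    def setup_sets(self, shifts_by_otu, genus_of, ci_lo=0.0):
        taxonomy = tax(genus_of)
        shifts = [rec(o, v) for o, v in shifts_by_otu.items()]
        genus_ci = {
            g: s.GenusCI(
                genus=g, treatment=Treatment.NH4, assay=Assay.DNA,
                lo=ci_lo, hi=1.0, n_otus=2, significant=True,
            )
            for g in set(genus_of.values())
        }
        f3 = call_set(set(shifts_by_otu), stage="F3", genus_ci=genus_ci)
        return f3, shifts, taxonomy

    def test_threshold_rule(self):
        f3, shifts, taxonomy = self.setup_sets(
            {"ref1": 0.030, "low": 0.010, "high": 0.035},
            {"ref1": "Nitrosomonas", "low": "G", "high": "G"},
        )
        out = filter4_reference_max(f3, shifts, taxonomy)
        assert out.otu_ids == {"ref1", "high"}
        assert out.removed_at["low"] == "F4"

    def test_reference_member_below_its_genus_ci_not_protected(self):
        f3, shifts, taxonomy = self.setup_sets(
            {"ref_hi": 0.030, "ref_lo": 0.001, "cand": 0.035},
            {"ref_hi": "Nitrosomonas", "ref_lo": "Nitrosomonas", "cand": "G"},
            ci_lo=0.02,
        )
        out = filter4_reference_max(f3, shifts, taxonomy)
        assert out.otu_ids == {"ref_hi", "cand"}

    def test_no_labeled_reference_passes_through_with_warning(self, caplog):
        f3, shifts, taxonomy = self.setup_sets(
            {"a": 0.01, "b": 0.02}, {"a": "G", "b": "G"}
        )
        with caplog.at_level("WARNING"):
            out = filter4_reference_max(f3, shifts, taxonomy)
        assert out.otu_ids == {"a", "b"}
        assert "passing through" in caplog.text

    def test_default_reference_depends_on_treatment(self):
        assert DEFAULT_REFERENCE_GENERA[Treatment.NO2] == ("Nitrospira",)
        assert DEFAULT_REFERENCE_GENERA[Treatment.NH4] == ("Nitrosomonas",)


class TestFractionalUptake:
    def test_two_otu_arithmetic(self):
        labeled = call_set({"a", "b"}, stage="F5")
        fracs = fractional_uptake(labeled, [rec("a", 0.03), rec("b", 0.01)])
        by = {f.otu_id: f.fraction for f in fracs}
        assert by["a"] == pytest.approx(0.75)
        assert by["b"] == pytest.approx(0.25)

    def test_single_otu_gets_everything(self):
        fracs = fractional_uptake(call_set({"a"}), [rec("a", 0.02)])
        assert fracs[0].fraction == pytest.approx(1.0)

    def test_matches_loop_oracle_and_sums_to_one(self):
        rng = np.random.default_rng(6)
        otus = [f"o{i}" for i in range(50)]
        shifts = {o: float(rng.uniform(0.001, 0.04)) for o in otus}
        fracs = fractional_uptake(
            call_set(set(otus)), [rec(o, v) for o, v in shifts.items()]
        )
        total = sum(shifts.values())
        for f in fracs:
            assert f.fraction == pytest.approx(shifts[f.otu_id] / total, abs=1e-12)
        assert sum(f.fraction for f in fracs) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_total_is_an_error(self):
        with pytest.raises(ValueError, match="not positive"):
            fractional_uptake(
                call_set({"a", "b"}), [rec("a", 0.01), rec("b", -0.02)]
            )

    def test_genus_uptake_sums_members(self):
        fracs = fractional_uptake(
            call_set({"a", "b", "c"}),
            [rec("a", 0.02), rec("b", 0.02), rec("c", 0.01)],
        )
        by_genus = genus_uptake(fracs, tax({"a": "G1", "b": "G1", "c": "G2"}))
        assert by_genus["G1"] == pytest.approx(0.8)
        assert by_genus["G2"] == pytest.approx(0.2)


class TestCascade:
    def test_stage_sizes_monotone_non_increasing(self, default_cascade):
        order = ["F1", "F2", "F3", "F4", "F5"]
        seen = set()
        for (t, a, _stage) in default_cascade.stages:
            if (t, a) in seen:
                continue
            seen.add((t, a))
            sizes = [len(default_cascade.get(t, a, st)) for st in order]
            assert all(x >= y for x, y in zip(sizes, sizes[1:])), (t, a, sizes)

    def test_nested_sets(self, default_cascade):
        for (t, a, stage), cs in default_cascade.stages.items():
            if stage == "F1":
                continue
            prev = default_cascade.get(t, a, f"F{int(stage[1]) - 1}")
            assert cs.otu_ids <= prev.otu_ids

    def test_same_seed_reproduces_cis_and_sets(self, default_dataset, default_shifts):
        a = s.run_filter_cascade(default_shifts, default_dataset.taxonomy, seed=5)
        b = s.run_filter_cascade(default_shifts, default_dataset.taxonomy, seed=5)
        assert {k: v.otu_ids for k, v in a.stages.items()} == {
            k: v.otu_ids for k, v in b.stages.items()
        }
        assert a.genus_ci_frame().equals(b.genus_ci_frame())
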