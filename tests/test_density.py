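"""Band-center estimators and buoyant-density shift computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sipshift as s
from sipshift.density import (
    AbsentOtuError,
    fit_gradient_profile,
    gradient_mean_bds,
    mean_bd_sparse,
    weighted_mean_bd,
)
from sipshift.model import Assay, Isotope, OtuFractionTable, Treatment
from sipshift.simulate import DesignSpec, default_community, simulate_gradient

from conftest import make_samples, make_table


def loop_weighted_mean(counts, densities, i):
    """Independent oracle: explicit sum loop over fractions."""
    num = den = 0.0
    for f in range(len(densities)):
        colsum = sum(counts[o][f] for o in range(len(counts)))
        if colsum == 0:
            continue
        rel = counts[i][f] / colsum
        num += rel * densities[f]
        den += rel
    return num / den


class TestWeightedMeanBd:
    def test_symmetric_profile_gives_center(self):
        t = make_table([[25, 50, 25], [75, 50, 75]], [1.74, 1.72, 1.70])
        assert weighted_mean_bd(t, "otu1") == pytest.approx(1.72)

    def test_single_support_point(self):
        t = make_table([[0, 7, 0], [5, 5, 5]], [1.751, 1.731, 1.711])
        assert weighted_mean_bd(t, "otu1") == pytest.approx(1.731)

    def test_matches_loop_oracle_on_random_gradients(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            counts = rng.integers(0, 50, size=(4, 5))
            counts[0] += 1  # keep the focal OTU present
            dens = np.sort(rng.uniform(1.66, 1.78, size=5))[::-1]
            t = make_table(counts, dens)
            expected = loop_weighted_mean(counts, dens, 0)
            assert weighted_mean_bd(t, "otu1") == pytest.approx(expected, abs=1e-12)

    @given(factor=st.integers(min_value=2, max_value=1000))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_column_scaling(self, factor):
        counts = np.array([[3, 9, 1], [5, 0, 7]])
        t = make_table(counts, [1.74, 1.72, 1.70])
        t2 = make_table(counts * factor, [1.74, 1.72, 1.70])
        assert weighted_mean_bd(t, "otu1") == pytest.approx(
            weighted_mean_bd(t2, "otu1"), abs=1e-12
        )

    def test_absent_otu_signals(self):
        t = make_table([[0, 0, 0], [1, 1, 1]], [1.74, 1.72, 1.70])
        with pytest.raises(AbsentOtuError):
            weighted_mean_bd(t, "otu1")


class TestFitGradientProfile:
    def test_recovers_noiseless_gaussian(self):
        dens = np.linspace(1.75, 1.83, 10)
        conc = 40.0 * np.exp(-((dens - 1.79) ** 2) / (2 * 0.012**2))
        prof = fit_gradient_profile(dens, conc)
        assert prof.fitted_mu == pytest.approx(1.79, abs=1e-6)
        assert prof.fitted_sigma == pytest.approx(0.012, abs=1e-6)
        assert not prof.moment_fallback

    def test_flat_profile_falls_back_to_moments(self):
        dens = np.linspace(1.75, 1.83, 8)
        conc = np.full(8, 5.0)
        prof = fit_gradient_profile(dens, conc)
        assert prof.fitted_mu == pytest.approx(dens.mean(), abs=1e-9)

    def test_noisy_gaussian_recovered_within_tolerance(self):
        rng = np.random.default_rng(21)
        dens = np.linspace(1.75, 1.83, 12)
        conc = 40.0 * np.exp(-((dens - 1.79) ** 2) / (2 * 0.012**2))
        conc *= rng.lognormal(0.0, 0.05, size=conc.shape)
        prof = fit_gradient_profile(dens, conc)
        assert prof.fitted_mu == pytest.approx(1.79, abs=0.002)

    def test_too_few_positive_fractions_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_gradient_profile([1.75, 1.76, 1.77, 1.78], [1.0, 2.0, 0.0, 0.0])


class TestMeanBdSparse:
    def profile(self, sigma=0.012):
        dens = np.linspace(1.84, 1.74, 8)
        conc = 40.0 * np.exp(-((dens - 1.79) ** 2) / (2 * sigma**2))
        return fit_gradient_profile(dens, conc)

    def test_single_observed_fraction(self):
        t = make_table(
            [[0, 9, 0], [3, 3, 3]], [1.82, 1.80, 1.78], assay=Assay.RNA
        )
        got = mean_bd_sparse(t, "otu1", self.profile())
        assert got == pytest.approx(1.80, abs=1e-4)

    def test_symmetric_two_point_support(self):
        t = make_table(
            [[5, 0, 5], [3, 3, 3]], [1.82, 1.80, 1.78], assay=Assay.RNA
        )
        got = mean_bd_sparse(t, "otu1", self.profile())
        assert got == pytest.approx(1.80, abs=1e-4)

    def test_agrees_with_full_data_weighted_mean(self):
        taxa = default_community()
        design = DesignSpec(rna_sequenced=16)
        full = simulate_gradient(
            taxa, design, Treatment.NH4, Isotope.C12, Assay.RNA, seed=33
        )
        idx = list(range(0, 16, 2))
        sub = OtuFractionTable(
            full.otu_ids, [full.samples[j] for j in idx], full.counts[:, idx]
        )
        prof = fit_gradient_profile(
            sub.densities, np.array([x.na_concentration for x in sub.samples])
        )
        for otu in full.otu_ids[::6]:
            sparse = mean_bd_sparse(sub, otu, prof)
            dense = weighted_mean_bd(full, otu)
            assert sparse == pytest.approx(dense, abs=0.003)


class TestComputeShifts:
    def two_isotope_tables(self, counts12, counts13, densities, assay=Assay.DNA):
        t12 = make_table(counts12, densities, isotope=Isotope.C12, assay=assay)
        t13 = make_table(counts13, densities, isotope=Isotope.C13, assay=assay,
                         column_id="column_2")
        return [t12, t13]

    def test_identical_tables_give_zero_shift(self):
        counts = [[10, 30, 10], [5, 5, 20]]
        tables = self.two_isotope_tables(counts, counts, [1.74, 1.72, 1.70])
        records = s.compute_shifts(tables)
        assert len(records) == 2
        assert all(r.shift == pytest.approx(0.0, abs=1e-12) for r in records)

    def test_antisymmetric_under_isotope_swap(self):
        rng = np.random.default_rng(9)
        c12 = rng.integers(1, 40, size=(3, 4))
        c13 = rng.integers(1, 40, size=(3, 4))
        dens = [1.76, 1.74, 1.72, 1.70]
        fwd = s.compute_shifts(self.two_isotope_tables(c12, c13, dens))
        rev = s.compute_shifts(self.two_isotope_tables(c13, c12, dens))
        fwd_map = {r.otu_id: r.shift for r in fwd}
        for r in rev:
            assert r.shift == pytest.approx(-fwd_map[r.otu_id], abs=1e-12)

    def test_missing_isotope_is_hard_error(self):
        t = make_table([[1, 2, 3]], [1.74, 1.72, 1.70])
        with pytest.raises(ValueError, match="C13"):
            s.compute_shifts([t])

    def test_otu_absent_from_one_isotope_gets_no_record(self):
        tables = self.two_isotope_tables(
            [[5, 5, 5], [1, 2, 1]], [[0, 0, 0], [1, 2, 1]], [1.74, 1.72, 1.70]
        )
        records = s.compute_shifts(tables)
        assert {r.otu_id for r in records} == {"otu2"}

    def test_planted_full_label_recovered(self, default_dataset, default_shifts):
        truth = {t.otu_id: t for t in default_dataset.taxa}
        dna_nh4 = [
            r for r in default_shifts
            if r.treatment is Treatment.NH4 and r.assay is Assay.DNA
        ]
        full = [r.shift for r in dna_nh4
                if truth[r.otu_id].atom_fraction.get(Treatment.NH4, 0) == 1.0]
        null = [r.shift for r in dna_nh4
                if truth[r.otu_id].atom_fraction.get(Treatment.NH4, 0) == 0.0]
        assert np.mean(full) == pytest.approx(0.036, abs=0.004)
        assert abs(np.mean(null)) < 0.003

    def test_monotone_dose_response(self):
        from sipshift.simulate import dose_response_community

        taxa, planted = dose_response_community()
        tables = []
        for iso, seed in ((Isotope.C12, 301), (Isotope.C13, 302)):
            tables.append(
                simulate_gradient(
                    taxa, DesignSpec(), Treatment.NH4, iso, Assay.DNA, seed=seed
                )
            )
        records = s.compute_shifts(tables)
        by_level: dict[float, list[float]] = {}
        for r in records:
            if r.otu_id in planted:
                by_level.setdefault(planted[r.otu_id], []).append(r.shift)
        levels = sorted(by_level)
        means = [np.mean(by_level[a]) for a in levels]
        assert all(a < b for a, b in zip(means, means[1:]))


def test_gradient_mean_bds_matches_scalar_api(small_table):
    vec = gradient_mean_bds(small_table)
    for i, otu in enumerate(small_table.otu_ids):
        assert vec[i] == pytest.approx(weighted_mean_bd(small_table, otu), abs=1e-12)
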