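import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cldla.genoio import MISSING
from cldla.pedigree import (AFFECTED_MALE, CARRIER_FEMALE, NULL_FEMALE,
                            UNKNOWN, WT_FEMALE, WT_MALE)
from cldla.simcohort import (CohortSummary, QTLSpec, SimConfig, cohort_summary,
                             inject_missingness, make_marker_map,
                             proportion_pct, simulate_haplotypes,
                             simulate_pedigree, simulate_phenotype,
                             survival_tally, transmit_x_linked,
                             _offspring_class)
from cldla.rng import stream


class TestSimulatePedigree:
    def test_minimal_cohort_structure(self):
        config = SimConfig(seed=1, n_sires=1, n_litters=1, litter_size_mean=4)
        ped = simulate_pedigree(config)
        assert set(ped.founders()) == {"DAM0", "SIRE1"}
        offspring = ped.table[ped.table["sire"] != UNKNOWN]
        assert len(offspring) >= 1
        # trio property: every case has both parents on record
        for s, d, c in ped.trios():
            assert s in ped.ids and d in ped.ids

    def test_study_scale_offspring_count(self):
        """Eleven litters of mean 11.6 give about 128 offspring in
        expectation."""
        totals = [len(simulate_pedigree(SimConfig(seed=s, n_litters=11))) - 8
                  for s in range(30)]
        assert abs(np.mean(totals) - 11 * 11.6) < 3 * np.std(totals) / np.sqrt(30)

    def test_same_seed_identical(self):
        a = simulate_pedigree(SimConfig(seed=7)).table
        b = simulate_pedigree(SimConfig(seed=7)).table
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            simulate_pedigree(SimConfig(n_litters=0))

    def test_case_target_reached(self):
        ped = simulate_pedigree(SimConfig(seed=3, n_cases_target=60,
                                          max_generations=6))
        assert len(ped.cases()) >= 60


class TestTransmitXLinked:
    def test_carrier_by_wt_class_probabilities(self):
        rng = stream(0, "t")
        counts = {}
        for _ in range(8000):
            c = _offspring_class(rng, CARRIER_FEMALE, WT_MALE)
            counts[c] = counts.get(c, 0) + 1
        assert set(counts) == {WT_MALE, AFFECTED_MALE, WT_FEMALE, CARRIER_FEMALE}
        for v in counts.values():
            assert abs(v / 8000 - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 8000)

    def test_carrier_by_affected_produces_null_females(self):
        rng = stream(0, "t")
        classes = {_offspring_class(rng, CARRIER_FEMALE, AFFECTED_MALE)
                   for _ in range(400)}
        assert classes == {WT_MALE, AFFECTED_MALE, CARRIER_FEMALE, NULL_FEMALE}

    def test_observed_litter_counts_inside_multinomial_region(self):
        """Simulated class counts at n=128, and the reported litter
        tallies (29, 34, 36, 29), lie inside the central 99% multinomial
        region around (32, 32, 32, 32)."""
        # chi-square radius of the 99% region for 4 equiprobable classes
        radius = stats.chi2.isf(0.01, df=3)

        def chi2_stat(counts):
            n = sum(counts)
            return sum((c - n / 4) ** 2 / (n / 4) for c in counts)

        assert chi2_stat([29, 34, 36, 29]) < radius
        config = SimConfig(seed=5, n_litters=11)
        ped = simulate_pedigree(config)
        counts = ped.class_counts()
        offspring_counts = [counts[WT_MALE] - 0, counts[AFFECTED_MALE],
                            counts[WT_FEMALE], counts[CARRIER_FEMALE]]
        # remove founder contributions (founder dam is a carrier, sires WT males)
        offspring_counts[0] -= 7
        offspring_counts[3] -= 1
        assert chi2_stat(offspring_counts) < radius

    def test_refill_requires_parent_classes(self, trio_pedigree):
        tab = trio_pedigree.table.copy()
        tab.loc[tab["id"] == "D1", "xclass"] = None
        from cldla.pedigree import Pedigree
        with pytest.raises(ValueError, match="class"):
            transmit_x_linked(Pedigree(tab), seed=0)

    def test_segregation_mean_over_replicates(self):
        """Over R=200 replicate cohorts of ~128 offspring the mean class
        frequencies are within 3 binomial SE of 1/4."""
        R = 200
        totals = np.zeros(4)
        n_total = 0
        for s in range(R):
            ped = simulate_pedigree(SimConfig(seed=s, n_litters=11))
            counts = ped.class_counts()
            totals += [counts[WT_MALE] - 7, counts[AFFECTED_MALE],
                       counts[WT_FEMALE], counts[CARRIER_FEMALE] - 1]
            n_total += len(ped) - 8
        margin = 3 * np.sqrt(0.25 * 0.75 / n_total)
        for f in totals / n_total:
            assert abs(f - 0.25) < margin


class TestSimulateHaplotypes:
    def test_no_recombination_transmits_intact_haplotypes(self):
        config = SimConfig(seed=9, n_litters=2, markers_per_chromosome=100,
                           cm_per_mbp=0.0)
        ped = simulate_pedigree(config)
        markers = make_marker_map(config)
        panel = simulate_haplotypes(ped, markers, config)
        idx = {ind: k for k, ind in enumerate(panel.ids)}
        offspring = ped.table[ped.table["sire"] != UNKNOWN]
        for _, row in offspring.iterrows():
            k = idx[row["id"]]
            pk = idx[row["sire"]]
            child_pat = panel.haps[2 * k]
            assert (np.array_equal(child_pat, panel.haps[2 * pk])
                    or np.array_equal(child_pat, panel.haps[2 * pk + 1]))

    def test_founder_frequencies_recovered(self):
        """Empirical founder allele frequencies match the drawn per-marker
        frequencies within 3 binomial SE (2,000 founder haplotypes)."""
        config = SimConfig(seed=10, n_sires=999, n_litters=1,
                           litter_size_mean=1, markers_per_chromosome=50)
        ped = simulate_pedigree(config)
        markers = make_marker_map(config)
        panel = simulate_haplotypes(ped, markers, config)
        founders = ped.founders()
        fp = panel.subset_individuals(founders)
        n_h = 2 * len(founders)
        emp = fp.haps.mean(axis=0)
        drawn = stream(config.seed, "founder_freqs").uniform(0.05, 0.95, 50)
        se = np.sqrt(drawn * (1 - drawn) / n_h)
        assert np.all(np.abs(emp - drawn) < 3.5 * se)

    def test_same_seed_identical_panels(self):
        config = SimConfig(seed=11, n_litters=2, markers_per_chromosome=60)
        ped = simulate_pedigree(config)
        markers = make_marker_map(config)
        p1 = simulate_haplotypes(ped, markers, config)
        p2 = simulate_haplotypes(ped, markers, config)
        np.testing.assert_array_equal(p1.haps, p2.haps)

    def test_qtl_marker_gets_configured_frequency(self):
        config = SimConfig(seed=12, n_sires=499, n_litters=1, litter_size_mean=1,
                           markers_per_chromosome=40,
                           qtl=QTLSpec("1", 500_000, 0.3, 10.0))
        ped = simulate_pedigree(config)
        markers = make_marker_map(config)
        panel = simulate_haplotypes(ped, markers, config)
        from cldla.simcohort import qtl_marker_index
        qi = qtl_marker_index(markers, config.qtl)
        founders = panel.subset_individuals(ped.founders())
        emp = founders.haps[:, qi].mean()
        assert abs(emp - 0.3) < 3 * np.sqrt(0.3 * 0.7 / founders.haps.shape[0])


class TestSimulatePhenotype:
    def test_degenerate_limit_all_equal_mean(self):
        config = SimConfig(seed=13, n_litters=3, var_polygenic=0.0,
                           var_residual=0.0, mean_lifespan=55.0)
        ped = simulate_pedigree(config)
        markers = make_marker_map(config)
        panel = simulate_haplotypes(ped, markers, config)
        phen = simulate_phenotype(ped, panel, config)
        assert (phen["lifespan_days"] == 55.0).all()

    def test_flooring_at_zero(self):
        config = SimConfig(seed=14, n_litters=3, var_polygenic=0.0,
                           var_residual=0.0, mean_lifespan=5.0,
                           qtl=QTLSpec("1", 12_500_000, 0.99, -100.0))
        ped = simulate_pedigree(config)
        markers = make_marker_map(config)
        panel = simulate_haplotypes(ped, markers, config)
        phen, comps = simulate_phenotype(ped, panel, config,
                                         return_components=True)
        carriers = comps["qtl_dosage"] >= 1
        assert (phen.loc[carriers.values, "lifespan_days"] == 0.0).all()

    def test_ols_recovers_additive_effect(self):
        """Regression of lifespan on causal dosage recovers the planted
        effect within 3 standard errors at n=400."""
        config = SimConfig(seed=15, n_cases_target=400, max_generations=8,
                           markers_per_chromosome=50,
                           qtl=QTLSpec("1", 12_500_000, 0.4, 30.0))
        ped = simulate_pedigree(config)
        markers = make_marker_map(config)
        panel = simulate_haplotypes(ped, markers, config)
        phen, comps = simulate_phenotype(ped, panel, config,
                                         return_components=True)
        x = comps["qtl_dosage"].to_numpy()
        y = phen["lifespan_days"].to_numpy()
        slope, _, _, _, se = stats.linregress(x, y)
        assert abs(slope - 30.0) < 3 * se

    def test_only_cases_phenotyped(self, small_cohort):
        _, ped, _, _, phen = small_cohort
        assert set(phen["individual_id"]) <= set(ped.cases())

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SimConfig(var_polygenic=-1.0)

    def test_polygenic_variance_recovered(self):
        """Pooled variance of gene-dropped polygenic deviates matches the
        configured variance within 15%."""
        from cldla.simcohort import _polygenic_gene_drop
        values = []
        for s in range(25):
            config = SimConfig(seed=100 + s, n_litters=6, var_polygenic=400.0)
            ped = simulate_pedigree(config)
            g = _polygenic_gene_drop(ped, config)
            values.extend(g[c] for c in ped.cases())
        assert abs(np.var(values) - 400.0) / 400.0 < 0.15


class TestInjectMissingness:
    def test_identity_when_rates_zero(self, small_cohort):
        config, _, _, panel, _ = small_cohort
        g = inject_missingness(panel, config)
        np.testing.assert_array_equal(g.dosages, panel.dosages().dosages)

    def test_missing_fraction_binomial(self, small_cohort):
        config, _, _, panel, _ = small_cohort
        from dataclasses import replace
        cfg = replace(config, missing_rate=0.1)
        g = inject_missingness(panel, cfg)
        n = g.dosages.size
        frac = (g.dosages == MISSING).mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_saturation_all_missing(self, small_cohort):
        config, _, _, panel, _ = small_cohort
        from dataclasses import replace
        cfg = replace(config, missing_rate=1.0)
        g = inject_missingness(panel, cfg)
        assert (g.dosages == MISSING).all()
        assert (g.marker_call_rate() == 0).all()
        assert (g.individual_call_rate() == 0).all()

    def test_error_rate_perturbs_dosages(self, small_cohort):
        config, _, _, panel, _ = small_cohort
        from dataclasses import replace
        cfg = replace(config, genotype_error_rate=0.05)
        g = inject_missingness(panel, cfg)
        truth = panel.dosages().dosages
        frac = (g.dosages != truth).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / truth.size)


class TestCohortSummary:
    def test_printed_survival_percentages(self):
        """The survival tallies (60, 12, 68, 3) of 143 cases give the
        percentages 42 / 8 / 48 / 2."""
        lifespans = [3.0] * 60 + [20.0] * 12 + [90.0] * 68 + [200.0] * 3
        counts = survival_tally(lifespans)
        assert counts == [60, 12, 68, 3]
        pcts = [proportion_pct(c, 143) for c in counts]
        assert pcts == [42, 8, 48, 2]

    def test_improved_management_neonatal_lethality(self):
        assert proportion_pct(12, 52) == 23

    def test_genotype_class_counts_sum(self, trio_pedigree):
        phen = pd.DataFrame({"individual_id": ["C1"], "lifespan_days": [30.0]})
        summary = cohort_summary(trio_pedigree, phen)
        assert summary.total_offspring == 2
        counts = {AFFECTED_MALE: 29, CARRIER_FEMALE: 34, WT_MALE: 36,
                  WT_FEMALE: 29}
        s = CohortSummary(counts, [1], (7, 30, 150), 1)
        assert s.total_offspring == 128

    def test_tallies_conserve_total(self, small_cohort):
        _, ped, _, _, phen = small_cohort
        summary = cohort_summary(ped, phen)
        assert sum(summary.survival_counts) == summary.total_cases == len(phen)

    def test_empty_case_set_rejected(self, trio_pedigree):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(trio_pedigree, pd.DataFrame(
                {"individual_id": [], "lifespan_days": []}))

    def test_edges_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            survival_tally([1.0], class_edges=(30, 7))
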