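"""Diversity dynamics: He, the mean-He ANOVA, PCA, private SNPs, abundance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import swardpop as sp
from swardpop.diversity import DiversityTable


def aaf_from_array(vals, samples):
    loci = [sp.Locus("chr1", 10 * (i + 1), "A", "G")
            for i in range(vals.shape[0])]
    return sp.AAFMatrix(loci=loci, samples=samples, aaf=vals)


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "p,he", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.25, 0.375)]
    )
    def test_he_formula(self, p, he):
        aaf = aaf_from_array(np.array([[p]]), ["s"])
        div = sp.heterozygosity(aaf)
        assert div.he[0, 0] == pytest.approx(he)

    @given(st.floats(0, 1))
    def test_he_symmetric_and_bounded(self, p):
        aaf = aaf_from_array(np.array([[p, 1 - p]]), ["a", "b"])
        div = sp.heterozygosity(aaf)
        assert div.he[0, 0] == pytest.approx(div.he[0, 1], abs=1e-12)
        assert 0.0 <= div.he[0, 0] <= 0.5

    def test_mixture_at_least_as_diverse_as_pure_stands(self, design,
                                                        small_trial):
        """Mixing differentiated cultivars raises expected heterozygosity."""
        _, trial = small_trial
        truth_aaf = aaf_from_array(
            trial.truth.sample_aaf, [s.sample_id for s in design]
        )
        mean_he = sp.heterozygosity(truth_aaf).mean_he
        by_content = {
            c: mean_he[[s.sample_id for s in design
                        if s.ryegrass_content == c]].mean()
            for c in ("Merks", "Meloni", "both")
        }
        assert by_content["both"] >= max(by_content["Merks"],
                                         by_content["Meloni"]) - 1e-3


class TestMeanHeAnova:
    def test_full_design_df_structure(self, design):
        rng = np.random.default_rng(0)
        div = DiversityTable(
            samples=[s.sample_id for s in design],
            he=np.empty((0, 56)),
            mean_he=pd.Series(rng.uniform(0.2, 0.4, 56),
                              index=[s.sample_id for s in design]),
        )
        tab = sp.anova_mean_he(div, design)
        assert tab.set_index("term")["df"].to_dict() == {
            "comp": 6, "comp_rep": 7, "comp_year": 21, "residual": 21,
        }
        assert tab["df"].sum() == 55

    def test_constant_response_gives_zero_ss(self, design):
        div = DiversityTable(
            samples=[s.sample_id for s in design],
            he=np.empty((0, 56)),
            mean_he=pd.Series(0.3, index=[s.sample_id for s in design]),
        )
        tab = sp.anova_mean_he(div, design)
        assert np.allclose(tab["sum_sq"], 0.0)

    def test_pure_composition_effect_lands_in_composition_term(self, design):
        comp_effect = {c: 0.01 * c for c in range(1, 8)}
        y = pd.Series(
            [0.3 + comp_effect[s.seed_composition] for s in design],
            index=[s.sample_id for s in design],
        )
        div = DiversityTable(samples=list(y.index), he=np.empty((0, 56)),
                             mean_he=y)
        tab = sp.anova_mean_he(div, design).set_index("term")
        assert tab.loc["comp", "sum_sq"] > 0
        for other in ("comp_rep", "comp_year", "residual"):
            assert tab.loc[other, "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_anova_terms_sum_to_total(self, design, small_pipeline):
        div = sp.heterozygosity(small_pipeline["aaf"])
        tab = sp.anova_mean_he(div, design)
        y = div.mean_he.to_numpy()
        assert tab["sum_sq"].sum() == pytest.approx(
            ((y - y.mean()) ** 2).sum(), rel=1e-9
        )


class TestPca:
    def test_disjoint_groups_separate_on_pc1(self):
        vals = np.zeros((50, 8))
        vals[:25, :4] = 0.9
        vals[25:, 4:] = 0.9
        aaf = aaf_from_array(vals, [f"s{i}" for i in range(8)])
        got = sp.pca_aaf(aaf)
        s1 = np.sign(got.scores[:4, 0])
        assert (s1 == s1[0]).all()
        assert (np.sign(got.scores[4:, 0]) == -s1[0]).all()
        assert got.variance_explained[0] > 0.9

    def test_duplicated_samples_add_no_variance(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.9, size=(30, 2))
        vals = np.column_stack([base, base])
        aaf = aaf_from_array(vals, list("abcd"))
        got = sp.pca_aaf(aaf)
        assert got.variance_explained[0] > 0
        assert np.isclose(got.variance_explained[2:], 0, atol=1e-12).all()

    def test_scores_invariant_to_sample_permutation(self, design,
                                                    small_pipeline):
        aaf = small_pipeline["aaf"]
        got = sp.pca_aaf(aaf, design)
        perm = np.random.default_rng(2).permutation(aaf.n_samples)
        shuffled = sp.AAFMatrix(
            loci=aaf.loci,
            samples=[aaf.samples[i] for i in perm],
            aaf=aaf.aaf[:, perm],
        )
        got2 = sp.pca_aaf(shuffled, design)
        assert np.allclose(got.scores[perm, 0], got2.scores[:, 0], atol=1e-8)

    def test_pure_merks_scores_negative_by_convention(self, design,
                                                      small_pipeline):
        got = sp.pca_aaf(small_pipeline["aaf"], design)
        pc1 = got.pc1()
        merks = [s.sample_id for s in design if s.ryegrass_content == "Merks"]
        assert pc1[merks].mean() < 0

    def test_mixtures_score_between_pure_clusters_ordered_by_w(
        self, design, small_trial, small_pipeline
    ):
        _, trial = small_trial
        got = sp.pca_aaf(small_pipeline["aaf"], design)
        pc1 = got.pc1()
        merks = [s.sample_id for s in design if s.ryegrass_content == "Merks"]
        meloni = [s.sample_id for s in design
                  if s.ryegrass_content == "Meloni"]
        mixed = [s.sample_id for s in design if s.ryegrass_content == "both"]
        assert pc1[merks].max() < pc1[mixed].min()
        assert pc1[mixed].max() < pc1[meloni].min()
        # more Merks => more negative PC1
        r = np.corrcoef(trial.truth.w[mixed], pc1[mixed])[0, 1]
        assert r < -0.8

    def test_missing_values_rejected(self):
        vals = np.array([[0.5, np.nan], [0.2, 0.3]])
        aaf = aaf_from_array(vals, ["a", "b"])
        with pytest.raises(sp.ValidationError, match="missing"):
            sp.pca_aaf(aaf)


class TestPrivateSnps:
    def make_design(self):
        return [sp.make_sample(c, r, y)
                for c in (1, 2, 5) for r in "AB" for y in (1, 2)]

    def test_definition_on_hand_built_matrix(self):
        design = self.make_design()
        vals = np.zeros((3, len(design)))
        merks_cols = [j for j, s in enumerate(design)
                      if s.ryegrass_content == "Merks"]
        meloni_cols = [j for j, s in enumerate(design)
                       if s.ryegrass_content == "Meloni"]
        vals[0, merks_cols] = 0.3          # locus 0: Merks-private
        vals[1, meloni_cols[0]] = 0.01     # locus 1: polymorphic in Meloni
        vals[1, merks_cols] = 0.3
        vals[2, :] = 0.0                   # locus 2: monomorphic
        aaf = aaf_from_array(vals, [s.sample_id for s in design])
        got = sp.private_snps(aaf, design, "Merks")
        assert got.tolist() == [0]

    def test_no_pure_nonfocal_plots_is_an_error(self):
        design = [sp.make_sample(1, "A", 1), sp.make_sample(5, "A", 1)]
        aaf = aaf_from_array(np.array([[0.1, 0.2]]),
                             [s.sample_id for s in design])
        with pytest.raises(sp.ValidationError, match="no pure"):
            sp.private_snps(aaf, design, "Merks")

    def test_recovery_supersets_truth_without_error_reads(self, design):
        """At eps=0 every surviving true private locus is recovered."""
        cfg = sp.SimulationConfig(n_loci=4000, seed=21, error_rate=0.0)
        trial = sp.simulate_trial(cfg)
        aaf, _ = sp.estimate_aaf_matrix(trial.counts, error_rate=1e-6)
        filt, rep = sp.filter_cascade(trial.counts, aaf,
                                      sp.FilterConfig.pool_preset())
        keep = rep.kept_indices
        for focal, profile in (("Merks", trial.truth.merks),
                               ("Meloni", trial.truth.meloni)):
            found = set(keep[sp.private_snps(filt, design, focal)].tolist())
            surviving_truth = set(profile.private_loci) & set(keep.tolist())
            assert surviving_truth <= found

    def test_recovery_precision_at_default_error_rate(self, design,
                                                      small_pipeline,
                                                      small_trial):
        _, trial = small_trial
        filt = small_pipeline["aaf"]
        keep = small_pipeline["report"].kept_indices
        for focal, profile in (("Merks", trial.truth.merks),
                               ("Meloni", trial.truth.meloni)):
            found = set(keep[sp.private_snps(filt, design, focal)].tolist())
            if found:
                hits = len(found & set(profile.private_loci))
                assert hits / len(found) > 0.9


class TestAbundance:
    def test_pure_plots_estimate_unit_proportion(self, design,
                                                 small_pipeline):
        filt = small_pipeline["aaf"]
        pm = sp.private_snps(filt, design, "Merks")
        po = sp.private_snps(filt, design, "Meloni")
        ab = sp.cultivar_abundance(filt, pm, po, design)
        merks = [s.sample_id for s in design if s.ryegrass_content == "Merks"]
        assert ab.loc[merks, "w_merks"].mean() == pytest.approx(1.0, abs=0.05)

    def test_mixture_proportion_recovered(self, design):
        """50:50 sowing with stable trajectory: w_hat near 0.5."""
        cfg = sp.SimulationConfig(
            n_loci=4000, seed=33,
            trajectory=sp.TrajectoryModel(plot_noise_sd=0.0),
        )
        trial = sp.simulate_trial(cfg)
        aaf, _ = sp.estimate_aaf_matrix(trial.counts)
        filt, rep = sp.filter_cascade(trial.counts, aaf,
                                      sp.FilterConfig.pool_preset())
        pm = sp.private_snps(filt, design, "Merks")
        po = sp.private_snps(filt, design, "Meloni")
        ab = sp.cultivar_abundance(filt, pm, po, design)
        mixed = [s.sample_id for s in design if s.ryegrass_content == "both"]
        assert ab.loc[mixed, "w_merks"].mean() == pytest.approx(0.5, abs=0.1)

    def test_nonmonotone_trajectory_shape_recovered(self, design):
        cfg = sp.SimulationConfig(
            n_loci=4000, seed=34,
            trajectory=sp.TrajectoryModel(
                year_logit_offsets=(0.405, -0.405, -0.405, 0.405),
                plot_noise_sd=0.1,
            ),
        )
        trial = sp.simulate_trial(cfg)
        aaf, _ = sp.estimate_aaf_matrix(trial.counts)
        filt, _ = sp.filter_cascade(trial.counts, aaf,
                                    sp.FilterConfig.pool_preset())
        pm = sp.private_snps(filt, design, "Merks")
        po = sp.private_snps(filt, design, "Meloni")
        ab = sp.cultivar_abundance(filt, pm, po, design)
        mixed = ab[ab.seed_composition.isin([5, 6, 7])]
        by_year = mixed.groupby("year")["w_merks"].mean()
        assert by_year[1] > by_year[2]
        assert by_year[4] > by_year[3]

    def test_empty_private_set_rejected(self, design, small_pipeline):
        filt = small_pipeline["aaf"]
        with pytest.raises(sp.ValidationError, match="non-empty"):
            sp.cultivar_abundance(filt, np.array([], int), np.array([0]),
                                  design)
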