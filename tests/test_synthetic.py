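"""Tests for the synthetic community generator."""

import math

import numpy as np
import pandas as pd
import pytest

import rhizoindic as ri
from rhizoindic import (
    GroundTruth,
    draw_abundances,
    generate_taxonomy,
    g_test,
    perturb_abundances,
    pick_specific_taxon,
    sample_experiment,
    set_proportion,
)
from rhizoindic.errors import DomainError, EmptySelectionError
from rhizoindic.tables import RANKS


class TestTaxonomy:
    def test_unspecific_count_rounds(self):
        t = generate_taxonomy(10, 0.3, seed=1)
        assert t.unspecific_flags.any(axis=1).sum() == 3

    def test_zero_fraction(self):
        t = generate_taxonomy(5, 0.0, seed=1)
        assert not t.unspecific_flags.any().any()

    def test_seed_determinism(self):
        a = generate_taxonomy(10, 0.3, seed=1)
        b = generate_taxonomy(10, 0.3, seed=1)
        pd.testing.assert_frame_equal(a.lineages, b.lineages)

    def test_one_label_per_rank(self):
        t = generate_taxonomy(50, 0.2, seed=3)
        assert list(t.lineages.columns) == list(RANKS)
        assert t.lineages.notna().all().all()

    def test_lineage_consistency(self):
        """Equal labels at a rank imply equal ancestors at all ranks above."""
        t = generate_taxonomy(400, 0.0, seed=4)
        lin = t.lineages
        for r, rank in enumerate(RANKS[1:], start=1):
            parents = lin.groupby(rank)[list(RANKS[:r])].nunique()
            assert (parents == 1).all().all()

    def test_unspecific_labels_at_genus_species_only(self):
        t = generate_taxonomy(200, 0.5, seed=5)
        flags = t.unspecific_flags
        assert not flags[list(RANKS[:5])].any().any()

    def test_domains_cover_bacteria_and_admixture(self):
        t = generate_taxonomy(1000, 0.0, seed=6)
        counts = t.domain_label.value_counts()
        assert counts["Bacteria"] > 900
        assert counts.get("Archaea", 0) == 10  # 1% of 1000
        assert counts.get("Eukaryota", 0) == 20  # 2% of 1000

    def test_empty_input_and_bad_fraction(self):
        with pytest.raises(EmptySelectionError):
            generate_taxonomy(0, 0.3, seed=1)
        with pytest.raises(DomainError):
            generate_taxonomy(5, 1.5, seed=1)


class TestAbundances:
    def test_sigma_zero_is_uniform(self):
        assert np.allclose(draw_abundances(4, 0.0, seed=99), 0.25)

    def test_normalization(self):
        for seed in range(5):
            p = draw_abundances(123, 2.0, seed=seed)
            assert abs(p.sum() - 1.0) < 1e-9
            assert (p >= 0).all()

    def test_lognormal_rare_tail(self):
        """Most taxa sit below the mean share: over 100 replicate draws the
        average fraction of taxa with proportion < 1/n exceeds one half."""
        fracs = [
            (draw_abundances(2000, 2.0, seed=s) < 1 / 2000).mean() for s in range(100)
        ]
        assert np.mean(fracs) > 0.5

    def test_negative_sigma_rejected(self):
        with pytest.raises(DomainError):
            draw_abundances(10, -1.0, seed=0)


class TestPerturb:
    def test_identity_fold(self):
        base = np.array([0.2, 0.3, 0.5])
        assert np.allclose(perturb_abundances(base, {1: 1.0}), base)

    def test_hand_renormalization(self):
        base = np.array([0.1] + [0.9 / 9] * 9)
        out = perturb_abundances(base, {0: 2.0})
        assert out[0] == pytest.approx(0.2 / 1.1)

    def test_fold_zero_annihilates(self):
        out = perturb_abundances(np.array([0.4, 0.6]), {0: 0.0})
        assert out[0] == 0.0 and out[1] == 1.0

    def test_negative_fold_rejected(self):
        with pytest.raises(DomainError):
            perturb_abundances(np.array([0.5, 0.5]), {0: -2.0})


class TestSetProportion:
    def test_pins_exact_value(self):
        base = draw_abundances(50, 2.0, seed=1)
        out = set_proportion(base, 7, 0.1)
        assert out[7] == pytest.approx(0.1)
        assert out.sum() == pytest.approx(1.0)
        # relative composition of the others is preserved
        others = np.delete(np.arange(50), 7)
        assert np.allclose(
            out[others] / out[others].sum(), base[others] / base[others].sum()
        )

    def test_picks_clearly_identified_taxon(self):
        tax = generate_taxonomy(200, 0.4, seed=2)
        base = draw_abundances(200, 2.0, seed=3)
        idx = pick_specific_taxon(tax, base, 0.05)
        assert not tax.unspecific_flags.iloc[idx].any()
        assert tax.domain_label.iloc[idx] == "Bacteria"


class TestExperiment:
    def test_column_totals_equal_depth(self, small_experiment):
        assert (small_experiment.table.sample_totals == 5000).all()

    def test_seed_determinism(self, small_taxonomy):
        truth = GroundTruth(base_proportions=draw_abundances(300, 1.5, seed=1), seed=2)
        a = sample_experiment(truth, small_taxonomy, 1000, n_pairs=2, seed=7)
        b = sample_experiment(truth, small_taxonomy, 1000, n_pairs=2, seed=7)
        pd.testing.assert_frame_equal(a.table.counts, b.table.counts)

    def test_effects_round_trip(self, small_experiment):
        assert small_experiment.truth.effects == {small_experiment.target_index: 4.0}

    def test_large_depth_recovers_fold_change(self, small_taxonomy):
        """No site noise, one million reads: the realized proportion ratio
        of a quadrupled low-abundance taxon lands near 4."""
        base = draw_abundances(300, 2.0, seed=21)
        target = pick_specific_taxon(small_taxonomy, base, 0.01)
        base = set_proportion(base, target, 0.01)
        truth = GroundTruth(
            base_proportions=base, effects={target: 4.0}, overdispersion=math.inf
        )
        exp = sample_experiment(truth, small_taxonomy, 10**6, n_pairs=1, seed=22)
        row = ";".join(small_taxonomy.lineages.iloc[target])
        t, c = exp.table.counts.loc[row]
        assert 3.5 <= t / c <= 4.5

    def test_depth_zero_rejected(self, small_taxonomy):
        truth = GroundTruth(base_proportions=draw_abundances(300, 1.0, seed=1))
        with pytest.raises(DomainError):
            sample_experiment(truth, small_taxonomy, 0, n_pairs=1)

    def test_overdispersion_adds_between_sample_noise(self, small_taxonomy):
        base = draw_abundances(300, 1.0, seed=31)
        tight = GroundTruth(base_proportions=base, overdispersion=math.inf)
        noisy = GroundTruth(base_proportions=base, overdispersion=50.0)
        e_tight = sample_experiment(tight, small_taxonomy, 20_000, 5, seed=32)
        e_noisy = sample_experiment(noisy, small_taxonomy, 20_000, 5, seed=32)
        v_tight = e_tight.table.counts.var(axis=1).sum()
        v_noisy = e_noisy.table.counts.var(axis=1).sum()
        assert v_noisy > 2 * v_tight

    def test_null_pairs_reject_at_nominal_rate(self, small_taxonomy):
        """Exchangeability: with no effects and no site noise, a G-test on
        each pair's common taxa rejects at about the nominal 5% level."""
        base = draw_abundances(300, 1.0, seed=41)
        truth = GroundTruth(base_proportions=base)
        rejections = 0
        n_rep = 400
        exp = sample_experiment(truth, small_taxonomy, 2000, n_pairs=n_rep, seed=42)
        for _, row in exp.manifest.iterrows():
            cnt = exp.table.counts[[row.treated_sample, row.control_sample]]
            common = cnt[(cnt > 0).all(axis=1)]
            _, _, p = g_test(common.to_numpy().T)
            rejections += p < 0.05
        rate = rejections / n_rep
        mc_se = math.sqrt(0.05 * 0.95 / n_rep)
        assert rate < 0.05 + 3 * mc_se
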