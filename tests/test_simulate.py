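"""Synthetic-data generators: trees, threats, occurrences, masks, grafting."""

import numpy as np
import pandas as pd
import pytest

from cycadrisk import clade_tips, faith_pd, fair_proportion_ed, mrca, prune_to
from cycadrisk.simulate import (
    SimConfig,
    SimulationError,
    genus_of,
    graft_missing_taxa,
    simulate_cycad_like_tree,
    simulate_occurrences,
    simulate_protected_mask,
    simulate_threats,
    simulate_tree,
)


class TestSimulateTree:
    def test_conditioned_yule_tree(self):
        t = simulate_tree(SimConfig(seed=1, n_species=50, birth=0.1))
        assert t.n_tips == 50
        assert t.is_ultrametric()

    def test_determinism(self):
        cfg = SimConfig(seed=9, n_species=30, birth=0.2, death=0.05)
        assert simulate_tree(cfg).to_newick() == simulate_tree(cfg).to_newick()

    def test_birth_death_prunes_extinct(self):
        t = simulate_tree(SimConfig(seed=2, n_species=40, birth=0.3, death=0.15))
        assert t.n_tips == 40
        assert t.is_ultrametric()
        assert all(len(t.children(i)) in (0, 2) for i in range(t.n_nodes))

    def test_zero_birth_rejected(self):
        with pytest.raises(SimulationError, match="birth"):
            simulate_tree(SimConfig(seed=0, n_species=10, birth=0.0))

    def test_yule_lineage_growth_law(self):
        # E[N(T)] = 2 exp(rT) from 2 lineages; check within 3 standard errors
        r, T = 0.1, 10.0
        counts = [
            simulate_tree(
                SimConfig(seed=1000 + i, n_species=2, birth=r), duration=T
            ).n_tips
            for i in range(800)
        ]
        counts = np.asarray(counts, dtype=float)
        expected = 2.0 * np.exp(r * T)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3.0 * se


class TestCycadLikeTree:
    def test_shape_and_monophyly(self, full_dataset, full_config):
        tree = full_dataset["tree"]
        assert tree.n_tips == full_config.n_species
        assert tree.is_ultrametric()
        genera = {}
        for lab in tree.tip_labels:
            genera.setdefault(genus_of(lab), []).append(lab)
        assert len(genera) == full_config.n_genera
        for genus, labs in genera.items():
            if len(labs) > 1:
                assert clade_tips(tree, mrca(tree, labs)) == set(labs), genus

    def test_stems_exceed_crowns(self, small_dataset):
        tree = small_dataset["tree"]
        ages = tree.ages()
        genera = {}
        for lab in tree.tip_labels:
            genera.setdefault(genus_of(lab), []).append(lab)
        crowns = [
            ages[mrca(tree, labs)] for labs in genera.values() if len(labs) > 1
        ]
        assert max(crowns) <= 13.0
        # every stem attachment sits on the >= 40 Myr backbone
        backbone = [
            ages[tree.parents[mrca(tree, labs)]] for labs in genera.values()
        ]
        assert min(backbone) >= 40.0

    def test_monotypic_genus_has_higher_ed_than_big_genus(self):
        cfg = SimConfig(seed=3, n_species=120, n_genera=5)
        tree = simulate_cycad_like_tree(cfg)
        ed = fair_proportion_ed(tree)
        sizes = {}
        for lab in tree.tip_labels:
            sizes.setdefault(genus_of(lab), []).append(lab)
        by_size = sorted(sizes.values(), key=len)
        smallest, largest = by_size[0], by_size[-1]
        assert len(largest) >= 20
        assert ed[smallest].mean() > ed[largest].mean()

    def test_too_few_species_rejected(self):
        with pytest.raises(SimulationError, match="n_species"):
            simulate_cycad_like_tree(SimConfig(seed=0, n_species=5, n_genera=6))


class TestThreats:
    def test_clustered_mode_matches_marginals_exactly(self, full_dataset):
        counts = full_dataset["threats"]["category"].value_counts()
        assert counts["VU"] == 78 and counts["EN"] == 70 and counts["CR"] == 67
        threatened = counts.reindex(["VU", "EN", "CR"]).sum()
        assert threatened == 215

    def test_iid_mode_within_binomial_error(self):
        cfg = SimConfig(seed=5, threat_mode="iid")
        tree = simulate_cycad_like_tree(cfg)
        th = simulate_threats(tree, cfg)
        n, p = 339, 215 / 339
        observed = th["category"].isin(["VU", "EN", "CR"]).sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(observed - n * p) < 4 * sd

    def test_degenerate_probs_give_uniform_category(self, small_dataset):
        cfg = SimConfig(seed=1, n_species=20, n_genera=3,
                        category_probs={"LC": 1.0}, threat_mode="iid")
        tree = simulate_cycad_like_tree(cfg)
        th = simulate_threats(tree, cfg)
        assert set(th["category"]) == {"LC"}

    def test_determinism(self, full_config, full_dataset):
        again = simulate_threats(full_dataset["tree"], full_config)
        pd.testing.assert_frame_equal(again, full_dataset["threats"])


class TestOccurrences:
    def test_every_species_occupies_a_cell(self, small_dataset):
        occ = small_dataset["occurrences"]
        assert (occ.range_sizes() >= 1).all()

    def test_we_conservation_downstream(self, small_dataset):
        from cycadrisk import weighted_endemism

        we, _ = weighted_endemism(small_dataset["occurrences"])
        assert we.sum() == pytest.approx(small_dataset["occurrences"].n_species)

    def test_sisters_overlap_more_than_random_pairs(self):
        # Brownian niche centers should make close relatives co-occur
        overlaps_sister, overlaps_random = [], []
        for rep in range(25):
            cfg = SimConfig(seed=200 + rep, n_species=60, n_genera=6,
                            grid_width=20, grid_height=10)
            tree = simulate_cycad_like_tree(cfg)
            occ = simulate_occurrences(tree, cfg)
            pres = occ.presence
            rng = np.random.default_rng(rep)

            def jaccard(a, b):
                u = (pres.loc[a] | pres.loc[b]).sum()
                return (pres.loc[a] & pres.loc[b]).sum() / u if u else 0.0

            for i in range(tree.n_nodes):
                kids = tree.children(i)
                if len(kids) == 2 and all(tree.is_tip(c) for c in kids):
                    a = tree.labels[kids[0]]
                    b = tree.labels[kids[1]]
                    overlaps_sister.append(jaccard(a, b))
                    x, y = rng.choice(tree.tip_labels, size=2, replace=False)
                    overlaps_random.append(jaccard(x, y))
        assert np.mean(overlaps_sister) > np.mean(overlaps_random)


class TestProtectedMask:
    @pytest.mark.parametrize("frac,expect", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_fractions(self, frac, expect):
        cfg = SimConfig(seed=0, protected_fraction=frac)
        mask = simulate_protected_mask(cfg)
        assert (mask == expect).all()

    def test_mean_close_to_target_and_reproducible(self):
        cfg = SimConfig(seed=12, protected_fraction=0.3)
        mask = simulate_protected_mask(cfg)
        assert abs(mask.mean() - 0.3) < 0.05
        pd.testing.assert_series_equal(mask, simulate_protected_mask(cfg))
        assert mask.between(0, 1).all()


class TestGrafting:
    def test_empty_list_is_identity(self, small_dataset):
        tree = small_dataset["tree"]
        assert graft_missing_taxa(tree, {}, seed=1) is tree

    def test_grow_two_tip_genus(self):
        cfg = SimConfig(seed=4, n_species=12, n_genera=4)
        tree = simulate_cycad_like_tree(cfg)
        genus = genus_of(tree.tip_labels[0])
        before = [lab for lab in tree.tip_labels if genus_of(lab) == genus]
        out = graft_missing_taxa(tree, {f"{genus}_extra": genus}, seed=2)
        after = [lab for lab in out.tip_labels if genus_of(lab) == genus]
        assert len(after) == len(before) + 1
        assert clade_tips(out, mrca(out, after)) == set(after)
        assert out.is_ultrametric()

    def test_type2_scale_graft(self):
        # 199-tip constraint tree completed to 339 taxa
        cfg = SimConfig(seed=3, n_species=199, n_genera=11)
        base = simulate_cycad_like_tree(cfg)
        genera = sorted({genus_of(lab) for lab in base.tip_labels})
        rng = np.random.default_rng(5)
        new = {
            f"{genera[rng.integers(len(genera))]}_new{i:03d}": None
            for i in range(140)
        }
        new = {k: genus_of(k) for k in new}
        full = graft_missing_taxa(base, new, seed=9)
        assert full.n_tips == 339
        assert full.is_ultrametric()
        # original tip relationships are untouched: restriction matches exactly
        restricted = prune_to(full, base.tip_labels)
        assert restricted.total_length == pytest.approx(base.total_length)
        assert faith_pd(full, base.tip_labels) == pytest.approx(base.total_length)

    def test_unknown_genus_rejected(self, small_dataset):
        with pytest.raises(SimulationError, match="no anchor"):
            graft_missing_taxa(small_dataset["tree"], {"Ghost_sp1": "Ghost"}, seed=0)
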