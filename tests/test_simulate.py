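import numpy as np
import pytest

import sctreesig as st
from sctreesig.simulate import DEFAULT_SAMPLES

from oracles import reflecting_walk_stationary


def clade_count(tree, cells):
    """Number of maximal clades covering the cell set (1 = monophyletic)."""
    cells = set(cells)
    t = tree.tree
    count = 0

    def walk(node):
        nonlocal count
        tips = {l.taxon.label for l in node.leaf_iter()}
        if tips <= cells:
            count += 1
            return
        if tips & cells:
            for ch in node.child_nodes():
                walk(ch)

    walk(t.seed_node)
    return count


class TestSimulateTree:
    def test_monophyletic_samples_are_clades(self):
        cfg = st.SimulationConfig(monophyly={s: True for s in DEFAULT_SAMPLES},
                                  seed=1)
        tree, labels = st.simulate_tree(cfg)
        for sample in DEFAULT_SAMPLES:
            cells = [c for c, s in labels.items() if s == sample]
            assert clade_count(tree, cells) == 1

    def test_polyphyletic_group_spans_clades(self):
        cfg = st.SimulationConfig(seed=2)  # CTC2 polyphyletic by default
        tree, labels = st.simulate_tree(cfg)
        ctc2 = [c for c, s in labels.items() if s == "CTC2"]
        assert clade_count(tree, ctc2) >= 2

    def test_tip_set_matches_config(self):
        cfg = st.SimulationConfig(samples={"X": 3, "Y": 2},
                                  monophyly={"X": True, "Y": True}, seed=3)
        tree, labels = st.simulate_tree(cfg)
        assert tree.n_tips == 5
        assert set(tree.tip_labels) == set(labels)

    def test_branch_lengths_positive(self):
        tree, _ = st.simulate_tree(st.SimulationConfig(seed=4))
        assert all(l is not None and l > 0 for l in tree.branch_lengths())

    def test_seed_determinism(self):
        cfg = st.SimulationConfig(seed=99)
        t1, l1 = st.simulate_tree(cfg)
        t2, l2 = st.simulate_tree(cfg)
        assert st.write_newick(t1) == st.write_newick(t2)
        assert l1 == l2

    def test_no_monophyletic_sample_rejected(self):
        cfg = st.SimulationConfig(samples={"X": 3},
                                  monophyly={"X": False})
        with pytest.raises(ValueError, match="monophyletic"):
            st.simulate_tree(cfg)


class TestEvolveOrdinal:
    def test_rate_zero_all_root_state(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 10, 0.0, seed=1)
        assert (m.values == 3.0).all()

    def test_values_complete_and_in_range(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 50, 2.0, seed=2)
        assert not np.isnan(m.values).any()
        assert m.values.min() >= 1 and m.values.max() <= 5

    def test_high_rate_approaches_stationary(self):
        # single long branch: state distribution -> stationary of the
        # reflecting walk (eigen-oracle: proportional to node degree)
        tree = st.parse_newick("(a:500,b:500);")
        m = st.evolve_ordinal(tree, 40_000, 1.0, seed=3)
        freqs = np.array([(m.values == k).mean() for k in range(1, 6)])
        np.testing.assert_allclose(freqs, reflecting_walk_stationary(),
                                   atol=0.02)

    def test_seed_determinism(self, balanced_tree):
        m1 = st.evolve_ordinal(balanced_tree, 30, 1.0, seed=7)
        m2 = st.evolve_ordinal(balanced_tree, 30, 1.0, seed=7)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_negative_rate(self, balanced_tree):
        with pytest.raises(ValueError, match="rate"):
            st.evolve_ordinal(balanced_tree, 5, -1.0)


class TestEvolveSnv:
    def test_rate_zero_identical_tips(self, balanced_tree):
        m = st.evolve_snv(balanced_tree, 30, 0.0, seed=1)
        assert (m.values == m.values[0]).all()

    def test_jc_expected_mismatch(self):
        # two tips at path distance d: mismatch ~ (3/4)(1 - exp(-4d/3))
        for d, seed in ((0.2, 11), (0.8, 12)):
            tree = st.parse_newick(f"(a:{d / 2},b:{d / 2});")
            m = st.evolve_snv(tree, 10_000, 1.0, seed=seed)
            frac = (m.values[0] != m.values[1]).mean()
            expect = 0.75 * (1 - np.exp(-4 * d / 3))
            se = np.sqrt(expect * (1 - expect) / 10_000)
            assert abs(frac - expect) < 3 * se

    def test_seed_determinism(self, balanced_tree):
        m1 = st.evolve_snv(balanced_tree, 30, 1.0, seed=7)
        m2 = st.evolve_snv(balanced_tree, 30, 1.0, seed=7)
        np.testing.assert_array_equal(m1.values, m2.values)


class TestApplyDropout:
    def test_keep_all(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 20, 1.0, seed=1)
        out, _ = st.apply_dropout(m, 1.0, seed=2)
        assert st.data_density(out).density == 1.0

    def test_keep_none(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 20, 1.0, seed=1)
        out, _ = st.apply_dropout(m, 0.0, seed=2)
        assert st.data_density(out).density == 0.0

    def test_realized_density_binomial(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 10_000, 1.0, seed=1)
        out, _ = st.apply_dropout(m, ("fixed", 0.3), seed=2)
        assert abs(st.data_density(out).density - 0.3) < 0.01

    def test_beta_rates_in_range(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 50, 1.0, seed=1)
        _, rates = st.apply_dropout(m, ("beta", 0.4, 4.0), seed=3)
        assert ((rates >= 0) & (rates <= 1)).all()
        assert rates.shape == (m.n_cells,)

    def test_snv_dropout_uses_n(self, balanced_tree):
        m = st.evolve_snv(balanced_tree, 50, 1.0, seed=1)
        out, _ = st.apply_dropout(m, 0.5, seed=2)
        assert (out.values == "N").any()

    def test_seed_determinism(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 40, 1.0, seed=1)
        o1, r1 = st.apply_dropout(m, ("beta", 0.5, 2.0), seed=9)
        o2, r2 = st.apply_dropout(m, ("beta", 0.5, 2.0), seed=9)
        np.testing.assert_array_equal(o1.values, o2.values)
        np.testing.assert_array_equal(r1, r2)

    def test_invalid_distribution(self, balanced_tree):
        m = st.evolve_ordinal(balanced_tree, 5, 1.0, seed=1)
        with pytest.raises(ValueError, match="keep-rate"):
            st.apply_dropout(m, ("gamma", 1.0), seed=1)


class TestGenerateBaseCounts:
    def test_depth_at_least_one_where_known(self, balanced_tree):
        m = st.evolve_snv(balanced_tree, 40, 1.0, seed=1)
        obs, _ = st.apply_dropout(m, 0.5, seed=2)
        table = st.generate_base_counts(obs, depth_mean=2.0, error_rate=0.1,
                                        seed=3)
        depths = table[["A", "C", "G", "T"]].sum(axis=1)
        assert (depths >= 1).all()
        assert len(table) == int(obs.known_mask().sum())

    def test_error_zero_counts_pure(self, balanced_tree):
        m = st.evolve_snv(balanced_tree, 40, 1.0, seed=1)
        table = st.generate_base_counts(m, depth_mean=3.0, error_rate=0.0,
                                        seed=4)
        nonzero = (table[["A", "C", "G", "T"]] > 0).sum(axis=1)
        assert (nonzero == 1).all()

    def test_seed_determinism(self, balanced_tree):
        m = st.evolve_snv(balanced_tree, 30, 1.0, seed=1)
        t1 = st.generate_base_counts(m, seed=5)
        t2 = st.generate_base_counts(m, seed=5)
        assert t1.equals(t2)


class TestSimulateDataset:
    def test_bit_reproducible(self):
        cfg = st.SimulationConfig(samples={"X": 4, "Y": 3},
                                  monophyly={"X": True, "Y": True},
                                  n_genes=30, n_sites=20, seed=77)
        d1 = st.simulate_dataset(cfg)
        d2 = st.simulate_dataset(cfg)
        assert st.write_newick(d1.truth.tree) == st.write_newick(d2.truth.tree)
        np.testing.assert_array_equal(d1.ordinal_observed.values,
                                      d2.ordinal_observed.values)
        np.testing.assert_array_equal(d1.snv_observed.values,
                                      d2.snv_observed.values)
        np.testing.assert_array_equal(d1.expression.values,
                                      d2.expression.values,)
        assert d1.base_counts.equals(d2.base_counts)

    def test_dataset_shapes_consistent(self, tiny_dataset):
        ds = tiny_dataset
        n = sum(ds.config.samples.values())
        assert ds.truth.tree.n_tips == n
        assert ds.ordinal_observed.n_cells == n
        assert ds.snv_observed.n_cells == n
        assert set(ds.truth.labels) == set(ds.ordinal_observed.cell_ids)
        assert len(ds.sites) == ds.config.n_sites

    def test_expression_reflects_ordinal_truth(self, tiny_dataset):
        ds = tiny_dataset
        known = ~np.isnan(ds.expression.values)
        np.testing.assert_array_equal(known,
                                      ds.ordinal_observed.known_mask())

    def test_label_shuffle_negative_control(self, rng):
        """After shuffling sample labels, FDR-significant calls occur at
        no more than the nominal rate."""
        cfg = st.SimulationConfig(
            samples={"A": 8, "B": 8, "C": 8},
            monophyly={"A": True, "B": True, "C": True},
            n_genes=100, dropout=("fixed", 0.6), seed=5)
        n_sig = n_tests = 0
        for rep in range(10):
            ds = st.simulate_dataset(
                st.SimulationConfig(**{**cfg.__dict__, "seed": 5 + rep}))
            cells = list(ds.truth.labels)
            shuffled_vals = rng.permutation([ds.truth.labels[c] for c in cells])
            labels = dict(zip(cells, shuffled_vals))
            ordinal = st.discretize_expression(ds.expression)
            tree = st.nj_tree(ordinal, "ordinal")
            results = [st.permutation_test(tree, labels, g, statistic=s,
                                           n_perm=199, seed=rep)
                       for g in ("A", "B", "C") for s in ("mpd", "mntd")]
            st.fdr_correct(results, alpha=0.05)
            n_sig += sum(r.fdr_significant for r in results)
            n_tests += len(results)
        assert n_sig / n_tests <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_tests)
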