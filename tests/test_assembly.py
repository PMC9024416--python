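import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio

from guyot.assembly import (
    beta_mntd_pair,
    bnti,
    classify_pair,
    partition_processes,
    raup_crick,
)
from guyot.data_io import CoverageError, OtuTable, PhyloTree


def _table(rows: dict[str, dict[str, int]], otus: list[str]) -> OtuTable:
    counts = pd.DataFrame(0, index=list(rows), columns=otus)
    for sid, vals in rows.items():
        for o, c in vals.items():
            counts.loc[sid, o] = c
    return OtuTable(counts)


class TestBetaMntd:
    def test_identical_communities_zero(self, four_taxon_tree):
        d = four_taxon_tree.patristic_matrix()
        a = pd.Series({"A": 0.5, "B": 0.5})
        assert beta_mntd_pair(a, a, d) == pytest.approx(0.0)

    def test_single_taxon_hand_computation(self, four_taxon_tree):
        d = four_taxon_tree.patristic_matrix()
        a = pd.Series({"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0})
        b = pd.Series({"A": 0.0, "B": 0.0, "C": 1.0, "D": 0.0})
        assert beta_mntd_pair(a, b, d) == pytest.approx(4.0)

    def test_missing_otu_raises_coverage_error(self, four_taxon_tree):
        d = four_taxon_tree.patristic_matrix()
        a = pd.Series({"A": 1.0, "X": 1.0})
        with pytest.raises(CoverageError):
            beta_mntd_pair(a, a, d)

    def test_matches_nested_loop_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        tree = PhyloTree(
            skbio.TreeNode.read(["((A:0.5,B:1.2):0.3,((C:0.7,D:0.2):0.4,(E:1,F:0.9):0.1):0.6);"])
        )
        d = tree.patristic_matrix()
        otus = list("ABCDEF")
        for _ in range(20):
            fa = pd.Series(rng.random(6) * (rng.random(6) > 0.3), index=otus)
            fb = pd.Series(rng.random(6) * (rng.random(6) > 0.3), index=otus)
            if fa.sum() == 0 or fb.sum() == 0:
                continue
            got = beta_mntd_pair(fa, fb, d)
            # independent brute force
            pa = fa[fa > 0] / fa[fa > 0].sum()
            pb = fb[fb > 0] / fb[fb > 0].sum()
            term_a = sum(
                w * min(d.loc[i, j] for j in pb.index) for i, w in pa.items()
            )
            term_b = sum(
                w * min(d.loc[j, i] for i in pa.index) for j, w in pb.items()
            )
            expected = 0.5 * (term_a + term_b)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_relabeling_invariance(self, four_taxon_tree):
        rng = np.random.default_rng(1)
        d = four_taxon_tree.patristic_matrix()
        otus = list("ABCD")
        fa = pd.Series(rng.random(4), index=otus)
        fb = pd.Series(rng.random(4), index=otus)
        v = beta_mntd_pair(fa, fb, d)
        assert v >= 0
        # joint relabeling of OTUs leaves the statistic unchanged
        relabel = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        d2 = d.rename(index=relabel, columns=relabel)
        fa2 = fa.rename(relabel)
        fb2 = fb.rename(relabel)
        assert beta_mntd_pair(fa2, fb2, d2) == pytest.approx(v, abs=1e-12)


class TestBnti:
    def _exact_null(self, table: OtuTable, tree: PhyloTree):
        """Exhaustive tip-permutation null for a 4-taxon tree."""
        d = tree.patristic_matrix(table.otu_ids)
        otus = table.otu_ids
        freq = table.relative_abundance()
        vals = {}
        for pair in itertools.combinations(table.sample_ids, 2):
            a, b = pair
            nulls = []
            for perm in itertools.permutations(otus):
                mapping = dict(zip(otus, perm))
                dp = d.rename(index=mapping, columns=mapping)
                nulls.append(beta_mntd_pair(freq.loc[a], freq.loc[b], dp))
            nulls = np.array(nulls)
            obs = beta_mntd_pair(freq.loc[a], freq.loc[b], d)
            vals[pair] = (obs - nulls.mean()) / nulls.std()
        return vals

    def test_monte_carlo_within_3se_of_exact_enumeration(self, four_taxon_tree):
        table = _table(
            {"s1": {"A": 6, "B": 3, "C": 1}, "s2": {"C": 5, "D": 5}},
            list("ABCD"),
        )
        exact = self._exact_null(table, four_taxon_tree)[("s1", "s2")]
        n_null = 999
        estimates = [
            bnti(table, four_taxon_tree, n_null=n_null, seed=s).bnti.loc["s1", "s2"]
            for s in range(20)
        ]
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean() - exact) < 3 * se + 0.02

    def test_star_tree_null_degenerate_flagged(self):
        tree = PhyloTree(skbio.TreeNode.read(["(A:1,B:1,C:1,D:1);"]))
        table = _table({"s1": {"A": 5, "B": 5}, "s2": {"C": 5, "D": 5}}, list("ABCD"))
        res = bnti(table, tree, n_null=99, seed=0)
        assert np.isnan(res.bnti.loc["s1", "s2"])

    def test_random_assembly_calibration(self):
        # communities random w.r.t. the phylogeny: |betaNTI| <= 2 for ~95%
        from guyot.simulate import simulate_tree

        tree = simulate_tree(60, seed=8)
        otus = tree.tip_names
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.multinomial(100, np.ones(60) / 60, size=12),
            index=[f"s{i}" for i in range(12)],
            columns=otus,
        )
        res = bnti(OtuTable(counts), tree, n_null=299, seed=1)
        z = res.bnti.to_numpy()[np.triu_indices(12, 1)]
        assert np.mean(np.abs(z) <= 2) >= 0.85

    def test_invariant_to_joint_relabeling(self, four_taxon_tree):
        table = _table({"s1": {"A": 4, "B": 1}, "s2": {"C": 3, "D": 2}}, list("ABCD"))
        res1 = bnti(table, four_taxon_tree, n_null=199, seed=7)
        relabel = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        tree2 = PhyloTree(
            skbio.TreeNode.read(["((W:1,X:1):1,(Y:1,Z:1):1);"])
        )
        counts2 = table.counts.rename(columns=relabel)
        res2 = bnti(OtuTable(counts2), tree2, n_null=199, seed=7)
        assert res1.bnti.loc["s1", "s2"] == pytest.approx(
            res2.bnti.loc["s1", "s2"], abs=1e-12
        )


class TestRaupCrick:
    def test_full_pool_samples_all_ties_give_zero(self):
        table = _table(
            {"s1": {"A": 1, "B": 1, "C": 1}, "s2": {"A": 2, "B": 2, "C": 2}},
            list("ABC"),
        )
        res = raup_crick(table, n_null=199, seed=0)
        assert res.brc.loc["s1", "s2"] == pytest.approx(0.0)

    def test_monte_carlo_matches_exact_enumeration(self):
        # pool of 4 equally-occupied OTUs, both samples richness 2, disjoint:
        # enumerate all C(4,2)^2 = 36 equally-likely draw pairs
        table = _table(
            {
                "s1": {"A": 3, "B": 2},
                "s2": {"C": 4, "D": 1},
                # two extra samples equalize occupancy across the pool
                "s3": {"A": 1, "B": 1, "C": 1, "D": 1},
                "s4": {"A": 1, "B": 1, "C": 1, "D": 1},
            },
            list("ABCD"),
        )
        ss_obs = 0
        exact_stats = []
        for sa in itertools.combinations("ABCD", 2):
            for sb in itertools.combinations("ABCD", 2):
                shared = len(set(sa) & set(sb))
                exact_stats.append(shared)
        exact_stats = np.array(exact_stats)
        p_exact = (np.sum(exact_stats > ss_obs) + 0.5 * np.sum(exact_stats == ss_obs)) / 36
        brc_exact = 2 * (p_exact - 0.5)

        n_null = 999
        vals = np.array(
            [
                raup_crick(table, n_null=n_null, seed=s, weighting="equal").brc.loc[
                    "s1", "s2"
                ]
                for s in range(20)
            ]
        )
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - brc_exact) < 3 * se + 0.01

    def test_symmetry_and_range(self, random_table):
        res = raup_crick(random_table, n_null=199, seed=2)
        m = res.brc.to_numpy()
        assert np.allclose(m, m.T)
        assert (m >= -1 - 1e-12).all() and (m <= 1 + 1e-12).all()

    def test_null_true_calibration(self):
        # communities drawn by (a close analogue of) the null itself: most
        # pairs should land in the drift band
        rng = np.random.default_rng(3)
        n_s, n_o = 12, 80
        pres = rng.random((n_s, n_o)) < 0.4
        pres[:, 0] = True  # keep rows non-empty
        counts = pd.DataFrame(
            pres.astype(int) * 3,
            index=[f"s{i}" for i in range(n_s)],
            columns=[f"o{j}" for j in range(n_o)],
        )
        res = raup_crick(OtuTable(counts), n_null=499, seed=4)
        vals = res.brc.to_numpy()[np.triu_indices(n_s, 1)]
        assert np.mean(np.abs(vals) < 0.95) >= 0.80


class TestPartition:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (3.0, 0.0, "variable_selection"),
            (-3.0, 0.0, "homogeneous_selection"),
            (0.0, 0.99, "dispersal_limitation"),
            (0.0, -0.99, "homogeneous_dispersal"),
            (0.0, 0.2, "drift"),
        ],
    )
    def test_threshold_truth_table(self, z, rc, expected):
        assert classify_pair(z, rc) == expected

    def test_selection_ignores_rc(self):
        assert classify_pair(2.5, 0.99) == "variable_selection"
        assert classify_pair(-2.5, -0.99) == "homogeneous_selection"

    def test_five_pairs_one_per_class_fractions(self):
        ids = [f"s{i}" for i in range(5)]
        z = pd.DataFrame(0.0, index=ids, columns=ids)
        rc = pd.DataFrame(0.0, index=ids, columns=ids)
        cases = [
            ("s0", "s1", 3.0, 0.0),
            ("s0", "s2", -3.0, 0.0),
            ("s0", "s3", 0.0, 0.99),
            ("s0", "s4", 0.0, -0.99),
            ("s1", "s2", 0.0, 0.2),
        ]
        # fill remaining pairs as drift too, then subset to the five
        for a, b, zz, rr in cases:
            z.loc[a, b] = z.loc[b, a] = zz
            rc.loc[a, b] = rc.loc[b, a] = rr
        part = partition_processes(z, rc)
        sub = part.pairs.set_index(["sample_a", "sample_b"])
        for a, b, zz, rr in cases:
            expected = classify_pair(zz, rr)
            assert sub.loc[(a, b), "process"] == expected
        assert sum(part.fractions.values()) == pytest.approx(1.0)

    def test_undefined_bnti_excluded_and_counted(self):
        ids = ["a", "b", "c"]
        z = pd.DataFrame(0.0, index=ids, columns=ids)
        z.loc["a", "b"] = z.loc["b", "a"] = np.nan
        rc = pd.DataFrame(0.5, index=ids, columns=ids)
        part = partition_processes(z, rc)
        assert part.n_excluded == 1
        assert part.n_pairs == 2
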