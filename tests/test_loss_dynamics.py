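import itertools
from fractions import Fraction
from math import comb

import dendropy
import numpy as np
import pytest
from scipy import stats as sps

from cifdyn.dataio import (
    GenePair,
    GeneRecord,
    LofMutation,
    Phenotype,
    Role,
    StrainRecord,
    read_newick,
)
from cifdyn.loss_dynamics import (
    binomial_two_sided,
    count_independent_lof_events,
    dispersion_test,
    fisher_exact_2x2,
    fisher_rate_compare,
    lof_event_subtrees,
    loss_order_test,
    paralog_distance_test,
    per_site_lof_rate,
    phenotype_association,
    pseudo_frequency_test,
    rxc_exact,
    terminal_branch_fraction,
)
from cifdyn.phylo import DistanceMatrix


class TestExactBinomial:
    def test_fourteen_vs_four_rounds_to_point_oh_three(self):
        # cifB-only vs cifA-only singly-pseudogenized pairs
        res = loss_order_test(14, 4)
        assert round(res.p_value, 2) == 0.03

    def test_symmetric_counts_give_p_one(self):
        assert loss_order_test(9, 9).p_value == 1.0

    def test_exact_tail_summation_oracle(self):
        # independent enumeration over the 2^18 equally likely outcomes,
        # summing those whose count probability <= that of 14
        n, k = 18, 14
        obs = comb(n, k)
        num = sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= obs)
        assert binomial_two_sided(k, n) == float(Fraction(num, 2**n))

    def test_agrees_with_scipy_binomtest(self):
        for n, k in [(18, 14), (10, 2), (25, 13), (40, 30), (7, 0)]:
            assert binomial_two_sided(k, n) == pytest.approx(
                sps.binomtest(k, n).pvalue, rel=1e-12
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            loss_order_test(0, 0)


class TestFisher:
    def test_no_pseudogenes_anywhere_gives_p_one(self):
        assert pseudo_frequency_test(0, 10, 0, 10).p_value == 1.0

    def test_row_swap_leaves_p_unchanged(self):
        p1 = pseudo_frequency_test(15, 124, 27, 97).p_value
        p2 = pseudo_frequency_test(27, 97, 15, 124).p_value
        assert p1 == p2

    def test_printed_frequencies_reproduced(self):
        res = pseudo_frequency_test(15, 124, 27, 97)
        assert res.extra["freq_a"] == pytest.approx(0.121, abs=0.001)
        assert res.extra["freq_b"] == pytest.approx(0.278, abs=0.001)

    def test_hypergeometric_enumeration_oracle(self):
        # p for the 15/124 vs 27/97 table from full enumeration over all
        # tables with the observed margins, in exact rational arithmetic
        a, b, c, d = 15, 109, 27, 70
        r1, r2, c1 = a + b, c + d, a + c
        N = r1 + r2
        weights = {
            x: comb(r1, x) * comb(r2, c1 - x)
            for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        }
        exact = Fraction(
            sum(w for w in weights.values() if w <= weights[a]), comb(N, c1)
        )
        assert fisher_exact_2x2([[a, b], [c, d]]) == float(exact)

    def test_agrees_with_scipy_on_assorted_tables(self):
        for table in [[[14, 1], [3, 13]], [[15, 109], [27, 70]],
                      [[2, 8], [6, 4]], [[0, 5], [5, 0]]]:
            assert fisher_exact_2x2(table) == pytest.approx(
                sps.fisher_exact(table)[1], rel=1e-12
            )

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestRates:
    def test_zero_events_zero_rate(self):
        assert per_site_lof_rate(0, 10_000) == 0.0

    def test_rate_arithmetic(self):
        assert per_site_lof_rate(10, 10_000) == pytest.approx(1e-3)

    def test_equal_rates_give_p_one(self):
        assert fisher_rate_compare(5, 1000, 5, 1000).p_value == 1.0

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            per_site_lof_rate(1, 0)


class TestIndependentEventCount:
    def _tree(self, newick):
        return read_newick(newick)

    def test_mutation_in_one_leaf_counts_once(self):
        t = self._tree("((A,B),(C,D));")
        assert count_independent_lof_events(t, {"m": {"A"}}) == 1

    def test_sister_leaves_coinherited_counts_once(self):
        t = self._tree("((A,B),(C,D));")
        assert count_independent_lof_events(t, {"m": {"A", "B"}}) == 1

    def test_duplicated_pairs_within_genome_count_once(self):
        # identical lesion in two paralogous pairs that are sisters on the
        # gene tree (a within-genome duplication)
        t = self._tree("((wRi_p1,wRi_p3),(x,y));")
        assert count_independent_lof_events(t, {"m": {"wRi_p1", "wRi_p3"}}) == 1

    def test_separated_carriers_count_twice(self):
        t = self._tree("((A,B),(C,D));")
        assert count_independent_lof_events(t, {"m": {"A", "C"}}) == 2

    def test_multiple_mutations_sum(self):
        t = self._tree("((A,B),(C,D));")
        presence = {"m1": {"A"}, "m2": {"C", "D"}}
        assert count_independent_lof_events(t, presence) == 2

    def test_unknown_leaf_rejected(self):
        t = self._tree("((A,B),(C,D));")
        with pytest.raises(ValueError, match="absent"):
            count_independent_lof_events(t, {"m": {"Z"}})

    def test_matches_brute_force_on_random_six_leaf_cases(self):
        # oracle: minimum number of clades (gain points) covering exactly
        # the carrier set, by exhaustive subset search over clades
        rng = np.random.default_rng(0)
        for _ in range(30):
            nwk = _random_topology(6, rng)
            t = read_newick(nwk)
            clades = []
            for nd in t.preorder_node_iter():
                clades.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
            leaves = sorted(max(clades, key=len))
            carriers = {l for l in leaves if rng.random() < 0.5}
            if not carriers:
                continue
            candidates = [c for c in clades if c <= carriers]
            best = None
            for r in range(1, len(candidates) + 1):
                for combo in itertools.combinations(candidates, r):
                    if set().union(*combo) == carriers:
                        best = r
                        break
                if best is not None:
                    break
            assert count_independent_lof_events(t, {"m": carriers}) == best


def _random_topology(n, rng):
    items = [f"L{i}" for i in range(n)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        items = [x for x in items if x not in (a, b)] + [f"({a},{b})"]
    return items[0] + ";"


class TestTerminalFraction:
    def test_all_leaf_events_give_one(self):
        t = read_newick("((A,B),(C,D));")
        assert terminal_branch_fraction(t, [frozenset({"A"}), frozenset({"C"})]) == 1.0

    def test_cherry_event_gives_zero(self):
        t = read_newick("((A,B),(C,D));")
        assert terminal_branch_fraction(t, [frozenset({"A", "B"})]) == 0.0

    def test_no_events_rejected(self):
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            terminal_branch_fraction(t, [])

    def test_uniform_random_placement_expectation(self):
        # placing gains on nodes uniformly at random, the expected terminal
        # fraction is (number of leaves) / (number of nodes)
        t = read_newick("(((A,B),(C,D)),(E,F));")
        nodes = [nd for nd in t.preorder_node_iter()]
        leaves = [nd for nd in nodes if nd.is_leaf()]
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(1000):
            nd = nodes[int(rng.integers(len(nodes)))]
            fracs.append(nd.is_leaf())
        expected = len(leaves) / len(nodes)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.05)


def _mini_catalog(rows):
    """rows: list of (strain_id, phenotype, [status codes]) where codes are
    'I' (intact), 'A'/'B'/'AB' (pseudo), 'P' (partial)."""
    out = []
    for sid, phen, codes in rows:
        pairs = []
        pos = 0
        for i, code in enumerate(codes, 1):
            pos += 100
            muts_a = [LofMutation(kind="premature_stop", codon_index=1,
                                  position_fraction=0.1)] if "A" in code else []
            muts_b = [LofMutation(kind="premature_stop", codon_index=1,
                                  position_fraction=0.1)] if "B" in code else []
            comp = "partial" if code == "P" else "full"
            ga = GeneRecord(gene_id=f"{sid}_p{i}_A", strain_id=sid, role=Role.A,
                            contig_id=f"{sid}_c", start=pos, end=pos + 6,
                            strand="+", sequence="ATGTAA", completeness=comp,
                            mutations=muts_a)
            gb = GeneRecord(gene_id=f"{sid}_p{i}_B", strain_id=sid, role=Role.B,
                            contig_id=f"{sid}_c", start=pos + 10, end=pos + 16,
                            strand="+", sequence="ATGTAA", completeness=comp,
                            mutations=muts_b)
            pos += 30
            pairs.append(GenePair(pair_id=f"{sid}_p{i}", strain_id=sid,
                                  gene_a=ga, gene_b=gb, syntenic=True))
        out.append(StrainRecord(strain_id=sid, phenotype=phen, pairs=pairs))
    return out


class TestPhenotypeAssociation:
    def _catalog_like_published_counts(self):
        rows = []
        # 14 CI strains with an intact pair, 1 non-CI with intact pair
        for i in range(14):
            rows.append((f"ci{i}", Phenotype.CI, ["I"]))
        rows.append(("mk0", Phenotype.MK, ["I"]))
        # 1 CI strain with no genes, 10 non-CI without genes
        rows.append(("ci14", Phenotype.CI, []))
        for i in range(10):
            rows.append((f"no{i}", Phenotype.none, []))
        # 2 CI strains and 3 non-CI strains with pseudogenes only
        for i in range(2):
            rows.append((f"cip{i}", Phenotype.CI, ["AB"]))
        for i in range(3):
            rows.append((f"nop{i}", Phenotype.P, ["B"]))
        # unknown-phenotype and partial-only strains must be discarded
        rows.append(("unk", Phenotype.unknown, ["I"]))
        rows.append(("part", Phenotype.CI, ["P"]))
        return _mini_catalog(rows)

    def test_published_contingency_table_reproduced(self):
        table, res = phenotype_association(self._catalog_like_published_counts())
        assert table.values.tolist() == [[14, 1], [1, 10], [2, 3]]
        assert res.p_value < 0.0001

    def test_collapse_matches_direct_fisher(self):
        _, res = phenotype_association(self._catalog_like_published_counts())
        assert res.p_value == fisher_exact_2x2([[14, 1], [3, 13]])

    def test_no_association_gives_p_one(self):
        rows = []
        for i in range(5):
            rows.append((f"a{i}", Phenotype.CI, ["I"]))
            rows.append((f"b{i}", Phenotype.none, ["I"]))
            rows.append((f"c{i}", Phenotype.CI, []))
            rows.append((f"d{i}", Phenotype.none, []))
        _, res = phenotype_association(_mini_catalog(rows))
        assert res.p_value == 1.0

    def test_all_unknown_rejected(self):
        with pytest.raises(ValueError):
            phenotype_association(_mini_catalog([("s", Phenotype.unknown, ["I"])]))


class TestRxCExact:
    def test_balanced_table_gives_p_one(self):
        assert rxc_exact([[5, 5], [5, 5], [0, 0]]) == 1.0

    def test_agrees_with_fisher_on_2x2(self):
        for table in [[[14, 1], [3, 13]], [[3, 7], [6, 2]]]:
            assert rxc_exact(table) == fisher_exact_2x2(table)


class TestDispersion:
    def test_poisson_counts_rarely_rejected(self):
        rng = np.random.default_rng(2)
        rej = 0
        reps = 500
        for _ in range(reps):
            z = dispersion_test(rng.poisson(1.7, 71)).statistic
            rej += abs(z) > 1.96
        assert rej / reps < 0.08

    def test_overdispersed_counts_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 100
        for _ in range(reps):
            lam = rng.gamma(2.0, 1.0, size=200)  # NB mixture: var = 2 * mean
            y = rng.poisson(lam)
            hits += dispersion_test(y).statistic > 1.96
        assert hits / reps >= 0.8

    def test_constant_counts_underdispersed(self):
        assert dispersion_test([3] * 20).statistic < 0

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValueError):
            dispersion_test([1, 2, 3])


class TestParalogDistance:
    def _catalog_and_dm(self, assignment, rng):
        """assignment: genome -> list of gene labels; D over all labels."""
        labels = [g for genes in assignment.values() for g in genes]
        pts = rng.normal(size=(len(labels), 3))
        M = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        D = DistanceMatrix(labels, M)
        rows = []
        for genome, genes in assignment.items():
            pairs = []
            for i, g in enumerate(genes, 1):
                ga = GeneRecord(gene_id=g, strain_id=genome, role=Role.A,
                                contig_id=f"{genome}_c", start=100 * i,
                                end=100 * i + 6, strand="+", sequence="ATGTAA")
                pairs.append(GenePair(pair_id=f"{genome}_p{i}", strain_id=genome,
                                      gene_a=ga, gene_b=None, syntenic=False))
            rows.append(StrainRecord(strain_id=genome, phenotype=Phenotype.CI,
                                     pairs=pairs))
        return rows, D

    def test_clustered_paralogs_detected(self):
        rng = np.random.default_rng(4)
        # genomes hold tight clusters: paralogs are mutual nearest neighbors
        n_genomes, per = 10, 2
        labels = {}
        pts = []
        names = []
        for g in range(n_genomes):
            center = rng.normal(scale=10, size=3)
            labels[f"G{g}"] = []
            for i in range(per):
                labels[f"G{g}"].append(f"G{g}_x{i}")
                names.append(f"G{g}_x{i}")
                pts.append(center + rng.normal(scale=0.01, size=3))
        M = np.linalg.norm(np.array(pts)[:, None] - np.array(pts)[None, :], axis=2)
        D = DistanceMatrix(names, M)
        catalog, _ = self._catalog_and_dm(labels, rng)
        res = paralog_distance_test(catalog, D, n_perm=999, seed=0)
        assert res.p_value <= 0.05
        assert res.statistic < np.mean(M)

    def test_random_assignment_p_uniform(self):
        rng = np.random.default_rng(5)
        rej = 0
        reps = 100
        for _ in range(reps):
            assignment = {f"G{g}": [f"G{g}_x{i}" for i in range(2)]
                          for g in range(6)}
            catalog, D = self._catalog_and_dm(assignment, rng)
            res = paralog_distance_test(catalog, D, n_perm=99,
                                        seed=int(rng.integers(2**31)))
            rej += res.p_value <= 0.05
        assert rej / reps < 0.12

    def test_single_genome_is_permutation_invariant(self):
        rng = np.random.default_rng(6)
        catalog, D = self._catalog_and_dm({"G0": [f"x{i}" for i in range(5)]}, rng)
        res = paralog_distance_test(catalog, D, n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_too_few_within_genome_pairs_rejected(self):
        rng = np.random.default_rng(7)
        catalog, D = self._catalog_and_dm({"G0": ["x0"], "G1": ["x1"]}, rng)
        with pytest.raises(ValueError):
            paralog_distance_test(catalog, D, n_perm=9, seed=0)


def test_event_count_matches_ground_truth_without_noise():
    # zero substitution noise, no transfer/deletion: every simulated lesion
    # is recovered and the minimum-gain count equals the logged event count
    from cifdyn.homolog_catalog import call_orf_disruptions
    from cifdyn.synthetic_evolution import SimulationConfig, simulate_dataset

    for seed in (0, 1):
        cfg = SimulationConfig(
            n_strains=10, seed=seed, subst_rate=0, indel_rate=0, hgt_rate=0,
            deletion_rate=0, recomb_rate=0, mu_b=0.4, mu_a=0.3,
        )
        catalog, tree, log = simulate_dataset(cfg)
        ref_a, ref_b = log._founder_seqs[0]
        presence = {}
        for strain in catalog:
            for pair in strain.pairs:
                for role, g, ref in (("A", pair.gene_a, ref_a),
                                     ("B", pair.gene_b, ref_b)):
                    for m in call_orf_disruptions(g.sequence, ref):
                        presence.setdefault(
                            (role, m.kind.value, m.codon_index), set()
                        ).add(strain.strain_id)
        n_true = len(log.of_kind("lof_a")) + len(log.of_kind("lof_b"))
        assert count_independent_lof_events(tree, presence) == n_true
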