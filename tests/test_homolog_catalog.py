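import numpy as np
import pytest
from Bio.Seq import Seq

from cifdyn.dataio import (
    CifType,
    GenePair,
    GeneRecord,
    Inheritance,
    LofMutation,
    MutationKind,
    Role,
)
from cifdyn.homolog_catalog import (
    HomologyHit,
    ScoringParams,
    assign_type,
    build_catalog_for_strain,
    call_orf_disruptions,
    classify_inheritance,
    extend_orf,
    pair_synteny,
    scan_genome,
)
from cifdyn.synthetic_evolution import SimulationConfig, simulate_dataset, _SENSE_CODONS

RNG = np.random.default_rng(42)


def _random_orf(ncod, rng=RNG, no_internal_atg=False):
    pool = [c for c in _SENSE_CODONS if not (no_internal_atg and c == "ATG")]
    body = "".join(pool[i] for i in rng.integers(0, len(pool), ncod - 2))
    return "ATG" + body + "TAA"


def _random_bases(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def _embed(orf, left=200, right=200, rng=RNG):
    return _random_bases(left, rng) + orf + _random_bases(right, rng)


class TestScan:
    def test_exact_copy_found_with_full_query_coverage(self):
        orf = _random_orf(120)
        contig = _embed(orf)
        query = str(Seq(orf[:-3]).translate())
        hits = scan_genome([("c1", contig)], [("q_A", query)])
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert h.fraction_of_smallest_query == pytest.approx(1.0, abs=0.02)
        assert h.start == pytest.approx(200, abs=3)

    def test_short_hit_without_partner_excluded(self):
        rng = np.random.default_rng(7)
        orf = _random_orf(120, rng)
        query = str(Seq(orf[:-3]).translate())
        # a bare 39%-coverage fragment, nothing to extend the alignment into
        contig = orf[: 3 * 46]
        hits = scan_genome([("c1", contig)], [("q_A", query)],
                           ScoringParams(min_score=40))
        assert hits == []

    def test_diverged_copy_recovered(self):
        # plant a copy with ~20% amino-acid divergence
        rng = np.random.default_rng(1)
        orf = _random_orf(150, rng)
        query = str(Seq(orf[:-3]).translate())
        codons = [orf[i:i + 3] for i in range(3, len(orf) - 3, 3)]
        n_mut = int(0.2 * len(codons))
        for idx in rng.choice(len(codons), size=n_mut, replace=False):
            codons[idx] = _SENSE_CODONS[rng.integers(0, 61)]
        diverged = "ATG" + "".join(codons) + "TAA"
        contig = _embed(diverged, rng=rng)
        hits = scan_genome([("c1", contig)], [("q_A", query)])
        assert len(hits) == 1
        assert hits[0].fraction_of_smallest_query > 0.9

    def test_reverse_strand_hit_mapped_back_to_contig_coords(self):
        rng = np.random.default_rng(2)
        orf = _random_orf(100, rng)
        query = str(Seq(orf[:-3]).translate())
        rc = str(Seq(orf).reverse_complement())
        contig = _random_bases(150, rng) + rc + _random_bases(150, rng)
        hits = scan_genome([("c1", contig)], [("q_A", query)])
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert 140 <= hits[0].start <= 160

    def test_synteny_rescues_short_partner(self):
        rng = np.random.default_rng(3)
        orf_a = _random_orf(150, rng)
        orf_b = _random_orf(250, rng)
        q_a = str(Seq(orf_a[:-3]).translate())
        q_b = str(Seq(orf_b[:-3]).translate())
        # plant full A and only 30% of B immediately downstream
        frag_b = orf_b[: 3 * 75]
        contig = _random_bases(100, rng) + orf_a + _random_bases(30, rng) + frag_b \
            + _random_bases(100, rng)
        params = ScoringParams(min_score=40)
        hits = scan_genome([("c1", contig)], [("q_A", q_a), ("q_B", q_b)], params)
        roles = sorted(h.role.value for h in hits)
        assert roles == ["A", "B"]

    def test_non_amino_acid_query_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            scan_genome([("c1", "ACGT" * 100)], [("q_A", "MKL123")])


class TestExtendOrf:
    def test_hit_already_bounded_unchanged(self):
        orf = _random_orf(100)
        contig = _embed(orf)
        hit = HomologyHit("c1", "q_A", 200, 200 + len(orf) - 3, "+", 200 % 3,
                          999.0, 1.0)
        g = extend_orf(hit, contig)
        assert (g.start, g.end) == (200, 200 + len(orf))
        assert g.completeness == "full"
        assert g.sequence == orf

    def test_internal_hit_extends_to_upstream_start(self):
        orf = _random_orf(100, no_internal_atg=True)
        contig = _embed(orf)
        hit = HomologyHit("c1", "q_A", 230, 260, "+", 230 % 3, 999.0, 0.1)
        g = extend_orf(hit, contig)
        assert g.start == 200
        assert g.sequence.startswith("ATG")
        assert g.sequence.endswith(("TAA", "TAG", "TGA"))

    def test_orf_running_off_contig_is_partial(self):
        # no stop before the contig end
        codons = "".join(_SENSE_CODONS[i] for i in RNG.integers(0, 61, 60))
        contig = _random_bases(99) + "ATG" + codons
        hit = HomologyHit("c1", "q_A", 99, 99 + 3 + 60, "+", 0, 999.0, 0.5)
        g = extend_orf(hit, contig)
        assert g.completeness == "partial"
        assert g.end == len(contig)


class TestPairSynteny:
    def _gene(self, gid, role, start, end, strand="+", contig="c1"):
        return GeneRecord(
            gene_id=gid, strain_id="s", role=role, contig_id=contig,
            start=start, end=end, strand=strand, sequence="N" * (end - start),
        )

    def test_adjacent_cooriented_genes_pair(self):
        a = self._gene("a", Role.A, 100, 1000)
        b = self._gene("b", Role.B, 1010, 4000)
        pairs = pair_synteny([a, b], max_gap=500)
        assert len(pairs) == 1 and pairs[0].syntenic

    def test_lone_b_gene_is_singleton(self):
        b = self._gene("b", Role.B, 1010, 4000)
        pairs = pair_synteny([b])
        assert len(pairs) == 1
        assert not pairs[0].syntenic and pairs[0].gene_a is None

    def test_opposite_strands_never_pair(self):
        a = self._gene("a", Role.A, 100, 1000, strand="+")
        b = self._gene("b", Role.B, 1010, 4000, strand="-")
        pairs = pair_synteny([a, b], max_gap=500)
        assert all(not p.syntenic for p in pairs)
        assert len(pairs) == 2

    def test_gap_beyond_max_gap_not_paired(self):
        a = self._gene("a", Role.A, 0, 100)
        b = self._gene("b", Role.B, 700, 900)
        assert all(not p.syntenic for p in pair_synteny([a, b], max_gap=500))

    def test_minus_strand_pairing_respects_orientation(self):
        # on '-', cifA upstream means A's span to the right of B's
        b = self._gene("b", Role.B, 100, 850, strand="-")
        a = self._gene("a", Role.A, 880, 1330, strand="-")
        pairs = pair_synteny([a, b], max_gap=500)
        assert len(pairs) == 1 and pairs[0].syntenic

    def test_every_gene_lands_in_exactly_one_pair(self, small_dataset):
        _, catalog, _, _ = small_dataset
        for strain in catalog:
            genes = strain.genes()
            if not genes:
                continue
            pairs = pair_synteny(genes, max_gap=500)
            placed = [g.gene_id for p in pairs
                      for g in (p.gene_a, p.gene_b) if g is not None]
            assert sorted(placed) == sorted(g.gene_id for g in genes)

    def test_simulator_pairing_reproduced(self, small_dataset):
        _, catalog, _, _ = small_dataset
        for strain in catalog:
            genes = strain.genes()
            if not genes:
                continue
            pairs = pair_synteny(genes, max_gap=500)
            got = sorted(
                (p.gene_a.gene_id, p.gene_b.gene_id) for p in pairs if p.syntenic
            )
            want = sorted(
                (p.gene_a.gene_id, p.gene_b.gene_id)
                for p in strain.pairs if p.syntenic
            )
            assert got == want


class TestOrfDisruptions:
    def test_identical_to_reference_is_clean(self):
        ref = _random_orf(300)
        assert call_orf_disruptions(ref, ref) == []

    def test_single_premature_stop_called_at_codon(self):
        ref = _random_orf(300)
        mutant = ref[:30] + "TAA" + ref[33:]
        muts = call_orf_disruptions(mutant, ref)
        assert len(muts) == 1
        m = muts[0]
        assert m.kind is MutationKind.premature_stop
        assert m.codon_index == 10
        assert m.position_fraction == pytest.approx(10 / 300)

    def test_single_nt_deletion_called_as_frameshift(self):
        ref = _random_orf(300)
        mutant = ref[:30] + ref[31:]
        muts = call_orf_disruptions(mutant, ref)
        assert any(
            m.kind is MutationKind.frameshift_indel and abs(m.codon_index - 10) <= 1
            for m in muts
        )

    def test_late_disruption_still_reported_with_high_position_fraction(self):
        ref = _random_orf(300)
        pos = 3 * 290
        mutant = ref[:pos] + "TAA" + ref[pos + 3:]
        muts = call_orf_disruptions(mutant, ref)
        assert len(muts) == 1
        assert muts[0].position_fraction > 0.9

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            call_orf_disruptions("", _random_orf(50))

    def test_recovers_simulated_lesions_and_stays_clean_on_intact(self):
        cfg = SimulationConfig(n_strains=10, seed=21, subst_rate=0.02,
                               indel_rate=0, hgt_rate=0.3, mu_b=0.6, mu_a=0.4,
                               deletion_rate=0)
        catalog, _, log = simulate_dataset(cfg)
        refs = {  # founder sequences by type
            t: seqs for t, seqs in zip("I II III IV V".split(), log._founder_seqs)
        }
        n_lesions = 0
        for strain in catalog:
            for pair in strain.pairs:
                ref_a, ref_b = refs[pair.cif_type.value]
                for g, ref in ((pair.gene_a, ref_a), (pair.gene_b, ref_b)):
                    called = call_orf_disruptions(g.sequence, ref)
                    if not g.is_pseudogene:
                        # simulator rejection rule: no spurious calls possible
                        assert called == []
                    else:
                        for true_mut in g.mutations:
                            n_lesions += 1
                            if true_mut.kind is MutationKind.premature_stop:
                                assert any(
                                    c.kind is MutationKind.premature_stop
                                    and c.codon_index == true_mut.codon_index
                                    for c in called
                                )
                            else:
                                assert any(
                                    c.kind is MutationKind.frameshift_indel
                                    and abs(c.codon_index - true_mut.codon_index) <= 1
                                    for c in called
                                )
        assert n_lesions > 0


class TestInheritance:
    def _aln(self):
        s = _random_orf(60)
        return [("g1", s), ("g2", s), ("g3", s)]

    def _mut(self, codon, kind=MutationKind.premature_stop):
        return LofMutation(kind=kind, codon_index=codon, position_fraction=codon / 60)

    def test_lone_mutation_is_unique(self):
        out = classify_inheritance([("g1", self._mut(50))], self._aln())
        assert out[0][1].inheritance is Inheritance.unique

    def test_shared_mutation_is_coinherited(self):
        table = [("g1", self._mut(50)), ("g2", self._mut(50))]
        out = classify_inheritance(table, self._aln())
        assert all(m.inheritance is Inheritance.coinherited for _, m in out)

    def test_same_codon_different_kinds_stay_unique(self):
        table = [
            ("g1", self._mut(50, MutationKind.premature_stop)),
            ("g2", self._mut(50, MutationKind.frameshift_indel)),
        ]
        out = classify_inheritance(table, self._aln())
        assert all(m.inheritance is Inheritance.unique for _, m in out)


class TestAssignType:
    def _refs(self):
        rng = np.random.default_rng(5)
        return {
            CifType(t): (_random_orf(100, rng), _random_orf(150, rng))
            for t in ["I", "II", "III", "IV"]
        }

    def _pair(self, seq_a, seq_b):
        ga = gb = None
        if seq_a is not None:
            ga = GeneRecord(gene_id="a", strain_id="s", role=Role.A, contig_id="c",
                            start=0, end=len(seq_a), strand="+", sequence=seq_a)
        if seq_b is not None:
            gb = GeneRecord(gene_id="b", strain_id="s", role=Role.B, contig_id="c",
                            start=1000, end=1000 + len(seq_b), strand="+",
                            sequence=seq_b)
        return GenePair(pair_id="p", strain_id="s", gene_a=ga, gene_b=gb,
                        syntenic=False)

    def test_identical_to_type_i_exemplar(self):
        refs = self._refs()
        a, b = refs[CifType.I]
        assert assign_type(self._pair(a, b), refs) is CifType.I

    def test_distant_pair_is_type_v(self):
        refs = self._refs()
        rng = np.random.default_rng(99)
        assert assign_type(
            self._pair(_random_orf(100, rng), _random_orf(150, rng)), refs
        ) is CifType.V

    def test_half_pair_assigned_from_single_gene(self):
        refs = self._refs()
        a, _ = refs[CifType.III]
        pair = self._pair(a, None)
        assert assign_type(pair, refs) is CifType.III

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            assign_type(self._pair("ATGTAA", None), {})
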