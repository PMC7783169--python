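"""Building the cif homolog catalog from contigs.

The scan re-creates a translated-homology search in-repo: each protein query
is locally aligned (affine gaps, BLOSUM62) against all six reading frames of
every contig.  Hits are kept when they score above a raw-score threshold and
cover at least 40% of the smallest query, except that sub-threshold-length
hits are rescued when they display the canonical cifA-cifB synteny with a
passing partner.  Hits are then extended to the nearest in-frame start and
stop codons, paired by synteny, screened for ORF-disrupting mutations
against an intact reference, and assigned to a phylogenetic type by
nearest-reference distance.

Query identifiers must end in ``_A`` or ``_B`` to declare their role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .dataio import (
    CifType,
    GenePair,
    GeneRecord,
    Inheritance,
    LofMutation,
    MutationKind,
    PairStatus,
    Role,
)

__all__ = [
    "HomologyHit",
    "ScoringParams",
    "scan_genome",
    "extend_orf",
    "pair_synteny",
    "call_orf_disruptions",
    "classify_inheritance",
    "assign_type",
    "build_catalog_for_strain",
]

_STOPS = {"TAA", "TAG", "TGA"}
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ScoringParams:
    """Raw-score threshold calibrated on shuffled-sequence nulls (no
    E-values); the 40%-of-smallest-query length rule and synteny rescue are
    the decisive acceptance criteria."""

    min_score: float = 60.0
    min_fraction: float = 0.4
    max_gap: int = 500
    gap_open: float = -11.0
    gap_extend: float = -1.0
    max_hits_per_frame: int = 32


@dataclass
class HomologyHit:
    contig_id: str
    query_id: str
    start: int  # contig coords, 0-based half-open, forward strand
    end: int
    strand: str
    frame: int  # 0,1,2 within the strand
    score: float
    fraction_of_smallest_query: float

    @property
    def role(self) -> Role:
        if self.query_id.endswith("_A"):
            return Role.A
        if self.query_id.endswith("_B"):
            return Role.B
        raise ValueError(f"query id {self.query_id!r} does not end in _A/_B")


def _aligner(params: ScoringParams, mode: str = "local") -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    al.mode = mode
    return al


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _frame_translation(sense: str, frame: int) -> str:
    sub = sense[frame : frame + 3 * ((len(sense) - frame) // 3)]
    return str(Seq(sub).translate()).replace("*", "X")


def scan_genome(
    contigs: Sequence[tuple[str, str]],
    protein_queries: Sequence[tuple[str, str]],
    scoring_params: ScoringParams | None = None,
) -> list[HomologyHit]:
    """Six-frame translated local-alignment scan of contigs for cif homologs.

    Multiple non-overlapping hits per frame are found by iterative masking of
    the best local alignment.  Returns hits passing the score threshold and
    either the 40%-of-smallest-query length rule or the synteny rescue.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    if not protein_queries:
        raise ValueError("no queries supplied")
    params = scoring_params or ScoringParams()
    for qid, q in protein_queries:
        bad = set(q.upper()) - _AA - {"X"}
        if bad:
            raise ValueError(f"query {qid} contains non-amino-acid symbols {sorted(bad)}")
    min_q = min(len(q) for _, q in protein_queries)
    al = _aligner(params)

    raw: list[HomologyHit] = []
    for contig_id, contig in contigs:
        contig = contig.upper()
        L = len(contig)
        for strand in "+-":
            sense = contig if strand == "+" else _revcomp(contig)
            for frame in range(3):
                prot = _frame_translation(sense, frame)
                if not prot:
                    continue
                work = prot
                for _ in range(params.max_hits_per_frame):
                    best = None
                    for qid, q in protein_queries:
                        alns = al.align(work, q.upper())
                        if len(alns) == 0:
                            continue
                        a = alns[0]
                        if best is None or a.score > best[1].score:
                            best = (qid, a, q)
                    if best is None or best[1].score < params.min_score:
                        break
                    qid, a, q = best
                    tstart = int(a.aligned[0][0][0])
                    tend = int(a.aligned[0][-1][1])
                    qspan = int(a.aligned[1][-1][1]) - int(a.aligned[1][0][0])
                    # sense-strand nt coords
                    s_nt = frame + 3 * tstart
                    e_nt = frame + 3 * tend
                    if strand == "+":
                        start, end = s_nt, e_nt
                    else:
                        start, end = L - e_nt, L - s_nt
                    raw.append(
                        HomologyHit(
                            contig_id=contig_id, query_id=qid, start=start, end=end,
                            strand=strand, frame=frame, score=float(a.score),
                            fraction_of_smallest_query=qspan / min_q,
                        )
                    )
                    work = work[:tstart] + "X" * (tend - tstart) + work[tend:]

    # collapse to the highest-scoring frame when spans overlap on one strand
    raw.sort(key=lambda h: -h.score)
    kept: list[HomologyHit] = []
    for h in raw:
        if any(
            k.contig_id == h.contig_id and k.strand == h.strand
            and min(k.end, h.end) - max(k.start, h.start) > 0.5 * (h.end - h.start)
            for k in kept
        ):
            continue
        kept.append(h)

    passing = [h for h in kept if h.fraction_of_smallest_query >= params.min_fraction]
    rescued = []
    for h in kept:
        if h in passing:
            continue
        for p in passing:
            if p.contig_id != h.contig_id or p.strand != h.strand:
                continue
            if p.role == h.role:
                continue
            a, b = (h, p) if h.role is Role.A else (p, h)
            gap = (b.start - a.end) if a.strand == "+" else (a.start - b.end)
            if 0 <= gap <= params.max_gap:
                rescued.append(h)
                break
    out = passing + rescued
    out.sort(key=lambda h: (h.contig_id, h.start))
    return out


def extend_orf(
    hit: HomologyHit,
    contig: str,
    strain_id: str = "",
    alt_starts: bool = False,
) -> GeneRecord:
    """Extend a hit 5' to the nearest in-frame start codon and 3' to the
    nearest in-frame stop; completeness becomes ``partial`` when either
    extension runs off the contig."""
    contig = contig.upper()
    L = len(contig)
    sense = contig if hit.strand == "+" else _revcomp(contig)
    if hit.strand == "+":
        s, e = hit.start, hit.end
    else:
        s, e = L - hit.end, L - hit.start
    starts = {"ATG"} | ({"GTG", "TTG"} if alt_starts else set())
    partial = False

    # 5' walk: nearest in-frame start, aborting at an in-frame stop
    best_start = None
    pos = s
    while pos >= 0:
        codon = sense[pos : pos + 3]
        if codon in starts:
            best_start = pos
            break
        if codon in _STOPS and pos < s:
            break
        pos -= 3
    if best_start is None:
        if pos < 0:
            partial = True
            best_start = s % 3  # truncated at contig edge, keep frame
        else:
            best_start = s

    # 3' walk: nearest in-frame stop, inclusive
    best_end = None
    pos = max(best_start, best_start + 3 * ((e - best_start) // 3) - 3)
    while pos + 3 <= len(sense):
        if sense[pos : pos + 3] in _STOPS:
            best_end = pos + 3
            break
        pos += 3
    if best_end is None:
        partial = True
        best_end = best_start + 3 * ((len(sense) - best_start) // 3)

    seq = sense[best_start:best_end]
    if hit.strand == "+":
        start, end = best_start, best_end
    else:
        start, end = L - best_end, L - best_start
    return GeneRecord(
        gene_id=f"{strain_id or hit.contig_id}:{start}-{end}{hit.strand}_{hit.role.value}",
        strain_id=strain_id,
        role=hit.role,
        contig_id=hit.contig_id,
        start=start,
        end=end,
        strand=hit.strand,
        sequence=seq,
        completeness="partial" if partial else "full",
    )


def pair_synteny(genes: Sequence[GeneRecord], max_gap: int = 500) -> list[GenePair]:
    """Form cifA-cifB pairs: same contig, same strand, A's 3' end at most
    ``max_gap`` nt upstream of B's 5' end.  Unpaired genes become singleton
    pairs (syntenic=False).  Every gene lands in exactly one pair."""
    a_genes = sorted(
        (g for g in genes if g.role is Role.A), key=lambda g: (g.contig_id, g.start)
    )
    b_genes = sorted(
        (g for g in genes if g.role is Role.B), key=lambda g: (g.contig_id, g.start)
    )
    used_b: set[str] = set()
    pairs: list[GenePair] = []
    counter = 0
    strain = genes[0].strain_id if genes else ""

    def pid() -> str:
        nonlocal counter
        counter += 1
        return f"{strain or 'pair'}_p{counter}"

    for a in a_genes:
        mate = None
        best_gap = None
        for b in b_genes:
            if b.gene_id in used_b or b.contig_id != a.contig_id or b.strand != a.strand:
                continue
            gap = (b.start - a.end) if a.strand == "+" else (a.start - b.end)
            if 0 <= gap <= max_gap and (best_gap is None or gap < best_gap):
                mate, best_gap = b, gap
        if mate is not None:
            used_b.add(mate.gene_id)
            pairs.append(
                GenePair(pair_id=pid(), strain_id=a.strain_id, gene_a=a, gene_b=mate,
                         syntenic=True)
            )
        else:
            pairs.append(
                GenePair(pair_id=pid(), strain_id=a.strain_id, gene_a=a, gene_b=None,
                         syntenic=False)
            )
    for b in b_genes:
        if b.gene_id not in used_b:
            pairs.append(
                GenePair(pair_id=pid(), strain_id=b.strain_id, gene_a=None, gene_b=b,
                         syntenic=False)
            )
    return pairs


# ---------------------------------------------------------------------------
# ORF-disruption calling


def _nt_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.match_score = 5
    al.mismatch_score = -4
    al.open_gap_score = -10
    al.extend_gap_score = -0.5
    al.mode = "global"
    return al


def call_orf_disruptions(gene_seq: str, reference_nt: str) -> list[LofMutation]:
    """Codon-aware screen of a homolog against an intact reference.

    ``reference_nt`` is the nucleotide sequence of an intact homolog (its
    translation defines codon coordinates).  Reported lesions:

    * ``premature_stop`` — an in-frame (gene frame) stop codon aligned within
      the reference ORF, excluding the terminal stop;
    * ``frameshift_indel`` — an alignment gap run whose length is not a
      multiple of 3, reported at the first affected reference codon.

    Lesions in the final 10% of codons are still reported and carry
    position_fraction > 0.9 for downstream sensitivity analyses.
    """
    gene_seq = gene_seq.upper().replace("U", "T")
    reference_nt = reference_nt.upper().replace("U", "T")
    if not gene_seq:
        raise ValueError("empty gene sequence")
    ref_ncod = len(reference_nt) // 3
    aln = _nt_aligner().align(reference_nt, gene_seq)[0]
    a_ref, a_gene = str(aln[0]), str(aln[1])

    muts: list[LofMutation] = []
    ref_i = gene_i = 0
    col = 0
    ncols = len(a_ref)
    while col < ncols:
        if a_ref[col] == "-" or a_gene[col] == "-":
            run_start_ref = ref_i
            run_start_col = col
            gap_len = 0
            while col < ncols and (a_ref[col] == "-" or a_gene[col] == "-"):
                if a_ref[col] == "-":
                    gene_i += 1
                else:
                    ref_i += 1
                gap_len += 1
                col += 1
            # leading/trailing gaps are terminal truncation, not lesions
            if run_start_col == 0 or col >= ncols:
                continue
            if gap_len % 3 != 0:
                codon = min(run_start_ref // 3, ref_ncod - 1)
                muts.append(
                    LofMutation(
                        kind=MutationKind.frameshift_indel,
                        codon_index=codon,
                        position_fraction=codon / ref_ncod,
                    )
                )
            continue
        # match column: check gene-frame stop codons at reference codon starts
        if ref_i % 3 == 0 and gene_i % 3 == 0 and col + 3 <= ncols:
            g3 = a_gene[col : col + 3]
            r3 = a_ref[col : col + 3]
            if "-" not in g3 and "-" not in r3:
                codon = ref_i // 3
                if g3 in _STOPS and codon < ref_ncod - 1:
                    muts.append(
                        LofMutation(
                            kind=MutationKind.premature_stop,
                            codon_index=codon,
                            position_fraction=codon / ref_ncod,
                        )
                    )
        ref_i += 1
        gene_i += 1
        col += 1
    # deduplicate (kind, codon)
    seen: set[tuple[str, int]] = set()
    out = []
    for m in muts:
        key = (m.kind.value, m.codon_index)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def classify_inheritance(
    mutation_table: Sequence[tuple[str, LofMutation]],
    gene_alignment: Sequence[tuple[str, str]],
) -> list[tuple[str, LofMutation]]:
    """Set the inheritance class of each lesion.

    Lesions of the same kind at the same aligned codon in more than one
    homolog are ``coinherited`` (shared through speciation or duplication);
    all others are ``unique``.  The decision is positional: the alignment
    column of the lesion's codon is the grouping key.
    """
    aligned = dict(gene_alignment)
    keys: dict[tuple[str, LofMutation] | int, tuple[int, str]] = {}
    groups: dict[tuple[int, str], list[int]] = {}
    entries = list(mutation_table)
    for idx, (gene_id, mut) in enumerate(entries):
        if gene_id not in aligned:
            raise ValueError(f"gene {gene_id} missing from alignment")
        seq = aligned[gene_id]
        # column of the codon's first nucleotide in this gene's row
        target = 3 * mut.codon_index
        count = -1
        colpos = None
        for col, ch in enumerate(seq):
            if ch != "-":
                count += 1
                if count == target:
                    colpos = col
                    break
        if colpos is None:
            colpos = len(seq)
        key = (colpos, mut.kind.value)
        groups.setdefault(key, []).append(idx)
        keys[idx] = key
    out: list[tuple[str, LofMutation]] = []
    for idx, (gene_id, mut) in enumerate(entries):
        inh = (
            Inheritance.coinherited
            if len(groups[keys[idx]]) > 1
            else Inheritance.unique
        )
        out.append(
            (
                gene_id,
                LofMutation(
                    kind=mut.kind,
                    codon_index=mut.codon_index,
                    position_fraction=mut.position_fraction,
                    inheritance=inh,
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Type assignment


def _edit_distance_fn(s1: str, s2: str) -> float:
    if not s1 or not s2:
        return 1.0
    d = edlib.align(s1, s2, task="distance")["editDistance"]
    return d / max(len(s1), len(s2))


def assign_type(
    pair: GenePair,
    reference_pairs: dict[CifType, tuple[str, str]],
    distance_fn: Callable[[str, str], float] | None = None,
    cutoff: float = 0.35,
) -> CifType:
    """Assign a pair to Types I-IV by nearest reference distance on the
    concatenated sequences; beyond ``cutoff`` from every reference the pair
    is the divergent assemblage (Type V); with no sequence at all it stays
    unassigned.  The cutoff is a divergence threshold standing in for clade
    membership and is configurable."""
    if not reference_pairs:
        raise ValueError("empty reference set")
    dist = distance_fn or _edit_distance_fn
    a = pair.gene_a.sequence if pair.gene_a is not None else None
    b = pair.gene_b.sequence if pair.gene_b is not None else None
    if a is None and b is None:
        return CifType.unassigned
    best_type, best_d = None, None
    for ctype, (ref_a, ref_b) in reference_pairs.items():
        if a is not None and b is not None:
            d = dist(a + b, ref_a + ref_b)
        elif a is not None:
            d = dist(a, ref_a)
        else:
            d = dist(b, ref_b)
        if best_d is None or d < best_d:
            best_type, best_d = CifType(ctype), d
    if best_d is not None and best_d <= cutoff:
        return best_type
    return CifType.V


def _merge_fragments(
    genes: list[GeneRecord], contig_map: dict[str, str], merge_gap: int = 60
) -> list[GeneRecord]:
    """Collapse same-role ORF fragments split by internal stop codons.

    A pseudogene whose ORF is interrupted yields several abutting hits after
    extension; fragments of the same role on the same contig and strand
    separated by at most ``merge_gap`` nt are reannotated as one gene
    spanning from the first start to the last stop."""
    genes = sorted(genes, key=lambda g: (g.contig_id, g.strand, g.role.value, g.start))
    out: list[GeneRecord] = []
    for g in genes:
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.role is g.role
            and prev.contig_id == g.contig_id
            and prev.strand == g.strand
            and g.start - prev.end <= merge_gap
        ):
            contig = contig_map[g.contig_id].upper()
            start, end = prev.start, max(prev.end, g.end)
            seq = contig[start:end]
            if g.strand == "-":
                seq = _revcomp(seq)
            merged = GeneRecord(
                gene_id=f"{prev.strain_id or g.contig_id}:{start}-{end}{g.strand}_{g.role.value}",
                strain_id=prev.strain_id,
                role=g.role,
                contig_id=g.contig_id,
                start=start,
                end=end,
                strand=g.strand,
                sequence=seq,
                completeness=(
                    "full"
                    if prev.completeness == "full" and g.completeness == "full"
                    else "partial"
                ),
            )
            out[-1] = merged
        else:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Convenience: full per-strain catalog construction


def build_catalog_for_strain(
    strain_id: str,
    contigs: Sequence[tuple[str, str]],
    protein_queries: Sequence[tuple[str, str]],
    reference_nt: dict[Role, str] | None = None,
    reference_pairs: dict[CifType, tuple[str, str]] | None = None,
    scoring_params: ScoringParams | None = None,
) -> list[GenePair]:
    """Scan -> extend -> pair -> disruption-call -> type-assign for one strain."""
    params = scoring_params or ScoringParams()
    hits = scan_genome(contigs, protein_queries, params)
    contig_map = {cid: seq for cid, seq in contigs}
    genes: list[GeneRecord] = []
    # strongest hit first; overlapping same-role ORFs collapse to one gene
    for h in sorted(hits, key=lambda h: -h.score):
        g = extend_orf(h, contig_map[h.contig_id], strain_id=strain_id)
        dup = any(
            k.role is g.role and k.contig_id == g.contig_id and k.strand == g.strand
            and min(k.end, g.end) - max(k.start, g.start)
            > 0.5 * min(k.end - k.start, g.end - g.start)
            for k in genes
        )
        if dup:
            continue
        genes.append(g)
    genes = _merge_fragments(genes, contig_map)
    if reference_nt is not None:
        for g in genes:
            if g.completeness == "full":
                g.mutations = call_orf_disruptions(g.sequence, reference_nt[g.role])
    pairs = pair_synteny(genes, max_gap=params.max_gap)
    if reference_pairs is not None:
        for p in pairs:
            p.cif_type = assign_type(p, reference_pairs)
    return pairs
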