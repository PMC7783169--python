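"""Alignment and tree building for cif homolog sets.

Covers translation-guided (codon-aware) alignment, conserved-block column
filtering, pairwise distance estimation (p, Jukes-Cantor, Kimura 2-parameter),
neighbor-joining with bootstrap bipartition support, midpoint rooting and
patristic distances.  Trees are :class:`dendropy.Tree` objects; distance
matrices are :class:`DistanceMatrix`.

Distance-based NJ stands in for full maximum-likelihood tree search: the
downstream statistics (Mantel, ParaFit, parental-distance nulls) consume
distances and topologies, for which NJ on corrected distances is adequate and
fully deterministic.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .dataio import read_fasta, write_fasta, write_newick

__all__ = [
    "DistanceMatrix",
    "codon_aware_align",
    "filter_conserved_blocks",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "midpoint_root",
    "patristic_distances",
    "bipartitions",
    "SATURATION_CEILING",
]

SATURATION_CEILING = 3.0  # substitutions/site assigned to saturated pairs


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over ordered labels."""

    labels: list[str]
    values: np.ndarray
    saturated: np.ndarray | None = None  # boolean mask of ceiling-clamped pairs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Codon-aware alignment

_STOPS = {"TAA", "TAG", "TGA"}


def _translate_masked(nt: str) -> str:
    """Translate, masking internal stop codons (recorded lesions) as X."""
    if len(nt) % 3:
        raise ValueError(
            f"sequence length {len(nt)} not divisible by 3; remove recorded "
            "frameshifts before aligning"
        )
    aa = []
    ncod = len(nt) // 3
    for i in range(ncod):
        codon = nt[3 * i : 3 * i + 3].upper()
        if codon in _STOPS:
            # terminal stop dropped, internal stop masked
            if i == ncod - 1:
                break
            aa.append("X")
        elif set(codon) <= set("ACGT"):
            aa.append(str(Seq(codon).translate()))
        else:
            aa.append("X")
    return "".join(aa)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    mat = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = _extend_matrix_for_x(mat)
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _extend_matrix_for_x(mat):
    # BLOSUM62 ships with X; just return as-is (kept as a hook for other matrices)
    return mat


def _pairwise_protein_align(p1: str, p2: str) -> tuple[str, str, float]:
    aligner = _protein_aligner()
    aln = aligner.align(p1, p2)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b, float(aln.score)


def _mafft_align(named_proteins: list[tuple[str, str]]) -> list[tuple[str, str]]:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.faa"
        write_fasta(fin, named_proteins)
        res = subprocess.run(
            ["mafft", "--quiet", "--auto", "--amino", "--anysymbol", str(fin)],
            capture_output=True,
            text=True,
            check=True,
        )
        out: list[tuple[str, str]] = []
        name, chunks = None, []
        for line in res.stdout.splitlines():
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.strip())
        if name is not None:
            out.append((name, "".join(chunks)))
    return out


def _backthread(nt: str, aligned_aa: str) -> str:
    """Thread nucleotide codons through an aligned amino-acid string."""
    out = []
    pos = 0
    for ch in aligned_aa:
        if ch == "-":
            out.append("---")
        else:
            out.append(nt[pos : pos + 3])
            pos += 3
    return "".join(out)


def codon_aware_align(
    nt_sequences: Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Align nucleotide ORFs via their amino-acid translations.

    Input sequences must have length divisible by 3 (frameshifts removed
    beforehand); internal stop codons are masked as X for the protein
    alignment.  The amino-acid alignment (exact affine-gap DP for two
    sequences, MAFFT for three or more) is back-threaded onto the
    nucleotides, so every gap is a codon-boundary multiple of 3.
    """
    if len(nt_sequences) < 2:
        raise ValueError("need at least 2 sequences")
    names = [n for n, _ in nt_sequences]
    nts = []
    for name, s in nt_sequences:
        s = s.upper().replace("U", "T")
        if len(s) % 3:
            raise ValueError(f"{name}: length {len(s)} not divisible by 3")
        # drop a terminal stop codon so it never aligns against sense codons
        if s[-3:] in _STOPS:
            s = s[:-3]
        nts.append(s)
    prots = [_translate_masked(s + "TAA") for s in nts]  # TAA restores terminal handling
    for name, p in zip(names, prots):
        if not p:
            raise ValueError(f"{name}: untranslatable sequence after masking")
    if len(nts) == 2:
        a, b, _ = _pairwise_protein_align(prots[0], prots[1])
        aligned_aa = [(names[0], a), (names[1], b)]
    else:
        aligned_aa = _mafft_align(list(zip(names, prots)))
        order = {n: i for i, n in enumerate(names)}
        aligned_aa.sort(key=lambda t: order[t[0]])
    return [
        (name, _backthread(nt, aa))
        for (name, aa), nt in zip(aligned_aa, nts)
    ]


def protein_alignment_score(p1: str, p2: str) -> float:
    """Score of the global affine-gap amino-acid alignment (BLOSUM62, -11/-1)."""
    return _pairwise_protein_align(p1, p2)[2]


# ---------------------------------------------------------------------------
# Conserved-block filtering


def filter_conserved_blocks(
    alignment: Sequence[tuple[str, str]],
    min_column_occupancy: float = 0.5,
    min_block_len: int = 30,
) -> tuple[list[tuple[str, str]], list[int]]:
    """Drop weakly conserved alignment regions.

    Columns whose non-gap fraction falls below ``min_column_occupancy`` are
    removed; surviving runs of consecutive kept columns shorter than
    ``min_block_len`` are also removed.  Returns the filtered alignment and
    the provenance map (original column index of each kept column).

    Raises ``ValueError`` when every column is filtered out.
    """
    if not alignment:
        raise ValueError("empty alignment")
    mat = np.array([list(s) for _, s in alignment])
    n, ncol = mat.shape
    occupancy = (mat != "-").sum(axis=0) / n
    keep = occupancy >= min_column_occupancy
    # remove short surviving runs
    cols = np.flatnonzero(keep)
    kept_final: list[int] = []
    run: list[int] = []
    for c in cols:
        if run and c != run[-1] + 1:
            if len(run) >= min_block_len:
                kept_final.extend(run)
            run = []
        run.append(c)
    if len(run) >= min_block_len:
        kept_final.extend(run)
    if not kept_final:
        raise ValueError("conserved-block filter removed every column")
    sub = mat[:, kept_final]
    out = [(name, "".join(row)) for (name, _), row in zip(alignment, sub)]
    return out, kept_final


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(
    alignment: Sequence[tuple[str, str]], model: str = "K2P"
) -> DistanceMatrix:
    """Pairwise distances from an alignment under p, JC or K2P corrections.

    Sites with a gap or ambiguity in either sequence of a pair are excluded
    pairwise.  Saturated pairs (log argument <= 0) are clamped to
    ``SATURATION_CEILING`` and flagged in ``.saturated``.
    """
    if len(alignment) < 2:
        raise ValueError("need >= 2 aligned sequences")
    if model not in {"p", "JC", "K2P"}:
        raise ValueError(f"unknown model {model!r}")
    labels = [n for n, _ in alignment]
    mat = np.array([list(s.upper()) for _, s in alignment])
    n = len(labels)
    D = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    valid = np.isin(mat, list("ACGT"))
    purine = np.isin(mat, list("AG"))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            L = int(ok.sum())
            if L == 0:
                d, is_sat = SATURATION_CEILING, True
            else:
                diff = (mat[i] != mat[j]) & ok
                p = diff.sum() / L
                if model == "p":
                    d, is_sat = p, False
                elif model == "JC":
                    arg = 1 - 4 * p / 3
                    if arg <= 0:
                        d, is_sat = SATURATION_CEILING, True
                    else:
                        d, is_sat = -0.75 * np.log(arg), False
                else:  # K2P
                    ts = (diff & (purine[i] == purine[j])).sum() / L  # transitions
                    tv = p - ts
                    a1 = 1 - 2 * ts - tv
                    a2 = 1 - 2 * tv
                    if a1 <= 0 or a2 <= 0:
                        d, is_sat = SATURATION_CEILING, True
                    else:
                        d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
                        is_sat = False
            D[i, j] = D[j, i] = min(d, SATURATION_CEILING)
            sat[i, j] = sat[j, i] = is_sat
    return DistanceMatrix(labels, D, saturated=sat)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic tie-break on the
    lexicographically smallest (i, j) index pair of the Q minimum."""
    n = len(D.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if not np.allclose(D.values, D.values.T, atol=1e-12):
        raise ValueError("non-symmetric distance matrix")
    active = list(range(n))
    dist = D.values.copy()
    newick = {i: D.labels[i] for i in range(n)}
    next_id = n
    dmap = {i: i for i in range(n)}  # node id -> row in dist

    # grow dist matrix dynamically via dict-of-dict to keep indexing simple
    dd: dict[int, dict[int, float]] = {
        i: {j: float(dist[i, j]) for j in range(n) if j != i} for i in range(n)
    }

    while len(active) > 2:
        m = len(active)
        r = {i: sum(dd[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dd[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = dd[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        dd[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dd[i][k] + dd[j][k] - dij)
            dd[u][k] = duk
            dd[k][u] = duk
        newick[u] = f"({newick[i]}:{li:.12g},{newick[j]}:{lj:.12g})"
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    s = f"({newick[i]}:{dd[i][j]:.12g},{newick[j]}:0);"
    tree = dendropy.Tree.get(
        data=s, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Unrooted bipartitions (both sides as label frozensets), trivial splits
    excluded."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset({side, other}))
    return out


def bootstrap_support(
    alignment: Sequence[tuple[str, str]],
    n_reps: int = 100,
    seed: int = 0,
    model: str = "K2P",
) -> dendropy.Tree:
    """NJ point tree with bipartition support (%) from column-resampled
    replicates; ``n_reps=0`` returns the point tree with no supports."""
    point = nj_tree(distance_matrix(alignment, model=model))
    if n_reps == 0:
        return point
    names = [n for n, _ in alignment]
    mat = np.array([list(s) for _, s in alignment])
    ncol = mat.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[frozenset[str]], int] = {bp: 0 for bp in bipartitions(point)}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_aln = [(nm, "".join(row)) for nm, row in zip(names, mat[:, cols])]
        try:
            rep = nj_tree(distance_matrix(rep_aln, model=model))
        except ValueError:
            continue
        rep_bps = bipartitions(rep)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = frozenset(names)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        bp = frozenset({side, all_leaves - side})
        if bp in counts:
            node.label = f"{100.0 * counts[bp] / n_reps:g}"
    return point


# ---------------------------------------------------------------------------
# Rooting and patristic distances


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path (dendropy)."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("midpoint rooting requires all branch lengths")
    t = tree.clone(depth=1)
    if t.is_rooted:  # deroot first so re-rooting an already-rooted tree works
        t.deroot()
    t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the leaf-to-leaf path, for all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            if d is None:
                raise ValueError("missing branch lengths")
            M[i, j] = M[j, i] = d
    return DistanceMatrix(labels, M)
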