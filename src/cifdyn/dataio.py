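"""Data model and on-disk formats for cif gene-pair catalogs.

A *catalog* is the set of :class:`StrainRecord` objects describing, for each
symbiont strain, the cifA-cifB homolog pairs found in its genome, the
loss-of-function lesions carried by each gene, and the strain's reproductive
phenotype.  Catalogs round-trip through four TSV tables (genes, pairs,
strains, mutations) plus FASTA for sequences and newick for trees.

Coordinates are 0-based half-open throughout; gene sequences are stored on
the sense strand (already reverse-complemented when strand is '-').
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "Role",
    "MutationKind",
    "Inheritance",
    "CifType",
    "PairStatus",
    "Phenotype",
    "LofMutation",
    "GeneRecord",
    "GenePair",
    "StrainRecord",
    "CatalogError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_catalog",
    "write_catalog",
    "read_config",
    "write_config",
    "derive_status",
]


class Role(str, Enum):
    A = "A"
    B = "B"


class MutationKind(str, Enum):
    premature_stop = "premature_stop"
    frameshift_indel = "frameshift_indel"
    mobile_element_insertion = "mobile_element_insertion"
    inversion = "inversion"


class Inheritance(str, Enum):
    unique = "unique"
    coinherited = "coinherited"


class CifType(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    unassigned = "unassigned"


class PairStatus(str, Enum):
    both_intact = "both_intact"
    a_pseudo_only = "a_pseudo_only"
    b_pseudo_only = "b_pseudo_only"
    both_pseudo = "both_pseudo"
    incomplete = "incomplete"


class Phenotype(str, Enum):
    """Reproductive phenotype of a strain: CI, male killing, parthenogenesis,
    mutualism, no manipulation, or unknown/conflicting reports."""

    CI = "CI"
    MK = "MK"
    P = "P"
    M = "M"
    none = "none"
    unknown = "unknown"


class CatalogError(ValueError):
    """Referential-integrity or vocabulary violation in catalog tables."""


class FastaParseError(ValueError):
    pass


@dataclass
class LofMutation:
    """One ORF-disrupting lesion.

    ``codon_index`` is 0-based in reference codon units; ``position_fraction``
    is codon_index / reference codon count, used downstream to flag lesions in
    the final 10% of the ORF.
    """

    kind: MutationKind
    codon_index: int
    position_fraction: float
    inheritance: Inheritance = Inheritance.unique

    def __post_init__(self) -> None:
        self.kind = MutationKind(self.kind)
        self.inheritance = Inheritance(self.inheritance)
        if self.codon_index < 0:
            raise ValueError("codon_index must be >= 0")
        if not (0.0 <= self.position_fraction <= 1.0):
            raise ValueError("position_fraction must lie in [0, 1]")


@dataclass
class GeneRecord:
    gene_id: str
    strain_id: str
    role: Role
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    completeness: str = "full"  # full | partial
    mutations: list[LofMutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: span end must exceed start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.completeness not in {"full", "partial"}:
            raise ValueError(f"{self.gene_id}: bad completeness {self.completeness!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != span "
                f"length {self.end - self.start}"
            )

    @property
    def is_pseudogene(self) -> bool:
        return len(self.mutations) > 0


@dataclass
class GenePair:
    pair_id: str
    strain_id: str
    gene_a: GeneRecord | None
    gene_b: GeneRecord | None
    syntenic: bool
    cif_type: CifType = CifType.unassigned
    status: PairStatus | None = None

    def __post_init__(self) -> None:
        self.cif_type = CifType(self.cif_type)
        if self.syntenic:
            if self.gene_a is None or self.gene_b is None:
                raise ValueError(f"{self.pair_id}: syntenic pair needs both genes")
            a, b = self.gene_a, self.gene_b
            if a.contig_id != b.contig_id or a.strand != b.strand:
                raise ValueError(
                    f"{self.pair_id}: syntenic genes must share contig and strand"
                )
            upstream_ok = a.end <= b.start if a.strand == "+" else b.end <= a.start
            if not upstream_ok:
                raise ValueError(f"{self.pair_id}: cifA must lie upstream of cifB")
        if self.status is None:
            self.status = derive_status(self.gene_a, self.gene_b)
        else:
            self.status = PairStatus(self.status)


def derive_status(gene_a: GeneRecord | None, gene_b: GeneRecord | None) -> PairStatus:
    """Pair status from gene presence, completeness, and lesion lists.

    Pairs missing a gene or containing a partially sequenced gene are
    ``incomplete``: their pseudogenization state cannot be determined.
    """
    if gene_a is None or gene_b is None:
        return PairStatus.incomplete
    if gene_a.completeness != "full" or gene_b.completeness != "full":
        return PairStatus.incomplete
    a_pseudo = gene_a.is_pseudogene
    b_pseudo = gene_b.is_pseudogene
    if a_pseudo and b_pseudo:
        return PairStatus.both_pseudo
    if a_pseudo:
        return PairStatus.a_pseudo_only
    if b_pseudo:
        return PairStatus.b_pseudo_only
    return PairStatus.both_intact


@dataclass
class StrainRecord:
    strain_id: str
    supergroup: str = ""
    host_taxon: str = ""
    host_order: str = ""
    phenotype: Phenotype = Phenotype.unknown
    pairs: list[GenePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phenotype = Phenotype(self.phenotype)

    def genes(self) -> list[GeneRecord]:
        out: list[GeneRecord] = []
        for p in self.pairs:
            if p.gene_a is not None:
                out.append(p.gene_a)
            if p.gene_b is not None:
                out.append(p.gene_b)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of (id, sequence).

    Sequences are uppercased and U is mapped to T.  Malformed input (first
    non-blank byte not '>', empty file, header with no id) raises
    :class:`FastaParseError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"{path}: line {lineno} precedes any '>' header"
                    )
                chunks.append(line.strip().upper().replace("U", "T"))
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_string: str | os.PathLike) -> dendropy.Tree:
    """Read a single newick tree.

    Missing branch lengths stay ``None`` (never silently 0).  Duplicate leaf
    labels and unbalanced parentheses raise ``ValueError``.
    """
    s = str(path_or_string)
    if os.path.exists(s):
        with open(s) as fh:
            text = fh.read()
    else:
        text = s
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ValueError(f"newick parse failure: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels in newick input: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | os.PathLike | None = None) -> str:
    """Serialize a tree to newick with branch lengths at 6 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    ).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ---------------------------------------------------------------------------
# Catalog TSVs

GENES_HEADER = [
    "gene_id", "strain_id", "role", "contig_id", "start", "end", "strand",
    "completeness", "sequence",
]
PAIRS_HEADER = [
    "pair_id", "strain_id", "gene_a_id", "gene_b_id", "syntenic", "cif_type", "status",
]
STRAINS_HEADER = ["strain_id", "supergroup", "host_taxon", "host_order", "phenotype"]
MUTATIONS_HEADER = ["gene_id", "kind", "codon_index", "position_fraction", "inheritance"]


def _read_tsv(path: str | os.PathLike, header: Sequence[str]) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise CatalogError(f"{path}: empty table")
    got = lines[0].split("\t")
    if got != list(header):
        raise CatalogError(f"{path}: bad header {got!r}, expected {list(header)!r}")
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise CatalogError(f"{path}: row has {len(fields)} fields, expected {len(header)}")
        rows.append(dict(zip(header, fields)))
    return rows


def read_catalog(
    genes_path: str | os.PathLike,
    pairs_path: str | os.PathLike,
    strains_path: str | os.PathLike,
    mutations_path: str | os.PathLike | None = None,
) -> list[StrainRecord]:
    """Load a catalog from its TSV tables, checking cross-references.

    A pairs row citing an unknown gene_id, or a phenotype outside the fixed
    vocabulary, raises :class:`CatalogError`.
    """
    gene_rows = _read_tsv(genes_path, GENES_HEADER)
    pair_rows = _read_tsv(pairs_path, PAIRS_HEADER)
    strain_rows = _read_tsv(strains_path, STRAINS_HEADER)

    mutations: dict[str, list[LofMutation]] = {}
    if mutations_path is not None and os.path.exists(mutations_path):
        for row in _read_tsv(mutations_path, MUTATIONS_HEADER):
            mutations.setdefault(row["gene_id"], []).append(
                LofMutation(
                    kind=MutationKind(row["kind"]),
                    codon_index=int(row["codon_index"]),
                    position_fraction=float(row["position_fraction"]),
                    inheritance=Inheritance(row["inheritance"]),
                )
            )

    genes: dict[str, GeneRecord] = {}
    for row in gene_rows:
        g = GeneRecord(
            gene_id=row["gene_id"],
            strain_id=row["strain_id"],
            role=Role(row["role"]),
            contig_id=row["contig_id"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            completeness=row["completeness"],
            sequence=row["sequence"],
            mutations=mutations.get(row["gene_id"], []),
        )
        if g.gene_id in genes:
            raise CatalogError(f"duplicate gene_id {g.gene_id}")
        genes[g.gene_id] = g
    for gid in mutations:
        if gid not in genes:
            raise CatalogError(f"mutations table cites unknown gene_id {gid}")

    pairs_by_strain: dict[str, list[GenePair]] = {}
    for row in pair_rows:
        ga = gb = None
        if row["gene_a_id"] not in {"", "."}:
            if row["gene_a_id"] not in genes:
                raise CatalogError(f"pairs table cites unknown gene_id {row['gene_a_id']}")
            ga = genes[row["gene_a_id"]]
        if row["gene_b_id"] not in {"", "."}:
            if row["gene_b_id"] not in genes:
                raise CatalogError(f"pairs table cites unknown gene_id {row['gene_b_id']}")
            gb = genes[row["gene_b_id"]]
        pair = GenePair(
            pair_id=row["pair_id"],
            strain_id=row["strain_id"],
            gene_a=ga,
            gene_b=gb,
            syntenic=row["syntenic"].lower() == "true",
            cif_type=CifType(row["cif_type"]),
            status=PairStatus(row["status"]),
        )
        pairs_by_strain.setdefault(pair.strain_id, []).append(pair)

    catalog: list[StrainRecord] = []
    seen: set[str] = set()
    for row in strain_rows:
        sid = row["strain_id"]
        if sid in seen:
            raise CatalogError(f"duplicate strain_id {sid}")
        seen.add(sid)
        try:
            phen = Phenotype(row["phenotype"])
        except ValueError:
            raise CatalogError(
                f"phenotype {row['phenotype']!r} outside vocabulary "
                f"{[p.value for p in Phenotype]}"
            ) from None
        catalog.append(
            StrainRecord(
                strain_id=sid,
                supergroup=row["supergroup"],
                host_taxon=row["host_taxon"],
                host_order=row["host_order"],
                phenotype=phen,
                pairs=pairs_by_strain.get(sid, []),
            )
        )
    placed = {p.strain_id for ps in pairs_by_strain.values() for p in ps}
    missing = placed - seen
    if missing:
        raise CatalogError(f"pairs table cites unknown strain_id(s) {sorted(missing)}")
    return catalog


def write_catalog(catalog: Sequence[StrainRecord], out_dir: str | os.PathLike) -> dict[str, str]:
    """Write genes/pairs/strains/mutations TSVs; returns {table: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": str(out / "genes.tsv"),
        "pairs": str(out / "pairs.tsv"),
        "strains": str(out / "strains.tsv"),
        "mutations": str(out / "mutations.tsv"),
    }
    with open(paths["genes"], "w") as fg, open(paths["pairs"], "w") as fp, open(
        paths["strains"], "w"
    ) as fs, open(paths["mutations"], "w") as fm:
        fg.write("\t".join(GENES_HEADER) + "\n")
        fp.write("\t".join(PAIRS_HEADER) + "\n")
        fs.write("\t".join(STRAINS_HEADER) + "\n")
        fm.write("\t".join(MUTATIONS_HEADER) + "\n")
        for strain in catalog:
            fs.write(
                "\t".join(
                    [
                        strain.strain_id,
                        strain.supergroup,
                        strain.host_taxon,
                        strain.host_order,
                        strain.phenotype.value,
                    ]
                )
                + "\n"
            )
            for pair in strain.pairs:
                fp.write(
                    "\t".join(
                        [
                            pair.pair_id,
                            pair.strain_id,
                            pair.gene_a.gene_id if pair.gene_a else ".",
                            pair.gene_b.gene_id if pair.gene_b else ".",
                            str(pair.syntenic),
                            pair.cif_type.value,
                            pair.status.value,
                        ]
                    )
                    + "\n"
                )
                for g in (pair.gene_a, pair.gene_b):
                    if g is None:
                        continue
                    fg.write(
                        "\t".join(
                            [
                                g.gene_id,
                                g.strain_id,
                                g.role.value,
                                g.contig_id,
                                str(g.start),
                                str(g.end),
                                g.strand,
                                g.completeness,
                                g.sequence,
                            ]
                        )
                        + "\n"
                    )
                    for m in g.mutations:
                        fm.write(
                            "\t".join(
                                [
                                    g.gene_id,
                                    m.kind.value,
                                    str(m.codon_index),
                                    repr(m.position_fraction),
                                    m.inheritance.value,
                                ]
                            )
                            + "\n"
                        )
    return paths


# ---------------------------------------------------------------------------
# Flat key-value config


def read_config(path: str | os.PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno} is not 'key = value'")
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out


def write_config(path: str | os.PathLike, values: dict[str, object]) -> None:
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k} = {v}\n")
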