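"""Simulator of cifA-cifB gene-pair evolution on a strain phylogeny.

The generative model encodes the evolutionary dynamics the analysis stages
are built to detect:

* strains diversify under a Yule (pure-birth) process;
* gene pairs are gained by horizontal transfer from a contemporaneous
  lineage carrying an intact pair (or from a divergent founder pool of five
  reference pairs, emulating the five phylogenetic types, when no donor
  exists);
* pairs are lost by deletion;
* ORF-disrupting (loss-of-function) mutations hit cifB at rate ``mu_b`` and
  cifA at rate ``mu_a``.  Under ``gating="strict"`` cifA cannot be hit while
  its partner cifB is intact — the sperm-modification gene, being selectively
  neutral in random mating, degenerates first, and only then is the rescue
  gene released from selection.  ``gating="independent"`` removes the
  ordering constraint (the host-suppression alternative);
* recombination between pairs is proposed at ``recomb_rate`` and accepted
  with probability exp(-d/theta) where d is the current nucleotide
  divergence between the two pairs — divergence-restricted recombination;
* nucleotide sequences evolve under a two-parameter (Kimura-style)
  substitution model; substitutions creating an in-frame internal stop are
  rejected on intact genes and accepted on pseudogenes, which additionally
  accrue small indels.

All randomness flows from ``SimulationConfig.seed`` through one root
generator; the strain tree, event history and sequence layer use distinct
fixed streams so that, e.g., rerunning the sequence layer never perturbs the
history.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence
from zlib import crc32

import dendropy
import numpy as np

from .dataio import (
    CifType,
    GenePair,
    GeneRecord,
    Inheritance,
    LofMutation,
    MutationKind,
    Phenotype,
    Role,
    StrainRecord,
    derive_status,
    write_catalog,
    write_fasta,
    write_newick,
)

__all__ = [
    "SimulationConfig",
    "EventRecord",
    "EventLog",
    "simulate_strain_tree",
    "simulate_cif_history",
    "evolve_sequences",
    "emit_dataset",
    "simulate_dataset",
]

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_KAPPA = 2.0  # transition/transversion rate bias of the substitution model
_FOUNDER_TYPES = [CifType.I, CifType.II, CifType.III, CifType.IV, CifType.V]
_HOST_ORDERS = ["Diptera", "Hymenoptera", "Lepidoptera", "Hemiptera", "Coleoptera"]


@dataclass
class SimulationConfig:
    """Rates are per unit time of the strain tree; defaults are illustrative
    (no rate estimates exist for gain/loss) but chosen so a ~30-strain tree
    of height ~3 carries a realistic mixture of 0-7 pairs per strain with
    intact, singly- and doubly-pseudogenized pairs."""

    n_strains: int = 30
    birth_rate: float = 1.0
    hgt_rate: float = 0.3
    deletion_rate: float = 0.1
    mu_b: float = 0.25
    mu_a: float = 0.15
    gating: str = "strict"  # strict | independent
    subst_rate: float = 0.05
    indel_rate: float = 0.002
    recomb_rate: float = 0.05
    recomb_scale: float = 0.05
    len_a: int = 150  # codons, including start and terminal stop
    len_b: int = 250
    n_root_pairs: int = 1
    founder_divergence: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.len_a < 10 or self.len_b < 10:
            raise ValueError("gene lengths must be >= 10 codons")
        if self.gating not in {"strict", "independent"}:
            raise ValueError("gating must be 'strict' or 'independent'")
        for name in (
            "birth_rate", "hgt_rate", "deletion_rate", "mu_b", "mu_a",
            "subst_rate", "indel_rate", "recomb_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EventRecord:
    time: float
    branch: str  # label of the tree node terminating the branch
    kind: str  # hgt_gain | deletion | lof_a | lof_b | recombination
    pair_uid: str
    detail: dict = field(default_factory=dict)


class EventLog:
    """Ordered ground-truth event record.

    Internal simulation state (pair registries used by the sequence layer)
    rides along on private attributes; the TSV serialization carries only the
    public records.
    """

    def __init__(self) -> None:
        self.records: list[EventRecord] = []
        self._pairs: dict[str, "_Pair"] = {}
        self._tip_pairs: dict[tuple[str, str], "_Pair"] = {}
        self._founder_seqs: list[tuple[str, str]] | None = None
        self._tip_time: float = 0.0

    def append(self, rec: EventRecord) -> None:
        self.records.append(rec)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.kind] = out.get(r.kind, 0) + 1
        return out

    def of_kind(self, kind: str) -> list[EventRecord]:
        return [r for r in self.records if r.kind == kind]

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("time\tbranch\tkind\tpair_uid\tdetail\n")
            for r in self.records:
                fh.write(
                    f"{r.time!r}\t{r.branch}\t{r.kind}\t{r.pair_uid}\t"
                    f"{json.dumps(r.detail, sort_keys=True)}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "EventLog":
        log = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["time", "branch", "kind", "pair_uid", "detail"]:
                raise ValueError(f"{path}: bad event-log header")
            for ln in fh:
                t, branch, kind, uid, detail = ln.rstrip("\n").split("\t", 4)
                log.append(EventRecord(float(t), branch, kind, uid, json.loads(detail)))
        return log


# ---------------------------------------------------------------------------
# Strain tree


def simulate_strain_tree(
    n_strains: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Ultrametric Yule tree with ``n_strains`` leaves.

    The k-lineage epoch lasts Exp(k * birth_rate), including a final epoch
    with all n lineages, so the expected root-to-tip height is
    sum_{k=2..n} 1/(k*birth_rate).
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    rng = np.random.default_rng([seed, 101])
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    width = max(2, len(str(n_strains)))
    if n_strains == 1:
        tree.seed_node.taxon = taxa.new_taxon(label="s" + "1".zfill(width))
        tree.seed_node.time = 0.0
        return tree

    # open lineages: (node, birth_time)
    root = tree.seed_node
    root.time = 0.0
    open_tips: list[dendropy.Node] = []
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    open_tips.extend([c1, c2])
    t = 0.0
    k = 2
    while k < n_strains:
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(0, len(open_tips)))
        parent = open_tips.pop(idx)
        parent.time = t
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        open_tips.extend([a, b])
        k += 1
    t += rng.exponential(1.0 / (n_strains * birth_rate))
    # leaf labels in a stable left-to-right order
    for node in tree.preorder_node_iter():
        if node in open_tips:
            node.time = t
    counter = 0
    for node in tree.leaf_node_iter():
        counter += 1
        node.taxon = taxa.new_taxon(label="s" + str(counter).zfill(width))
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.time - node.parent_node.time
    _label_internal(tree)
    return tree


def _label_internal(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if node.label is None:
            node.label = f"n{i}"


def _node_times(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    times: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            times[node] = 0.0
        else:
            if node.edge.length is None:
                raise ValueError("tree has missing branch lengths")
            times[node] = times[node.parent_node] + node.edge.length
    return times


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"id{id(node)}"


# ---------------------------------------------------------------------------
# Pair state


class _Anc:
    """Genealogy node used for the analytic divergence proxy."""

    __slots__ = ("parent", "time")

    def __init__(self, parent: Optional["_Anc"], time: float) -> None:
        self.parent = parent
        self.time = time


class _Pair:
    def __init__(self, uid: str, founder: int, birth_time: float,
                 anc_parent: Optional[_Anc]) -> None:
        self.uid = uid
        self.founder = founder
        self.birth_time = birth_time
        self.a_intact = True
        self.b_intact = True
        self.a_lesions: list[dict] = []
        self.b_lesions: list[dict] = []
        self.strand = "+"
        self.anc = _Anc(anc_parent, birth_time)
        # chronological per-pair event list used by the sequence layer:
        # (time, kind, detail); kind in {birth_founder, birth_copy, lof_a,
        # lof_b, recombination}
        self.events: list[tuple[float, str, dict]] = []
        self.parent: Optional[_Pair] = None
        # sequence-layer state
        self.a_seq: str | None = None
        self.b_seq: str | None = None
        self.last_t: float = birth_time

    def copy_at(self, uid: str, t: float) -> "_Pair":
        child = _Pair(uid, self.founder, t, self.anc)
        child.a_intact = self.a_intact
        child.b_intact = self.b_intact
        child.a_lesions = copy.deepcopy(self.a_lesions)
        child.b_lesions = copy.deepcopy(self.b_lesions)
        child.strand = self.strand
        child.parent = self
        child.events.append((t, "birth_copy", {"parent_uid": self.uid}))
        return child

    @property
    def both_intact(self) -> bool:
        return self.a_intact and self.b_intact


def _divergence(p: _Pair, q: _Pair, t: float, cfg: SimulationConfig) -> float:
    """Analytic nucleotide-divergence proxy between two pairs at time t:
    2 * subst_rate * (t - t_mrca) for pairs sharing a founder, else the fixed
    founder divergence.  Homogenization by past recombination is ignored."""
    if p.founder != q.founder:
        return cfg.founder_divergence
    seen: dict[int, float] = {}
    a: Optional[_Anc] = p.anc
    while a is not None:
        seen[id(a)] = a.time
        a = a.parent
    a = q.anc
    while a is not None:
        if id(a) in seen:
            return 2.0 * cfg.subst_rate * max(0.0, t - a.time)
        a = a.parent
    return cfg.founder_divergence


# ---------------------------------------------------------------------------
# History simulation


def simulate_cif_history(
    tree: dendropy.Tree, config: SimulationConfig
) -> tuple[list[StrainRecord], EventLog]:
    """Simulate gain, deletion, loss-of-function and recombination events on
    a strain tree with branch lengths.

    Events are drawn by exponential waiting times in a tree-wide Gillespie
    walk so horizontal-transfer donors are chosen among lineages alive at the
    event time.  Returns the tip catalog (gene sequences are placeholders
    until :func:`evolve_sequences` runs) and the ground-truth event log.
    """
    if tree.seed_node is None or len(tree.leaf_nodes()) == 0:
        raise ValueError("empty tree")
    rng = np.random.default_rng([config.seed, 202])
    log = EventLog()
    times = _node_times(tree)
    tips = tree.leaf_nodes()
    _label_internal(tree)

    uid_counter = [0]

    def new_uid() -> str:
        uid_counter[0] += 1
        return f"P{uid_counter[0]:05d}"

    def register(p: _Pair) -> _Pair:
        log._pairs[p.uid] = p
        return p

    def new_founder_pair(founder: int, t: float) -> _Pair:
        p = register(_Pair(new_uid(), founder, t, anc_parent=None))
        p.strand = "+" if rng.random() < 0.8 else "-"
        p.events.append((t, "birth_founder", {"founder": founder}))
        return p

    # root state
    root = tree.seed_node
    root_state: list[_Pair] = [
        new_founder_pair(i % 5, 0.0) for i in range(config.n_root_pairs)
    ]

    if len(tips) == 1 and root.is_leaf():
        # degenerate single-strain tree: no branches to evolve along
        catalog = [_tip_record(root, root_state, config, rng)]
        log._tip_pairs.update(
            {(catalog[0].strain_id, gp.pair_id): p
             for gp, p in zip(catalog[0].pairs, root_state)}
        )
        log._tip_time = 0.0
        return catalog, log

    state: dict[dendropy.Node, list[_Pair]] = {}
    for child in root.child_nodes():
        state[child] = [p.copy_at(new_uid(), 0.0) for p in root_state]
        for c in state[child]:
            register(c)

    rtimes = {n: round(t, 12) for n, t in times.items()}
    boundaries = sorted({t for n, t in rtimes.items() if n is not root})
    tip_time = max(boundaries)
    prev = 0.0
    for t_hi in boundaries:
        live = [n for n in state if rtimes[n] >= t_hi]
        t = prev
        while live:
            # per-lineage, per-pair rates
            lin_rates = []
            for n in live:
                r = config.hgt_rate
                for p in state[n]:
                    r += config.deletion_rate + config.recomb_rate
                    if p.b_intact:
                        r += config.mu_b
                    if p.a_intact and (
                        config.gating == "independent" or not p.b_intact
                    ):
                        r += config.mu_a
                lin_rates.append(r)
            total = float(sum(lin_rates))
            if total <= 0.0:
                break
            t_next = t + rng.exponential(1.0 / total)
            if t_next >= t_hi:
                break
            t = t_next
            n = live[int(rng.choice(len(live), p=np.asarray(lin_rates) / total))]
            _fire_event(n, t, state, live, config, rng, log, new_uid, register)
        prev = t_hi
        # terminate branches ending at t_hi; leaves keep their final state
        for n in [n for n in list(state) if rtimes[n] == t_hi]:
            if n.is_leaf():
                continue
            pairs = state.pop(n)
            for child in n.child_nodes():
                state[child] = [p.copy_at(new_uid(), t_hi) for p in pairs]
                for c in state[child]:
                    register(c)

    catalog: list[StrainRecord] = []
    for tip in tips:
        pairs = state.get(tip, [])
        rec = _tip_record(tip, pairs, config, rng)
        catalog.append(rec)
        for gp, p in zip(rec.pairs, pairs):
            log._tip_pairs[(rec.strain_id, gp.pair_id)] = p
    log._tip_time = tip_time
    log.records.sort(key=lambda r: (r.time, r.pair_uid))
    return catalog, log


def _fire_event(node, t, state, live, config, rng, log, new_uid, register) -> None:
    pairs = state[node]
    # build the within-lineage event menu
    menu: list[tuple[str, Optional[_Pair], float]] = [("hgt_gain", None, config.hgt_rate)]
    for p in pairs:
        menu.append(("deletion", p, config.deletion_rate))
        menu.append(("recombination", p, config.recomb_rate))
        if p.b_intact:
            menu.append(("lof_b", p, config.mu_b))
        if p.a_intact and (config.gating == "independent" or not p.b_intact):
            menu.append(("lof_a", p, config.mu_a))
    weights = np.array([w for _, _, w in menu], dtype=float)
    kind, pair, _ = menu[int(rng.choice(len(menu), p=weights / weights.sum()))]
    branch = _node_name(node)

    if kind == "hgt_gain":
        donors = [
            q for n2 in live for q in state[n2]
            if q.both_intact and n2 is not node
        ]
        if donors:
            donor = donors[int(rng.integers(0, len(donors)))]
            child = register(donor.copy_at(new_uid(), t))
            child.events[-1] = (t, "birth_copy", {"parent_uid": donor.uid, "hgt": True})
            pairs.append(child)
            log.append(EventRecord(t, branch, "hgt_gain", child.uid,
                                   {"donor_uid": donor.uid, "founder": donor.founder}))
        else:
            founder = int(rng.integers(0, 5))
            child = _Pair(new_uid(), founder, t, anc_parent=None)
            child.strand = "+" if rng.random() < 0.8 else "-"
            child.events.append((t, "birth_founder", {"founder": founder}))
            register(child)
            pairs.append(child)
            log.append(EventRecord(t, branch, "hgt_gain", child.uid,
                                   {"donor_uid": None, "founder": founder}))
    elif kind == "deletion":
        pairs.remove(pair)
        log.append(EventRecord(t, branch, "deletion", pair.uid, {}))
    elif kind in ("lof_a", "lof_b"):
        ncod = config.len_a if kind == "lof_a" else config.len_b
        lesion_kind = (
            MutationKind.premature_stop
            if rng.random() < 0.5
            else MutationKind.frameshift_indel
        )
        codon = int(rng.integers(1, ncod - 1))
        detail = {"kind": lesion_kind.value, "codon": codon}
        if lesion_kind is MutationKind.frameshift_indel:
            detail["indel_len"] = int(rng.integers(1, 3))
            detail["indel_ins"] = bool(rng.random() < 0.5)
            detail["indel_fill"] = "".join(
                rng.choice(list("ACGT"), size=detail["indel_len"])
            )
        if kind == "lof_a":
            pair.a_intact = False
            pair.a_lesions.append(detail)
        else:
            pair.b_intact = False
            pair.b_lesions.append(detail)
        pair.events.append((t, kind, detail))
        log.append(EventRecord(t, branch, kind, pair.uid, dict(detail)))
    else:  # recombination proposal
        others = [q for n2 in live for q in state[n2] if q is not pair and q.both_intact]
        if not others:
            return
        donor = others[int(rng.integers(0, len(others)))]
        d = _divergence(pair, donor, t, config)
        accept_p = np.exp(-d / config.recomb_scale) if config.recomb_scale > 0 else float(d == 0)
        if rng.random() >= accept_p:
            return
        frac = float(rng.uniform(0.1, 0.9))
        within = donor.founder == pair.founder
        detail = {
            "donor_uid": donor.uid,
            "donor_founder": donor.founder,
            "breakpoint_frac": frac,
            "within_type": within,
            "parent_divergence": d,
        }
        pair.events.append((t, "recombination", detail))
        log.append(EventRecord(t, _node_name(node), "recombination", pair.uid, dict(detail)))


def _tip_record(
    tip: dendropy.Node, pairs: list[_Pair], config: SimulationConfig, rng
) -> StrainRecord:
    strain = _node_name(tip)
    gene_pairs: list[GenePair] = []
    pos = 0
    contig = f"{strain}_ctg1"
    for i, p in enumerate(pairs, start=1):
        pid = f"{strain}_p{i}"
        la, lb = 3 * config.len_a, 3 * config.len_b
        pos += 100  # spacer
        if p.strand == "+":
            a_span = (pos, pos + la)
            b_span = (pos + la + 30, pos + la + 30 + lb)
        else:
            b_span = (pos, pos + lb)
            a_span = (pos + lb + 30, pos + lb + 30 + la)
        pos += la + lb + 30
        ga = GeneRecord(
            gene_id=f"{pid}_A", strain_id=strain, role=Role.A, contig_id=contig,
            start=a_span[0], end=a_span[1], strand=p.strand, sequence="N" * la,
            mutations=[_lesion_to_mutation(d, config.len_a) for d in p.a_lesions],
        )
        gb = GeneRecord(
            gene_id=f"{pid}_B", strain_id=strain, role=Role.B, contig_id=contig,
            start=b_span[0], end=b_span[1], strand=p.strand, sequence="N" * lb,
            mutations=[_lesion_to_mutation(d, config.len_b) for d in p.b_lesions],
        )
        gene_pairs.append(
            GenePair(
                pair_id=pid, strain_id=strain, gene_a=ga, gene_b=gb,
                syntenic=True, cif_type=_FOUNDER_TYPES[p.founder % 5],
            )
        )
    phenotype = (
        Phenotype.CI
        if any(gp.status.value == "both_intact" for gp in gene_pairs)
        else Phenotype.none
    )
    return StrainRecord(
        strain_id=strain,
        supergroup="A" if rng.random() < 0.5 else "B",
        host_taxon=f"host_{strain}",
        host_order=_HOST_ORDERS[int(rng.integers(0, len(_HOST_ORDERS)))],
        phenotype=phenotype,
        pairs=gene_pairs,
    )


def _lesion_to_mutation(detail: dict, ncod: int) -> LofMutation:
    return LofMutation(
        kind=MutationKind(detail["kind"]),
        codon_index=int(detail["codon"]),
        position_fraction=detail["codon"] / ncod,
        inheritance=Inheritance.unique,
    )


# ---------------------------------------------------------------------------
# Sequence layer


def _founder_sequences(config: SimulationConfig) -> list[tuple[str, str]]:
    """Five divergent founder (cifA_nt, cifB_nt) pairs, deterministic in the
    seed; independent random sense codons give ~0.75 pairwise divergence."""
    rng = np.random.default_rng([config.seed, 303])
    out = []
    for _ in range(5):
        a = "ATG" + "".join(
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), config.len_a - 2)
        ) + "TAA"
        b = "ATG" + "".join(
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), config.len_b - 2)
        ) + "TAA"
        out.append((a, b))
    return out


def _substitute(seq: str, pos: int, rng) -> str:
    base = seq[pos]
    if rng.random() < _KAPPA / (_KAPPA + 2.0):
        new = _TRANSITION[base]
    else:
        tvs = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
        new = tvs[int(rng.integers(0, 2))]
    return seq[:pos] + new + seq[pos + 1 :]


def _advance_gene(seq: str, dt: float, intact: bool, cfg: SimulationConfig, rng) -> str:
    """Evolve one gene for time dt: Poisson substitutions (stop-creating ones
    rejected on intact genes) plus, for pseudogenes, Poisson 1-2 nt indels."""
    if dt <= 0:
        return seq
    L = len(seq)
    nsub = rng.poisson(cfg.subst_rate * L * dt) if cfg.subst_rate > 0 else 0
    for _ in range(nsub):
        pos = int(rng.integers(0, len(seq)))
        new = _substitute(seq, pos, rng)
        if intact:
            cstart = 3 * (pos // 3)
            codon = new[cstart : cstart + 3]
            if codon in _STOPS and cstart < len(new) - 3:
                continue  # rejected: would create an internal stop in-frame
            if cstart == 0:
                continue  # keep the start codon of intact genes
            if cstart == len(new) - 3 and codon not in _STOPS:
                continue  # keep the terminal stop of intact genes
        seq = new
    if not intact and cfg.indel_rate > 0:
        nind = rng.poisson(cfg.indel_rate * L * dt)
        for _ in range(nind):
            ilen = int(rng.integers(1, 3))
            if rng.random() < 0.5 and len(seq) > ilen + 6:
                pos = int(rng.integers(3, len(seq) - ilen - 3))
                seq = seq[:pos] + seq[pos + ilen :]
            else:
                pos = int(rng.integers(3, len(seq) - 3))
                fill = "".join(rng.choice(list("ACGT"), size=ilen))
                seq = seq[:pos] + fill + seq[pos:]
    return seq


def _apply_lesion(seq: str, detail: dict) -> str:
    codon = detail["codon"]
    cstart = min(3 * codon, max(0, len(seq) - 6))
    if detail["kind"] == MutationKind.premature_stop.value:
        return seq[:cstart] + "TAA" + seq[cstart + 3 :]
    ilen = detail.get("indel_len", 1)
    if detail.get("indel_ins", False):
        return seq[:cstart] + detail.get("indel_fill", "A" * ilen) + seq[cstart:]
    return seq[:cstart] + seq[cstart + ilen :]


def evolve_sequences(
    catalog: list[StrainRecord],
    log: EventLog,
    tree: dendropy.Tree,
    config: SimulationConfig,
) -> list[StrainRecord]:
    """Fill in nucleotide sequences by replaying the simulated history.

    Requires the in-process event log produced by
    :func:`simulate_cif_history` (the pair registry is not serialized).
    Lesions recorded in the history materialize as concrete premature stops
    or 1-2 nt indels; intact genes never acquire an in-frame internal stop.
    """
    if any(s.pairs for s in catalog) and not log._pairs:
        raise ValueError(
            "event log lacks the in-process pair registry; run "
            "simulate_cif_history and evolve_sequences in the same session"
        )
    rng = np.random.default_rng([config.seed, 404])
    founders = _founder_sequences(config)
    log._founder_seqs = founders

    def advance(p: _Pair, t: float) -> None:
        dt = t - p.last_t
        if dt <= 0:
            return
        p.a_seq = _advance_gene(p.a_seq, dt, p.a_intact_now, config, rng)
        p.b_seq = _advance_gene(p.b_seq, dt, p.b_intact_now, config, rng)
        p.last_t = t

    # chronological replay over every pair's private event list
    queue: list[tuple[float, str, _Pair, str, dict]] = []
    for p in log._pairs.values():
        for t, kind, detail in p.events:
            queue.append((t, p.uid, p, kind, detail))
        p.a_intact_now = True
        p.b_intact_now = True
    queue.sort(key=lambda q: (q[0], q[1]))

    for t, _, p, kind, detail in queue:
        if kind == "birth_founder":
            p.a_seq, p.b_seq = founders[detail["founder"]]
            p.last_t = t
        elif kind == "birth_copy":
            parent = log._pairs[detail["parent_uid"]]
            advance(parent, t)
            p.a_seq, p.b_seq = parent.a_seq, parent.b_seq
            p.a_intact_now = parent.a_intact_now
            p.b_intact_now = parent.b_intact_now
            p.last_t = t
        elif kind in ("lof_a", "lof_b"):
            advance(p, t)
            if kind == "lof_a":
                p.a_seq = _apply_lesion(p.a_seq, detail)
                p.a_intact_now = False
            else:
                p.b_seq = _apply_lesion(p.b_seq, detail)
                p.b_intact_now = False
        elif kind == "recombination":
            donor = log._pairs[detail["donor_uid"]]
            advance(donor, t)
            advance(p, t)
            # codon-boundary breakpoint so chimeric stop codons cannot form
            cat_d = donor.a_seq + donor.b_seq
            cat_r = p.a_seq + p.b_seq
            ncod = min(len(cat_d), len(cat_r)) // 3
            pos = 3 * int(detail["breakpoint_frac"] * ncod)
            new = cat_d[:pos] + cat_r[pos:]
            la = len(p.a_seq)
            p.a_seq, p.b_seq = new[:la], new[la:]

    tip_time = log._tip_time
    times = _node_times(tree)
    tip_times = {
        _node_name(n): times[n] for n in tree.leaf_node_iter()
    }
    out: list[StrainRecord] = []
    for strain in catalog:
        new_pairs: list[GenePair] = []
        pos = 0
        contig = f"{strain.strain_id}_ctg1"
        for gp in strain.pairs:
            p = log._tip_pairs[(strain.strain_id, gp.pair_id)]
            advance(p, tip_times.get(strain.strain_id, tip_time))
            la, lb = len(p.a_seq), len(p.b_seq)
            pos += 100
            if p.strand == "+":
                a_span, b_span = (pos, pos + la), (pos + la + 30, pos + la + 30 + lb)
            else:
                b_span, a_span = (pos, pos + lb), (pos + lb + 30, pos + lb + 30 + la)
            pos += la + lb + 30
            ga = GeneRecord(
                gene_id=gp.gene_a.gene_id, strain_id=strain.strain_id, role=Role.A,
                contig_id=contig, start=a_span[0], end=a_span[1], strand=p.strand,
                sequence=p.a_seq, mutations=gp.gene_a.mutations,
            )
            gb = GeneRecord(
                gene_id=gp.gene_b.gene_id, strain_id=strain.strain_id, role=Role.B,
                contig_id=contig, start=b_span[0], end=b_span[1], strand=p.strand,
                sequence=p.b_seq, mutations=gp.gene_b.mutations,
            )
            new_pairs.append(
                GenePair(
                    pair_id=gp.pair_id, strain_id=strain.strain_id,
                    gene_a=ga, gene_b=gb, syntenic=True, cif_type=gp.cif_type,
                )
            )
        out.append(
            StrainRecord(
                strain_id=strain.strain_id, supergroup=strain.supergroup,
                host_taxon=strain.host_taxon, host_order=strain.host_order,
                phenotype=strain.phenotype, pairs=new_pairs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Dataset emission


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def emit_dataset(
    catalog: list[StrainRecord],
    tree: dendropy.Tree,
    log: EventLog,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write the full dataset: catalog TSVs, per-role FASTA, contig FASTA,
    strain tree newick, event-log TSV and, when available, founder reference
    sequences.  ``read_catalog`` on the output reproduces the input."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_catalog(catalog, out)
    paths["tree"] = str(out / "strain_tree.nwk")
    write_newick(tree, paths["tree"])
    a_recs, b_recs = [], []
    contigs: list[tuple[str, str]] = []
    for strain in catalog:
        layout: list[tuple[int, int, str]] = []
        contig_id = None
        for gp in strain.pairs:
            for g in (gp.gene_a, gp.gene_b):
                if g is None:
                    continue
                contig_id = g.contig_id
                seq = g.sequence if g.strand == "+" else _revcomp(g.sequence)
                layout.append((g.start, g.end, seq))
                (a_recs if g.role is Role.A else b_recs).append((g.gene_id, g.sequence))
        if contig_id is not None:
            layout.sort()
            srng = np.random.default_rng(crc32(contig_id.encode()))
            total = layout[-1][1] + 100
            bases = srng.choice(list("ACGT"), size=total)
            arr = list("".join(bases))
            for s, e, seq in layout:
                arr[s:e] = list(seq)
            contigs.append((contig_id, "".join(arr)))
    paths["cifA_fasta"] = str(out / "cifA.fasta")
    paths["cifB_fasta"] = str(out / "cifB.fasta")
    paths["contigs"] = str(out / "contigs.fasta")
    if a_recs:
        write_fasta(paths["cifA_fasta"], a_recs)
    else:
        Path(paths["cifA_fasta"]).write_text("")
    if b_recs:
        write_fasta(paths["cifB_fasta"], b_recs)
    else:
        Path(paths["cifB_fasta"]).write_text("")
    if contigs:
        write_fasta(paths["contigs"], contigs)
    else:
        Path(paths["contigs"]).write_text("")
    paths["events"] = str(out / "events.tsv")
    log.write_tsv(paths["events"])
    if log._founder_seqs:
        refs = []
        for i, (a, b) in enumerate(log._founder_seqs):
            refs.append((f"ref_type{_FOUNDER_TYPES[i].value}_A", a))
            refs.append((f"ref_type{_FOUNDER_TYPES[i].value}_B", b))
        paths["references"] = str(out / "references_nt.fasta")
        write_fasta(paths["references"], refs)
    return paths


def simulate_dataset(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> tuple[list[StrainRecord], dendropy.Tree, EventLog]:
    """One-call simulation: tree, history, sequences and (optionally) files."""
    tree = simulate_strain_tree(config.n_strains, config.birth_rate, config.seed)
    catalog, log = simulate_cif_history(tree, config)
    catalog = evolve_sequences(catalog, log, tree, config)
    if out_dir is not None:
        emit_dataset(catalog, tree, log, out_dir)
    return catalog, tree, log
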