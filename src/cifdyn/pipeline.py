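"""End-to-end pipeline: simulate -> scan -> phylo -> congruence -> recomb ->
lossdyn, with deterministic per-stage seeding, a hashed output manifest and a
summary report juxtaposing estimates against simulator ground truth."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from . import congruence as cg
from . import homolog_catalog as hc
from . import loss_dynamics as ld
from . import phylo as ph
from . import recombination as rc
from . import synthetic_evolution as se
from .dataio import PairStatus, Role, StrainRecord, read_fasta, write_newick

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "stage_seed"]

_STAGES = ["simulate", "scan", "phylo", "congruence", "recomb", "lossdyn"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed: hashing (seed, stage) means toggling
    one stage never shifts another stage's randomness."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "cifdyn_run"
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    phylo: dict = field(default_factory=lambda: {"model": "K2P", "bootstrap": 0})
    congruence: dict = field(default_factory=lambda: {"n_perm": 999})
    recomb: dict = field(default_factory=lambda: {"alpha": 0.05, "min_window": 10,
                                                  "n_perm": 200})
    lossdyn: dict = field(default_factory=lambda: {"n_perm": 999})

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _trim_codon(seq: str) -> str:
    return seq[: 3 * (len(seq) // 3)]


def _concat_pair_alignment(catalog: Sequence[StrainRecord]):
    """Codon-aware alignment of concatenated cifA+cifB per full syntenic pair."""
    a_seqs, b_seqs = [], []
    for strain in catalog:
        for pair in strain.pairs:
            if pair.status is PairStatus.incomplete or not pair.syntenic:
                continue
            a_seqs.append((pair.pair_id, _trim_codon(pair.gene_a.sequence)))
            b_seqs.append((pair.pair_id, _trim_codon(pair.gene_b.sequence)))
    if len(a_seqs) < 3:
        return None
    aln_a = ph.codon_aware_align(a_seqs)
    aln_b = ph.codon_aware_align(b_seqs)
    amap = dict(aln_a)
    bmap = dict(aln_b)
    return [(pid, amap[pid] + bmap[pid]) for pid, _ in a_seqs]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict
    (also written to ``manifest.tsv`` with SHA-256 content hashes)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    results: dict[str, object] = {}
    catalog = tree = log = None

    def add(name: str, path: str | Path) -> None:
        manifest[name] = str(path)

    try:
        if config.stages.get("simulate", True):
            sim_cfg = se.SimulationConfig(
                seed=stage_seed(config.seed, "simulate"), **config.simulate
            )
            catalog, tree, log = se.simulate_dataset(sim_cfg, out_dir=out / "sim")
            for key in ("genes", "pairs", "strains", "mutations", "tree",
                        "contigs", "events", "references"):
                p = out / "sim" / {
                    "genes": "genes.tsv", "pairs": "pairs.tsv",
                    "strains": "strains.tsv", "mutations": "mutations.tsv",
                    "tree": "strain_tree.nwk", "contigs": "contigs.fasta",
                    "events": "events.tsv", "references": "references_nt.fasta",
                }[key]
                if p.exists():
                    add(f"sim/{p.name}", p)
            results["sim_event_counts"] = log.counts()
        if catalog is None:
            raise RuntimeError("pipeline currently requires the simulate stage")

        if config.stages.get("scan", True):
            refs = dict(read_fasta(out / "sim" / "references_nt.fasta"))
            queries = [
                (name.replace("ref_", ""), str(Seq(nt[:-3]).translate()))
                for name, nt in refs.items()
            ]
            contigs = read_fasta(out / "sim" / "contigs.fasta")
            scan_dir = out / "scan"
            scan_dir.mkdir(exist_ok=True)
            n_hits = 0
            rows = []
            for strain in catalog:
                sc = [c for c in contigs if c[0].startswith(strain.strain_id + "_")]
                if not sc:
                    continue
                pairs = hc.build_catalog_for_strain(strain.strain_id, sc, queries)
                n_hits += sum(
                    (p.gene_a is not None) + (p.gene_b is not None) for p in pairs
                )
                for p in pairs:
                    rows.append(
                        f"{p.pair_id}\t{p.strain_id}\t{p.syntenic}\t"
                        f"{p.gene_a.start if p.gene_a else '.'}\t"
                        f"{p.gene_b.start if p.gene_b else '.'}"
                    )
            scan_path = scan_dir / "rescan_pairs.tsv"
            scan_path.write_text(
                "pair_id\tstrain_id\tsyntenic\ta_start\tb_start\n" + "\n".join(rows) + "\n"
            )
            add("scan/rescan_pairs.tsv", scan_path)
            results["scan_genes_found"] = n_hits
            results["scan_genes_true"] = sum(len(s.genes()) for s in catalog)

        alignment = None
        gene_tree = None
        if config.stages.get("phylo", True):
            alignment = _concat_pair_alignment(catalog)
            if alignment is not None:
                filtered, _ = ph.filter_conserved_blocks(alignment)
                D = ph.distance_matrix(filtered, model=config.phylo.get("model", "K2P"))
                nboot = int(config.phylo.get("bootstrap", 0))
                if nboot > 0:
                    gene_tree = ph.bootstrap_support(
                        filtered, n_reps=nboot, seed=stage_seed(config.seed, "phylo")
                    )
                else:
                    gene_tree = ph.nj_tree(D)
                gene_tree = ph.midpoint_root(gene_tree)
                tree_path = out / "gene_tree.nwk"
                write_newick(gene_tree, tree_path)
                add("gene_tree.nwk", tree_path)
                results["n_aligned_pairs"] = len(alignment)

        if config.stages.get("congruence", True) and alignment is not None:
            # cifA vs cifB congruence over syntenic pairs
            amap = {}
            bmap = {}
            for strain in catalog:
                for pair in strain.pairs:
                    if pair.status is PairStatus.incomplete or not pair.syntenic:
                        continue
                    amap[pair.pair_id] = _trim_codon(pair.gene_a.sequence)
                    bmap[pair.pair_id] = _trim_codon(pair.gene_b.sequence)
            if len(amap) >= 4:
                aln_a = ph.codon_aware_align(list(amap.items()))
                aln_b = ph.codon_aware_align(list(bmap.items()))
                Da = ph.distance_matrix(aln_a, model="K2P")
                Db = ph.distance_matrix(aln_b, model="K2P").submatrix(Da.labels)
                n_perm = int(config.congruence.get("n_perm", 999))
                mres = cg.mantel_test(
                    Da, Db, n_perm=n_perm, seed=stage_seed(config.seed, "congruence")
                )
                results["mantel_cifA_cifB_r"] = mres.statistic
                results["mantel_cifA_cifB_p"] = mres.p_value

        if config.stages.get("recomb", True) and alignment is not None:
            types = {}
            for strain in catalog:
                for pair in strain.pairs:
                    types[pair.pair_id] = pair.cif_type.value
            events = rc.detect_events(
                alignment,
                type_assignments=types,
                alpha=float(config.recomb.get("alpha", 0.05)),
                min_window=int(config.recomb.get("min_window", 10)),
                n_perm=int(config.recomb.get("n_perm", 200)),
                seed=stage_seed(config.seed, "recomb"),
            )
            ev_path = out / "events_detected.tsv"
            with open(ev_path, "w") as fh:
                fh.write("recombinant\tparent_major\tparent_minor\tbreakpoints\t"
                         "p_value\twithin_type\tparent_distance\n")
                for ev in events:
                    fh.write(
                        f"{ev.recombinant_id}\t{ev.parent_major_id}\t"
                        f"{ev.parent_minor_id}\t{','.join(map(str, ev.breakpoints))}\t"
                        f"{ev.p_value:.4g}\t{ev.within_type}\t{ev.parent_distance:.4g}\n"
                    )
            add("events_detected.tsv", ev_path)
            results["n_recomb_events"] = len(events)
            if events:
                results["within_type_fraction"] = float(
                    np.mean([bool(e.within_type) for e in events])
                )
            if log is not None:
                true_rec = log.of_kind("recombination")
                results["n_recomb_events_true"] = len(true_rec)
                if true_rec:
                    results["within_type_fraction_true"] = float(
                        np.mean([r.detail["within_type"] for r in true_rec])
                    )

        if config.stages.get("lossdyn", True):
            presence: dict[tuple, set[str]] = {}
            for strain in catalog:
                for pair in strain.pairs:
                    if pair.status is PairStatus.incomplete:
                        continue
                    for role, g in (("A", pair.gene_a), ("B", pair.gene_b)):
                        if g is None:
                            continue
                        for m in g.mutations:
                            presence.setdefault(
                                (role, m.kind.value, m.codon_index), set()
                            ).add(pair.pair_id)
            summary_tree = gene_tree
            if summary_tree is not None:
                tree_leaves = {
                    lf.taxon.label for lf in summary_tree.leaf_node_iter()
                }
                presence = {
                    k: v & tree_leaves for k, v in presence.items() if v & tree_leaves
                }
            summ = ld.loss_summary(
                catalog,
                gene_tree=summary_tree,
                mutation_presence=presence if summary_tree is not None else None,
            )
            results["loss_summary"] = {
                "n_pairs_full": summ.n_pairs_full,
                "n_intact": summ.n_intact,
                "n_a_pseudo_only": summ.n_a_pseudo_only,
                "n_b_pseudo_only": summ.n_b_pseudo_only,
                "n_both_pseudo": summ.n_both_pseudo,
                "n_independent_events": summ.n_independent_events,
                "terminal_fraction": summ.terminal_fraction,
            }
            if log is not None:
                results["n_lof_events_true"] = (
                    len(log.of_kind("lof_a")) + len(log.of_kind("lof_b"))
                )
            if summ.n_b_pseudo_only + summ.n_a_pseudo_only >= 1:
                lot = ld.loss_order_test(summ.n_b_pseudo_only, summ.n_a_pseudo_only)
                results["loss_order_p"] = lot.p_value
            counts = [
                sum(
                    1 for p in s.pairs
                    if p.status is PairStatus.both_intact and p.syntenic
                )
                for s in catalog
            ]
            if len(counts) >= 10 and sum(counts) > 0:
                disp = ld.dispersion_test(counts)
                results["dispersion_z"] = disp.statistic
                results["dispersion_p"] = disp.p_value
            tab, assoc = ld.phenotype_association(catalog)
            results["phenotype_table"] = tab.values.tolist()
            results["phenotype_fisher_p"] = assoc.p_value
            if gene_tree is not None:
                Dg = ph.patristic_distances(gene_tree)
                # paralog test operates on pair-level labels: adapt by treating
                # the concatenated pair as the gene unit
                pair_catalog = _pairs_as_genes(catalog)
                try:
                    ptest = ld.paralog_distance_test(
                        pair_catalog, Dg,
                        n_perm=int(config.lossdyn.get("n_perm", 999)),
                        seed=stage_seed(config.seed, "lossdyn"),
                        scope="intact_vs_pseudo",
                    )
                    results["paralog_distance_p"] = ptest.p_value
                    results["paralog_mean_intact_intact"] = ptest.extra[
                        "mean_intact_intact"
                    ]
                    results["paralog_mean_intact_pseudo"] = ptest.extra[
                        "mean_intact_pseudo"
                    ]
                except ValueError:
                    pass
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    results_path = out / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
    add("results.json", results_path)
    man_path = out / "manifest.tsv"
    with open(man_path, "w") as fh:
        fh.write("name\tpath\tsha256\n")
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\t{_sha256(Path(manifest[name]))}\n")
    report_path = out / "report.md"
    report_path.write_text(make_report(results))
    return {"manifest": manifest, "results": results,
            "manifest_path": str(man_path), "report_path": str(report_path)}


def _pairs_as_genes(catalog: Sequence[StrainRecord]) -> list[StrainRecord]:
    """View each syntenic pair as one 'gene' labelled by pair_id so the
    paralog-distance test can run on the concatenated-pair tree."""
    from .dataio import GenePair, GeneRecord

    out = []
    for strain in catalog:
        pairs = []
        for p in strain.pairs:
            if p.status is PairStatus.incomplete or p.gene_a is None:
                continue
            g = GeneRecord(
                gene_id=p.pair_id, strain_id=strain.strain_id, role=Role.A,
                contig_id=p.gene_a.contig_id, start=p.gene_a.start,
                end=p.gene_a.end, strand=p.gene_a.strand,
                sequence=p.gene_a.sequence,
                mutations=p.gene_a.mutations + (p.gene_b.mutations if p.gene_b else []),
            )
            pairs.append(
                GenePair(pair_id=p.pair_id, strain_id=strain.strain_id, gene_a=g,
                         gene_b=None, syntenic=False)
            )
        out.append(
            StrainRecord(
                strain_id=strain.strain_id, supergroup=strain.supergroup,
                host_taxon=strain.host_taxon, host_order=strain.host_order,
                phenotype=strain.phenotype, pairs=pairs,
            )
        )
    return out


def make_report(results: dict) -> str:
    """Human-readable summary juxtaposing pipeline estimates with simulator
    ground truth where an event log was available."""
    lines = ["# cifdyn pipeline report", ""]
    ls = results.get("loss_summary")
    if ls:
        lines += [
            "## Pseudogenization categories (fully sequenced syntenic pairs)",
            f"- pairs: {ls['n_pairs_full']}",
            f"- both intact: {ls['n_intact']}",
            f"- cifA pseudogenized only: {ls['n_a_pseudo_only']}",
            f"- cifB pseudogenized only: {ls['n_b_pseudo_only']}",
            f"- both pseudogenized: {ls['n_both_pseudo']}",
        ]
        if ls.get("n_independent_events") is not None:
            lines.append(
                f"- independent loss-of-function events (minimum-gain count): "
                f"{ls['n_independent_events']}"
                + (
                    f" (ground truth {results['n_lof_events_true']})"
                    if "n_lof_events_true" in results
                    else ""
                )
            )
        if ls.get("terminal_fraction") is not None:
            lines.append(f"- terminal-branch fraction: {ls['terminal_fraction']:.2f}")
        lines.append("")
    if "loss_order_p" in results:
        lines.append(f"Loss-ordering binomial p: {results['loss_order_p']:.4g}")
    if "phenotype_fisher_p" in results:
        lines.append(
            f"CI-phenotype association Fisher p (2x2 collapse): "
            f"{results['phenotype_fisher_p']:.4g}"
        )
    if "dispersion_z" in results:
        lines.append(
            f"Poisson equidispersion z = {results['dispersion_z']:.2f} "
            f"(p = {results['dispersion_p']:.3f})"
        )
    if "mantel_cifA_cifB_r" in results:
        lines.append(
            f"cifA-cifB Mantel r = {results['mantel_cifA_cifB_r']:.3f} "
            f"(p = {results['mantel_cifA_cifB_p']:.4g})"
        )
    if "n_recomb_events" in results:
        line = f"Recombination events detected: {results['n_recomb_events']}"
        if "n_recomb_events_true" in results:
            line += f" (ground truth {results['n_recomb_events_true']})"
        lines.append(line)
        if "within_type_fraction" in results:
            line = f"Within-type fraction: {results['within_type_fraction']:.2f}"
            if "within_type_fraction_true" in results:
                line += f" (ground truth {results['within_type_fraction_true']:.2f})"
            lines.append(line)
    if "paralog_distance_p" in results:
        lines.append(
            f"Within-genome paralog distance permutation p: "
            f"{results['paralog_distance_p']:.4g}"
        )
        if results.get("paralog_mean_intact_intact") is not None:
            mii = results["paralog_mean_intact_intact"]
            mip = results.get("paralog_mean_intact_pseudo")
            lines.append(
                f"Mean within-genome distance intact-intact: {mii:.3f}"
                + (f", intact-pseudo: {mip:.3f}" if mip is not None else "")
            )
    if "scan_genes_found" in results:
        lines.append(
            f"Homolog scan recovered {results['scan_genes_found']} / "
            f"{results['scan_genes_true']} simulated genes"
        )
    lines.append("")
    return "\n".join(lines)
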