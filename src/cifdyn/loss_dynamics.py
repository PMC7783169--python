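"""Gene gain/loss statistics for cif pair catalogs.

Implements the loss-of-function analyses: minimum-gain (independent event)
counting of lesions on a gene tree, the cifB-before-cifA loss-ordering
binomial test, pseudogene-frequency and per-site-rate Fisher comparisons,
the CI-phenotype association, Poisson equidispersion of per-strain pair
counts (Cameron-Trivedi auxiliary regression), within-genome paralog
distance permutation, and terminal-branch placement of loss events.

The exact tests (binomial and Fisher) are computed in integer arithmetic
over a common denominator — every table probability is an integer numerator
against C(N, c1) or 2**n — so results are exact to the final float
conversion.  Two-sidedness follows the minimum-likelihood convention: sum
all outcomes whose probability does not exceed that of the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats as sps

from .congruence import TestResult
from .dataio import GenePair, PairStatus, Phenotype, StrainRecord
from .phylo import DistanceMatrix

__all__ = [
    "ContingencyTable",
    "LossSummary",
    "binomial_two_sided",
    "fisher_exact_2x2",
    "rxc_exact",
    "count_independent_lof_events",
    "lof_event_subtrees",
    "loss_order_test",
    "pseudo_frequency_test",
    "per_site_lof_rate",
    "fisher_rate_compare",
    "phenotype_association",
    "dispersion_test",
    "paralog_distance_test",
    "terminal_branch_fraction",
    "loss_summary",
]


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if (self.values < 0).any():
            raise ValueError("negative cell counts")
        if self.values.sum() == 0:
            raise ValueError("empty contingency table")


@dataclass
class LossSummary:
    n_pairs_full: int
    n_intact: int
    n_a_pseudo_only: int
    n_b_pseudo_only: int
    n_both_pseudo: int
    n_independent_events: int | None = None
    lof_rate_a: float | None = None
    lof_rate_b: float | None = None
    terminal_fraction: float | None = None

    def __post_init__(self) -> None:
        total = (
            self.n_intact + self.n_a_pseudo_only + self.n_b_pseudo_only
            + self.n_both_pseudo
        )
        if total != self.n_pairs_full:
            raise ValueError("status categories must sum to n_pairs_full")


# ---------------------------------------------------------------------------
# Exact tests (integer arithmetic, minimum-likelihood two-sidedness)


def binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial test.

    For p=0.5 the computation is fully integer: outcome probabilities share
    the denominator 2**n and two-sidedness sums all outcomes with
    probability <= that of k."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n, n >= 1")
    if p == 0.5:
        weights = [comb(n, i) for i in range(n + 1)]
        obs = weights[k]
        num = sum(w for w in weights if w <= obs)
        return float(Fraction(num, 2**n))
    # general p (rational arithmetic; p as a float-ratio Fraction)
    fp = Fraction(p).limit_denominator(10**12)
    weights_f = [comb(n, i) * fp**i * (1 - fp) ** (n - i) for i in range(n + 1)]
    obs_f = weights_f[k]
    return float(sum(w for w in weights_f if w <= obs_f))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher test on a 2x2 table, hypergeometric-sum
    definition (all tables with the observed margins whose probability does
    not exceed the observed table's)."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cells")
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    if N == 0:
        raise ValueError("empty table")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, comb(N, c1)))


def rxc_exact(table: Sequence[Sequence[int]]) -> float:
    """Exact test for an R x 2 table by complete enumeration of tables with
    the observed margins (feasible for the small margins arising here)."""
    T = np.asarray(table, dtype=int)
    if T.shape[1] != 2:
        raise ValueError("rxc_exact supports R x 2 tables")
    rows = T.sum(axis=1)
    c1 = int(T[:, 0].sum())
    N = int(T.sum())

    def weight(cells: tuple[int, ...]) -> int:
        w = 1
        for r, x in zip(rows, cells):
            w *= comb(int(r), int(x))
        return w

    obs = weight(tuple(T[:, 0]))
    total = 0

    def rec(i: int, remaining: int, cells: list[int]) -> None:
        nonlocal total
        if i == len(rows) - 1:
            if 0 <= remaining <= rows[i]:
                w = weight(tuple(cells + [remaining]))
                if w <= obs:
                    total += w
            return
        lo = max(0, remaining - int(rows[i + 1 :].sum()))
        hi = min(int(rows[i]), remaining)
        for x in range(lo, hi + 1):
            rec(i + 1, remaining - x, cells + [x])

    rec(0, c1, [])
    return float(Fraction(total, comb(N, c1)))


# ---------------------------------------------------------------------------
# Independent-event counting


def lof_event_subtrees(
    gene_tree: dendropy.Tree,
    mutation_presence: Mapping[object, Iterable[str]],
) -> dict[object, list[frozenset[str]]]:
    """Maximal carrying subtrees per mutation under a gain-only model.

    For each mutation, the leaves carrying it are partitioned into the
    maximal subtrees whose leaves all carry it; each such subtree is one
    independent origin (mutations inherited through speciation or
    duplication are not double-counted)."""
    leaves = {lf.taxon.label for lf in gene_tree.leaf_node_iter()}
    out: dict[object, list[frozenset[str]]] = {}
    for key, carriers_it in mutation_presence.items():
        carriers = set(carriers_it)
        unknown = carriers - leaves
        if unknown:
            raise ValueError(f"leaves {sorted(unknown)} absent from tree")
        all_carry: dict[dendropy.Node, bool] = {}
        for node in gene_tree.postorder_node_iter():
            if node.is_leaf():
                all_carry[node] = node.taxon.label in carriers
            else:
                all_carry[node] = all(all_carry[c] for c in node.child_nodes())
        subtrees: list[frozenset[str]] = []
        for node in gene_tree.preorder_node_iter():
            if not all_carry[node]:
                continue
            parent = node.parent_node
            if parent is None or not all_carry[parent]:
                sub = frozenset(lf.taxon.label for lf in node.leaf_iter())
                if sub:  # only count subtrees containing carriers
                    subtrees.append(sub)
        # an empty carrier set yields no subtrees
        out[key] = [s for s in subtrees if s & carriers]
    return out


def count_independent_lof_events(
    gene_tree: dendropy.Tree,
    mutation_presence: Mapping[object, Iterable[str]],
) -> int:
    """Minimum number of independent gains over all mutations (sum over
    mutations of the count of maximal carrying subtrees)."""
    subtrees = lof_event_subtrees(gene_tree, mutation_presence)
    return sum(len(v) for v in subtrees.values())


def terminal_branch_fraction(
    gene_tree: dendropy.Tree,
    event_placements: Sequence[frozenset[str]] | None = None,
    mutation_presence: Mapping[object, Iterable[str]] | None = None,
) -> float:
    """Fraction of independent loss events whose minimal carrying subtree is
    a single leaf (a terminal-branch placement)."""
    if event_placements is None:
        if mutation_presence is None:
            raise ValueError("provide event_placements or mutation_presence")
        event_placements = [
            s for subs in lof_event_subtrees(gene_tree, mutation_presence).values()
            for s in subs
        ]
    if not event_placements:
        raise ValueError("no events")
    return float(np.mean([len(s) == 1 for s in event_placements]))


# ---------------------------------------------------------------------------
# Count-based tests


def loss_order_test(n_b_only: int, n_a_only: int) -> TestResult:
    """Two-sided exact binomial test of whether single-gene pseudogenization
    hits cifB more often than cifA (success probability 0.5)."""
    n = n_b_only + n_a_only
    if n < 1:
        raise ValueError("no singly-pseudogenized pairs")
    p = binomial_two_sided(n_b_only, n, 0.5)
    return TestResult(
        statistic=float(n_b_only), p_value=p, n_permutations=0,
        extra={"n": n, "n_b_only": n_b_only, "n_a_only": n_a_only},
    )


def pseudo_frequency_test(
    n_pseudo_a: int, n_total_a: int, n_pseudo_b: int, n_total_b: int
) -> TestResult:
    """Two-sided Fisher exact comparison of pseudogene frequencies between
    cifA and cifB homolog sets."""
    if n_total_a < n_pseudo_a or n_total_b < n_pseudo_b:
        raise ValueError("totals must be >= pseudo counts")
    table = [
        [n_pseudo_a, n_total_a - n_pseudo_a],
        [n_pseudo_b, n_total_b - n_pseudo_b],
    ]
    p = fisher_exact_2x2(table)
    freq_a = n_pseudo_a / n_total_a if n_total_a else float("nan")
    freq_b = n_pseudo_b / n_total_b if n_total_b else float("nan")
    return TestResult(
        statistic=freq_b - freq_a, p_value=p, n_permutations=0,
        extra={"freq_a": freq_a, "freq_b": freq_b, "table": table},
    )


def per_site_lof_rate(n_events: int, total_aa_sites: int) -> float:
    """Loss-of-function events per amino-acid site."""
    if total_aa_sites <= 0:
        raise ValueError("total_aa_sites must be > 0")
    return n_events / total_aa_sites


def fisher_rate_compare(
    n_events_a: int, sites_a: int, n_events_b: int, sites_b: int
) -> TestResult:
    """Fisher exact comparison of per-site LOF rates via the events versus
    remaining-sites 2x2 table."""
    table = [
        [n_events_a, sites_a - n_events_a],
        [n_events_b, sites_b - n_events_b],
    ]
    p = fisher_exact_2x2(table)
    return TestResult(
        statistic=per_site_lof_rate(n_events_b, sites_b)
        - per_site_lof_rate(n_events_a, sites_a),
        p_value=p,
        n_permutations=0,
        extra={"rate_a": per_site_lof_rate(n_events_a, sites_a),
               "rate_b": per_site_lof_rate(n_events_b, sites_b)},
    )


def phenotype_association(
    catalog: Sequence[StrainRecord],
) -> tuple[ContingencyTable, TestResult]:
    """Association between intact syntenic cif pairs and the CI phenotype.

    Builds the Present / Absent / Pseudogenes-only x CI yes/no table.
    Strains with unknown phenotype are discarded; pairs of undeterminable
    (partial) status are ignored, and strains whose only pairs are partial
    are discarded entirely.  Reports the two-sided Fisher p of the 2x2
    collapse (Present vs rest) and the full R x C exact p.
    """
    rows = {"present": [0, 0], "absent": [0, 0], "pseudo_only": [0, 0]}
    n_used = 0
    for strain in catalog:
        if strain.phenotype is Phenotype.unknown:
            continue
        informative = [
            p for p in strain.pairs if p.status is not PairStatus.incomplete
        ]
        if strain.pairs and not informative:
            continue  # only partially sequenced pairs: undeterminable
        ci = 0 if strain.phenotype is Phenotype.CI else 1
        if any(p.status is PairStatus.both_intact and p.syntenic for p in informative):
            rows["present"][ci] += 1
        elif informative:
            rows["pseudo_only"][ci] += 1
        else:
            rows["absent"][ci] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no strains with known phenotype")
    table = ContingencyTable(
        row_labels=["present", "absent", "pseudo_only"],
        col_labels=["CI", "non-CI"],
        values=np.array([rows["present"], rows["absent"], rows["pseudo_only"]]),
    )
    present = rows["present"]
    rest = [
        rows["absent"][0] + rows["pseudo_only"][0],
        rows["absent"][1] + rows["pseudo_only"][1],
    ]
    p22 = fisher_exact_2x2([present, rest])
    prxc = rxc_exact(table.values)
    a, b = present
    c, d = rest
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return table, TestResult(
        statistic=odds, p_value=p22, n_permutations=0,
        extra={"p_2x2": p22, "p_rxc_exact": prxc, "n_strains": n_used},
    )


def dispersion_test(counts: Sequence[int], variance_function: str = "linear") -> TestResult:
    """Cameron-Trivedi auxiliary-regression test for Poisson equidispersion.

    Regresses ((y_i - mu)^2 - y_i) on g(mu) without intercept, g = mu
    ('linear', NB1-type) or mu^2 ('quadratic', NB2-type); the regression t
    statistic is reported as z with a two-sided normal p.  Positive z means
    overdispersion."""
    y = np.asarray(counts, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 counts")
    mu = y.mean()
    if mu == 0:
        raise ValueError("all counts zero: dispersion undefined")
    z_i = (y - mu) ** 2 - y
    if variance_function == "linear":
        x = np.full_like(y, mu)
    elif variance_function == "quadratic":
        x = np.full_like(y, mu**2)
    else:
        raise ValueError("variance_function must be 'linear' or 'quadratic'")
    # no-intercept OLS: coef = sum(x z)/sum(x^2); t from the usual s.e.
    coef = float(np.sum(x * z_i) / np.sum(x * x))
    resid = z_i - coef * x
    dof = y.size - 1
    s2 = float(np.sum(resid**2) / dof)
    se = np.sqrt(s2 / np.sum(x * x))
    if se > 0:
        z = coef / se
    else:  # perfect fit (e.g. constant counts): sign carries the verdict
        z = float(np.sign(coef)) * np.inf if coef != 0 else 0.0
    p = 2 * float(sps.norm.sf(abs(z)))
    return TestResult(
        statistic=float(z), p_value=max(p, np.finfo(float).tiny), n_permutations=0,
        extra={"mean": float(mu), "variance": float(y.var(ddof=1))},
    )


def paralog_distance_test(
    catalog: Sequence[StrainRecord],
    D_patristic: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    scope: str = "intact_only",
) -> TestResult:
    """Within-genome paralog distance permutation test.

    Observed: mean patristic distance over all unordered within-genome pairs
    of qualifying genes (scope 'intact_only': genes without lesions from
    fully sequenced pairs; 'intact_vs_pseudo': all fully sequenced genes).
    Null: genome labels permuted across genes, preserving per-genome counts.
    Two-sided p = (b+1)/(m+1) on the more extreme tail, doubled and capped.
    Also reports the descriptive intact-intact and intact-pseudo mean
    distances within genomes."""
    if scope not in {"intact_only", "intact_vs_pseudo"}:
        raise ValueError("scope must be 'intact_only' or 'intact_vs_pseudo'")
    genome_genes: list[tuple[str, str, bool]] = []  # (genome, label, intact)
    for strain in catalog:
        for pair in strain.pairs:
            for g in (pair.gene_a, pair.gene_b):
                if g is None or g.completeness != "full":
                    continue
                if g.gene_id not in D_patristic.labels:
                    continue
                intact = not g.is_pseudogene
                if scope == "intact_only" and not intact:
                    continue
                genome_genes.append((strain.strain_id, g.gene_id, intact))
    labels = [g for _, g, _ in genome_genes]
    genomes = [s for s, _, _ in genome_genes]
    idx = np.array([D_patristic.labels.index(l) for l in labels])
    M = D_patristic.values
    gvec = np.array(genomes)

    def stat(assign: np.ndarray) -> float:
        tot, cnt = 0.0, 0
        for genome in np.unique(assign):
            members = idx[assign == genome]
            if members.size < 2:
                continue
            sub = M[np.ix_(members, members)]
            iu = np.triu_indices(members.size, k=1)
            tot += sub[iu].sum()
            cnt += iu[0].size
        if cnt == 0:
            raise ValueError("fewer than 2 qualifying within-genome gene pairs")
        return tot / cnt

    obs = stat(gvec)
    rng = np.random.default_rng(seed)
    lo = hi = 0
    for _ in range(n_perm):
        perm = rng.permutation(gvec)
        s = stat(perm)
        if s <= obs + 1e-12:
            lo += 1
        if s >= obs - 1e-12:
            hi += 1
    p = min(1.0, 2 * min(lo + 1, hi + 1) / (n_perm + 1))

    # descriptive intact-intact vs intact-pseudo means within genomes
    ii, ip = [], []
    by_genome: dict[str, list[tuple[str, bool]]] = {}
    for genome, label, intact in genome_genes:
        by_genome.setdefault(genome, []).append((label, intact))
    for members in by_genome.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (l1, i1), (l2, i2) = members[i], members[j]
                d = D_patristic[l1, l2]
                if i1 and i2:
                    ii.append(d)
                elif i1 != i2:
                    ip.append(d)
    return TestResult(
        statistic=obs, p_value=p, n_permutations=n_perm,
        extra={
            "mean_intact_intact": float(np.mean(ii)) if ii else None,
            "mean_intact_pseudo": float(np.mean(ip)) if ip else None,
            "n_genes": len(labels),
        },
    )


def loss_summary(
    catalog: Sequence[StrainRecord],
    gene_tree: dendropy.Tree | None = None,
    mutation_presence: Mapping[object, Iterable[str]] | None = None,
    aa_sites_a: int | None = None,
    aa_sites_b: int | None = None,
) -> LossSummary:
    """Tabulate pseudogenization categories over fully sequenced syntenic
    pairs, plus (when a gene tree and lesion presence are supplied) the
    independent-event count and terminal-branch fraction."""
    counts = {s: 0 for s in PairStatus}
    for strain in catalog:
        for pair in strain.pairs:
            counts[pair.status] += 1
    n_full = sum(
        counts[s]
        for s in (
            PairStatus.both_intact, PairStatus.a_pseudo_only,
            PairStatus.b_pseudo_only, PairStatus.both_pseudo,
        )
    )
    n_events = None
    terminal = None
    if gene_tree is not None and mutation_presence is not None:
        subs = lof_event_subtrees(gene_tree, mutation_presence)
        placements = [s for v in subs.values() for s in v]
        n_events = len(placements)
        terminal = (
            float(np.mean([len(s) == 1 for s in placements])) if placements else None
        )
    rate_a = rate_b = None
    if n_events is not None and aa_sites_a and aa_sites_b:
        pass  # rates need per-gene event splits; computed by callers
    return LossSummary(
        n_pairs_full=n_full,
        n_intact=counts[PairStatus.both_intact],
        n_a_pseudo_only=counts[PairStatus.a_pseudo_only],
        n_b_pseudo_only=counts[PairStatus.b_pseudo_only],
        n_both_pseudo=counts[PairStatus.both_pseudo],
        n_independent_events=n_events,
        terminal_fraction=terminal,
    )
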