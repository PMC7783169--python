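"""Recombination detection among aligned cifA-cifB concatemers.

A MaxChi-style scan: for each pair within a sequence triplet, sites that
vary within the triplet are reduced to a match/mismatch vector; every
candidate partition point yields a 2x2 (match/mismatch x left/right) table
and the statistic is the maximum chi-square over partitions.  Significance
comes from permuting the order of variable sites, which regenerates the
max-statistic null and thereby absorbs the multiplicity of partitions;
a Bonferroni correction over the number of triplets scanned is applied when
scanning whole alignments.  Detected events carry a within-type flag and the
distance between their inferred parents, feeding the parental-distance
permutation test of the claim that recombination is restricted to closely
related sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .congruence import TestResult
from .phylo import DistanceMatrix, distance_matrix

__all__ = [
    "RecombinationEvent",
    "MaxChiResult",
    "maxchi_scan",
    "detect_events",
    "parental_distance_test",
    "breakpoint_profile",
]


@dataclass
class RecombinationEvent:
    recombinant_id: str
    parent_major_id: str
    parent_minor_id: str
    breakpoints: list[int]  # alignment columns, strictly increasing
    p_value: float  # Bonferroni-corrected
    within_type: bool | None = None
    parent_distance: float | None = None

    def __post_init__(self) -> None:
        if self.recombinant_id in (self.parent_major_id, self.parent_minor_id):
            raise ValueError("parents must be distinct from the recombinant")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")


@dataclass
class MaxChiResult:
    testable: bool
    chi2: float = 0.0
    p_value: float = 1.0
    breakpoint_col: int | None = None  # alignment column of the best partition
    breakpoint_var_index: int | None = None  # index among variable sites
    pair: tuple[int, int] | None = None  # indices within the triplet
    n_variable: int = 0


def _variable_sites(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    mat = np.array([list(s.upper()) for s in seqs])
    ok = np.all(np.isin(mat, list("ACGT")), axis=0)
    var = ok & ~np.all(mat == mat[0], axis=0)
    cols = np.flatnonzero(var)
    return mat[:, cols], cols


def _chi2_profile(match: np.ndarray, min_window: int) -> np.ndarray:
    """Chi-square of the 2x2 (match/mismatch x left/right) table at every
    partition point k in [min_window, n-min_window] (vectorized).

    ``match`` may be 1-D (one vector) or 2-D (rows are permuted replicates);
    returns an array of chi2 values with partition as the last axis."""
    m = np.atleast_2d(match).astype(np.int64)
    n = m.shape[1]
    ks = np.arange(min_window, n - min_window + 1)
    cum = np.cumsum(m, axis=1)
    a = cum[:, ks - 1]          # left matches
    b = ks[None, :] - a         # left mismatches
    total = cum[:, -1][:, None]
    c = total - a               # right matches
    d = (n - ks)[None, :] - c   # right mismatches
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = a * d - b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * num.astype(float) ** 2 / denom, 0.0)
    return chi2 if match.ndim > 1 else chi2[0]


def _max_chi2(match: np.ndarray, min_window: int) -> tuple[float, int]:
    """Max chi-square over partitions of one match vector; returns
    (max chi2, argmax partition point)."""
    chi2 = _chi2_profile(match, min_window)
    i = int(np.argmax(chi2))
    return float(chi2[i]), min_window + i


def maxchi_scan(
    triplet_alignment: Sequence[tuple[str, str]],
    min_window: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
) -> MaxChiResult:
    """MaxChi scan of one aligned triplet.

    Returns an untestable result when fewer than ``2 * min_window`` variable
    sites exist.  The p-value is the permutation tail probability of the
    maximum chi-square over all pairs and partitions under random ordering
    of variable sites.
    """
    if len(triplet_alignment) != 3:
        raise ValueError("maxchi_scan needs exactly 3 aligned sequences")
    names = [n for n, _ in triplet_alignment]
    seqs = [s for _, s in triplet_alignment]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    var_mat, cols = _variable_sites(seqs)
    nvar = var_mat.shape[1]
    if nvar < 2 * min_window:
        return MaxChiResult(testable=False, n_variable=nvar)

    pairs = [(0, 1), (0, 2), (1, 2)]
    matches = {pq: (var_mat[pq[0]] == var_mat[pq[1]]) for pq in pairs}
    obs, obs_k, obs_pair = 0.0, None, None
    for pq in pairs:
        chi2, k = _max_chi2(matches[pq], min_window)
        if chi2 > obs:
            obs, obs_k, obs_pair = chi2, k, pq
    rng = np.random.default_rng(seed)
    # one set of site-order permutations shared by the three pairs
    perms = np.argsort(rng.random((n_perm, nvar)), axis=1)
    best = np.zeros(n_perm)
    for pq in pairs:
        permuted = matches[pq][perms]
        best = np.maximum(best, _chi2_profile(permuted, min_window).max(axis=1))
    b = int(np.sum(best >= obs - 1e-12))
    p = (b + 1) / (n_perm + 1)
    col = int(cols[obs_k]) if obs_k is not None and obs_k < nvar else None
    return MaxChiResult(
        testable=True, chi2=float(obs), p_value=float(p),
        breakpoint_col=col, breakpoint_var_index=obs_k, pair=obs_pair,
        n_variable=nvar,
    )


def _identify_recombinant(
    seqs: list[str], k_col: int, names: list[str]
) -> tuple[str, str, str] | None:
    """Designate the triplet member whose nearest neighbor switches across
    the breakpoint as the recombinant; the nearer parent on the larger side
    is the major parent."""
    mat = np.array([list(s.upper()) for s in seqs])
    left, right = mat[:, :k_col], mat[:, k_col:]

    def pdist(block: np.ndarray, i: int, j: int) -> float:
        ok = np.isin(block[i], list("ACGT")) & np.isin(block[j], list("ACGT"))
        if ok.sum() == 0:
            return 0.0
        return float(np.mean(block[i][ok] != block[j][ok]))

    for r in range(3):
        others = [x for x in range(3) if x != r]
        dl = {o: pdist(left, r, o) for o in others}
        dr = {o: pdist(right, r, o) for o in others}
        nn_l = min(others, key=lambda o: dl[o])
        nn_r = min(others, key=lambda o: dr[o])
        if nn_l != nn_r:
            # major parent = parent of the longer flank
            major = nn_l if k_col >= mat.shape[1] - k_col else nn_r
            minor = nn_r if major == nn_l else nn_l
            return names[r], names[major], names[minor]
    return None


def detect_events(
    alignment: Sequence[tuple[str, str]],
    type_assignments: dict[str, str] | None = None,
    alpha: float = 0.05,
    min_window: int = 10,
    seed: int = 0,
    n_perm: int = 200,
    D: DistanceMatrix | None = None,
) -> list[RecombinationEvent]:
    """Scan all triplets of an alignment and merge significant signals.

    Significance is Bonferroni-corrected over the number of triplets scanned.
    Signals sharing a recombinant with overlapping breakpoint windows merge
    into a single event (strongest signal kept).  ``within_type`` is set when
    recombinant and both parents share a type assignment.
    """
    names = [n for n, _ in alignment]
    if len(names) < 3:
        raise ValueError("need at least 3 sequences")
    if D is None:
        D = distance_matrix(alignment, model="p")
    triplets = list(itertools.combinations(range(len(names)), 3))
    n_tests = len(triplets)
    rng = np.random.default_rng(seed)
    raw: list[RecombinationEvent] = []
    for idx, trip in enumerate(triplets):
        sub = [alignment[i] for i in trip]
        res = maxchi_scan(sub, min_window=min_window, n_perm=n_perm,
                          seed=int(rng.integers(0, 2**31 - 1)))
        if not res.testable:
            continue
        p_corr = min(1.0, res.p_value * n_tests)
        if p_corr > alpha:
            continue
        ident = _identify_recombinant(
            [s for _, s in sub], res.breakpoint_col, [n for n, _ in sub]
        )
        if ident is None:
            continue
        rec, major, minor = ident
        within = None
        if type_assignments is not None:
            within = len({type_assignments.get(x) for x in (rec, major, minor)}) == 1
        raw.append(
            RecombinationEvent(
                recombinant_id=rec,
                parent_major_id=major,
                parent_minor_id=minor,
                breakpoints=[res.breakpoint_col],
                p_value=p_corr,
                within_type=within,
                parent_distance=D[major, minor],
            )
        )
    # merge: same recombinant, breakpoints within one window
    raw.sort(key=lambda e: e.p_value)
    merged: list[RecombinationEvent] = []
    for ev in raw:
        dup = False
        for kept in merged:
            if kept.recombinant_id == ev.recombinant_id and any(
                abs(b1 - b2) <= 3 * min_window
                for b1 in kept.breakpoints
                for b2 in ev.breakpoints
            ):
                dup = True
                break
        if not dup:
            merged.append(ev)
    return merged


def parental_distance_test(
    events: Sequence[RecombinationEvent],
    D: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Are inferred parents closer than random sequence pairs?

    Observed statistic: mean distance between each event's parents.  Null:
    each event's parent pair replaced by a uniformly drawn unordered pair of
    distinct sequences.  One-sided (lower tail), p = (b+1)/(m+1).
    """
    if not events:
        raise ValueError("no events supplied")
    for ev in events:
        for pid in (ev.parent_major_id, ev.parent_minor_id):
            if pid not in D.labels:
                raise ValueError(f"event parent {pid} absent from distance matrix")
    obs = float(np.mean([D[ev.parent_major_id, ev.parent_minor_id] for ev in events]))
    n = len(D.labels)
    iu = np.triu_indices(n, k=1)
    all_pairs = D.values[iu]
    rng = np.random.default_rng(seed)
    k = len(events)
    draws = rng.integers(0, all_pairs.size, size=(n_perm, k))
    null_means = all_pairs[draws].mean(axis=1)
    b = int(np.sum(null_means <= obs + 1e-12))
    return TestResult(
        statistic=obs,
        p_value=(b + 1) / (n_perm + 1),
        n_permutations=n_perm,
        extra={"n_events": k},
    )


def breakpoint_profile(
    recombinant: tuple[str, str],
    parents: Sequence[tuple[str, str]],
    window: int = 50,
) -> dict[str, np.ndarray]:
    """Sliding-window identity of the recombinant against each parent.

    Returns per-parent identity traces over window midpoints plus the
    column where the two traces cross (None when they never cross)."""
    rname, rseq = recombinant
    if len(parents) != 2:
        raise ValueError("need exactly 2 parents")
    L = len(rseq)
    if window > L:
        raise ValueError("window larger than alignment")
    r = np.array(list(rseq.upper()))
    traces = {}
    for pname, pseq in parents:
        p = np.array(list(pseq.upper()))
        same = (r == p).astype(float)
        kernel = np.ones(window) / window
        traces[pname] = np.convolve(same, kernel, mode="valid")
    (n1, t1), (n2, t2) = traces.items()
    diff = t1 - t2
    crossing = None
    sign = np.sign(diff)
    nz = np.flatnonzero(sign != 0)
    if nz.size >= 2:
        s = sign[nz]
        flips = np.flatnonzero(np.diff(s) != 0)
        if flips.size:
            crossing = int(nz[flips[0]] + window // 2)
    return {"traces": traces, "crossing": crossing}
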