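"""Cophylogenetic congruence statistics.

Mantel tests on patristic-distance matrices and ParaFit (principal
coordinates + fourth-corner cross-product) with per-link contributions are
used to ask whether cifA and cifB trees, or cif gene trees and their strain
tree, codiverge.  All permutation p-values use the (b+1)/(m+1) convention,
so p is never reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phylo import DistanceMatrix

__all__ = [
    "AssociationMatrix",
    "TestResult",
    "mantel_test",
    "categorical_distance",
    "parafit_global",
]


@dataclass
class AssociationMatrix:
    """Binary host x parasite association matrix (e.g., strain x cif gene)."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("association matrix shape mismatch")
        if not np.isin(self.values, [0, 1]).all():
            raise ValueError("association matrix must be binary")

    @property
    def links(self) -> list[tuple[str, str]]:
        rr, cc = np.nonzero(self.values)
        return [(self.row_labels[i], self.col_labels[j]) for i, j in zip(rr, cc)]


@dataclass
class TestResult:
    __test__ = False  # keep pytest from collecting this dataclass

    statistic: float
    p_value: float
    n_permutations: int
    per_link: list[tuple[tuple[str, str], float, float, bool]] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_permutations > 0 and self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p-value below permutation floor")


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mantel_test(
    D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> TestResult:
    """One-sided (positive association) Mantel test.

    The statistic is the Pearson correlation of the off-diagonal entries; the
    null distribution permutes rows and columns of D2 simultaneously;
    p = (b+1)/(m+1) with b the number of permuted statistics >= observed.
    """
    if D1.labels != D2.labels:
        raise ValueError("label mismatch between distance matrices")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _offdiag(D1.values)
    M2 = D2.values
    y = _offdiag(M2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) distance matrix")
    n = M2.shape[0]
    xc = (x - x.mean()) / x.std()

    def corr(yv: np.ndarray) -> float:
        return float(np.mean(xc * (yv - yv.mean()) / yv.std()))

    obs = corr(y)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _offdiag(M2[np.ix_(perm, perm)])
        if np.std(yp) == 0:
            b += 1
            continue
        if corr(yp) >= obs - 1e-12:
            b += 1
    return TestResult(statistic=obs, p_value=(b + 1) / (n_perm + 1), n_permutations=n_perm)


def categorical_distance(labels: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """0/1 distance matrix from (item, category) pairs: 0 within a category,
    1 between categories.  Items with an empty category are excluded."""
    kept = [(i, c) for i, c in labels if c]
    ids = [i for i, _ in kept]
    cats = np.array([c for _, c in kept])
    M = (cats[:, None] != cats[None, :]).astype(float)
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(ids, M)


# ---------------------------------------------------------------------------
# ParaFit


def _pcoa_coords(D: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Principal-coordinate axes of a distance matrix.

    Axes with eigenvalue below -tol * max(eig) indicate non-metricity; such
    axes are dropped (patristic matrices are metric, so the correction mass
    is ordinarily negligible)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    G = (G + G.T) / 2
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vmax = max(vals.max(), 1.0)
    keep = vals > tol * vmax
    return vecs[:, keep] * np.sqrt(vals[keep])


def _parafit_stat(Bh: np.ndarray, A: np.ndarray, Bp: np.ndarray) -> float:
    # fourth-corner cross product: hosts x axes_h, A hosts x parasites
    D = Bh.T @ A @ Bp
    return float(np.sum(D * D))


def parafit_global(
    D_host: DistanceMatrix,
    D_parasite: DistanceMatrix,
    A: AssociationMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    with_links: bool = True,
) -> TestResult:
    """Global ParaFit test of host-parasite cophylogenetic congruence.

    The global statistic is the sum of squared entries of the fourth-corner
    cross-product of the two sets of principal coordinates through A.  The
    null permutes, independently for each parasite, its host associations.
    Per-link contributions are leave-one-link-out differences, each with its
    own permutation p and a significance flag at ``alpha``.
    """
    if A.values.sum() == 0:
        raise ValueError("association matrix has no links")
    if A.row_labels != D_host.labels or A.col_labels != D_parasite.labels:
        raise ValueError("association labels must match distance-matrix labels")
    Bh = _pcoa_coords(D_host.values)
    Bp = _pcoa_coords(D_parasite.values)
    Amat = A.values.astype(float)
    n_h = Amat.shape[0]
    obs = _parafit_stat(Bh, Amat, Bp)

    rng = np.random.default_rng(seed)
    perms = [
        np.column_stack([rng.permutation(n_h) for _ in range(Amat.shape[1])])
        for _ in range(n_perm)
    ]

    def permuted(Ap_idx: np.ndarray) -> np.ndarray:
        out = np.empty_like(Amat)
        for j in range(Amat.shape[1]):
            out[:, j] = Amat[Ap_idx[:, j], j]
        return out

    null_stats = np.array([_parafit_stat(Bh, permuted(p), Bp) for p in perms])
    b = int(np.sum(null_stats >= obs - 1e-12))
    p_global = (b + 1) / (n_perm + 1)

    per_link = None
    if with_links:
        per_link = []
        links = list(zip(*np.nonzero(A.values)))
        for (i, j) in links:
            A1 = Amat.copy()
            A1[i, j] = 0.0
            link_obs = obs - _parafit_stat(Bh, A1, Bp)
            bl = 0
            for pidx, pm in enumerate(perms):
                Ap = permuted(pm)
                Ap1 = Ap.copy()
                # drop the permuted image of this link
                ip = int(np.nonzero(pm[:, j] == i)[0][0])
                if Ap1[ip, j] == 1.0:
                    Ap1[ip, j] = 0.0
                link_null = null_stats[pidx] - _parafit_stat(Bh, Ap1, Bp)
                if link_null >= link_obs - 1e-12:
                    bl += 1
            pl = (bl + 1) / (n_perm + 1)
            per_link.append(
                (
                    (A.row_labels[i], A.col_labels[j]),
                    float(link_obs),
                    float(pl),
                    bool(pl <= alpha),
                )
            )
    return TestResult(
        statistic=obs, p_value=p_global, n_permutations=n_perm, per_link=per_link
    )
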