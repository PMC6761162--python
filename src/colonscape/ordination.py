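"""Ordination and variance decomposition of community composition.

Principal coordinates analysis (with a Lingoes correction for
non-Euclidean dissimilarities such as Bray-Curtis), permutational
multivariate analysis of variance (perMANOVA), distance-based redundancy
analysis (db-RDA in the McArdle-Anderson style: the response is the full set
of corrected principal coordinates), and variation partitioning of community
composition into named predictor blocks on the Ezekiel-adjusted R-squared
scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._rng import substream
from .diversity import validate_distance_matrix

__all__ = [
    "PcoaResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "DbrdaResult",
    "dbrda",
    "VarpartResult",
    "variation_partition",
    "design_matrices",
]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame       # samples x retained axes, scaled by sqrt(eig)
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray
    correction_applied: bool
    lingoes_constant: float


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(d: pd.DataFrame, correction: str = "lingoes", eig_tol: float = 1e-8) -> PcoaResult:
    """Principal coordinates of a dissimilarity matrix.

    The Gower-centered matrix of -0.5 * D^2 is eigendecomposed; if the most
    negative eigenvalue is materially negative (below ``-eig_tol`` times the
    largest), the Lingoes constant is added to all squared off-diagonal
    dissimilarities and the decomposition is redone, which makes semimetric
    inputs such as Bray-Curtis representable in Euclidean space.
    """
    validate_distance_matrix(d)
    ids = d.index
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two samples")
    d2 = d.to_numpy(dtype=float) ** 2

    applied = False
    constant = 0.0
    eigval, eigvec = np.linalg.eigh(_gower_center(d2))
    if correction == "lingoes" and eigval.min() < -eig_tol * max(eigval.max(), 1e-300):
        constant = -eigval.min()
        d2c = d2 + 2.0 * constant
        np.fill_diagonal(d2c, 0.0)
        eigval, eigvec = np.linalg.eigh(_gower_center(d2c))
        applied = True

    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eig_tol * max(abs(eigval).max(), 1e-300)
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    positive = eigval[eigval > 0].sum()
    prop = np.where(eigval > 0, eigval, 0.0) / positive if positive > 0 else eigval * 0.0
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return PcoaResult(
        coordinates=frame,
        eigenvalues=eigval,
        proportion_explained=prop,
        correction_applied=applied,
        lingoes_constant=float(constant),
    )


# ---------------------------------------------------------------------------
# perMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    statistic: float                # pseudo-F
    pvalue: float
    ss_total: float
    ss_within: float
    ss_between: float
    n_groups: int
    n_samples: int
    n_permutations: int


def _ss_within(d2: np.ndarray, indicator: np.ndarray, sizes: np.ndarray) -> float:
    # sum_g (1/n_g) sum_{i<j in g} d2_ij, via quadratic forms of group indicators
    per_group = np.einsum("ig,ij,jg->g", indicator, d2, indicator) / 2.0
    return float(np.sum(per_group / sizes))


def permanova(
    d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """Permutational MANOVA on a dissimilarity matrix.

    Partitions the total sum of squared dissimilarities into between- and
    within-group components and assesses the pseudo-F statistic against
    ``n_perm`` random relabelings of the samples.  The reported p-value uses
    the ``(exceedances + 1) / (n_perm + 1)`` convention and therefore can
    never be zero.
    """
    validate_distance_matrix(d)
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("groups must align with the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs at least two samples")

    d2 = d.to_numpy(dtype=float) ** 2
    ss_total = float(d2.sum()) / (2.0 * n)
    ind = np.zeros((n, a))
    ind[np.arange(n), codes] = 1.0
    ss_within = _ss_within(d2, ind, sizes)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))

    rng = substream(seed, "permanova")
    exceed = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        ssw = _ss_within(d2, ind[perm], sizes)
        ssb = ss_total - ssw
        f_perm = (ssb / (a - 1)) / (ssw / (n - a))
        if f_perm >= f_obs:
            exceed += 1
    pvalue = (exceed + 1.0) / (n_perm + 1.0)
    return PermanovaResult(
        statistic=float(f_obs),
        pvalue=float(pvalue),
        ss_total=ss_total,
        ss_within=float(ss_within),
        ss_between=float(ss_between),
        n_groups=a,
        n_samples=n,
        n_permutations=int(n_perm),
    )


# ---------------------------------------------------------------------------
# db-RDA and variation partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DbrdaResult:
    r2: float
    adj_r2: float
    rank: int
    n_samples: int


def _as_matrix(x) -> np.ndarray:
    arr = x.to_numpy(dtype=float) if hasattr(x, "to_numpy") else np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _fit_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """R^2 of multivariate Y on centered X, with the predictor rank used."""
    yc = _center(y)
    xc = _center(x)
    ss_total = float(np.sum(yc**2))
    if ss_total == 0:
        raise ValueError("response has zero variance")
    q, r = np.linalg.qr(xc)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1e-300)
    q = q[:, keep]
    fitted = q @ (q.T @ yc)
    return float(np.sum(fitted**2)) / ss_total, int(keep.sum())


def _adjust(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        raise ValueError("too many predictors for the sample size")
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - m - 1.0)


def dbrda(d: pd.DataFrame, x, condition=None) -> DbrdaResult:
    """Distance-based RDA: fraction of a dissimilarity matrix's inertia
    explained by predictors ``x``.

    The response is the full set of Lingoes-corrected principal coordinates
    of ``d``; with ``condition`` both response and predictors are first
    residualised on the conditioning variables, yielding a partial fit.
    ``adj_r2`` applies the Ezekiel correction with the predictor rank.
    """
    y = pcoa(d).coordinates.to_numpy()
    xm = _as_matrix(x)
    n = y.shape[0]
    if xm.shape[0] != n:
        raise ValueError("predictors must align with the distance matrix")
    if condition is not None:
        cm = _center(_as_matrix(condition))
        qc, rc = np.linalg.qr(cm)
        diag = np.abs(np.diag(rc))
        qc = qc[:, diag > 1e-10 * max(diag.max(), 1e-300)]
        pre_norm = np.linalg.norm(_center(xm), axis=0)
        y = _center(y) - qc @ (qc.T @ _center(y))
        xm = _center(xm) - qc @ (qc.T @ _center(xm))
        # predictors absorbed by the condition carry no partial information
        post_norm = np.linalg.norm(xm, axis=0)
        keep = post_norm > 1e-8 * np.maximum(pre_norm, 1e-300)
        xm = xm[:, keep]
        if xm.shape[1] == 0:
            return DbrdaResult(r2=0.0, adj_r2=0.0, rank=0, n_samples=n)
    r2, rank = _fit_r2(y, xm)
    return DbrdaResult(r2=r2, adj_r2=_adjust(r2, n, rank), rank=rank, n_samples=n)


@dataclass(frozen=True)
class VarpartResult:
    """Variation partition of community composition over 2-3 predictor blocks.

    ``fractions`` maps frozensets of block names to the fraction of adjusted
    R-squared unique to exactly that combination (inclusion-exclusion on the
    adjusted scale); negative fractions are reported as-is.  ``marginal`` and
    ``unique`` give per-block adjusted R-squared alone and conditioned on all
    other blocks, respectively.
    """

    fractions: dict
    marginal: dict
    unique: dict
    total_adj_r2: float
    residual: float
    subset_adj_r2: dict

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"component": "+".join(sorted(k)), "fraction": v}
            for k, v in self.fractions.items()
        ]
        rows.append({"component": "residual", "fraction": self.residual})
        return pd.DataFrame(rows)


def variation_partition(d: pd.DataFrame, blocks: dict) -> VarpartResult:
    """Partition a dissimilarity matrix's inertia among predictor blocks.

    Every non-empty subset of blocks is fitted by :func:`dbrda`; the subset
    adjusted R-squared values are combined by inclusion-exclusion into unique
    and shared fractions.  Entering blocks in any order yields the same
    partition.
    """
    names = list(blocks)
    if not 2 <= len(names) <= 3:
        raise ValueError("variation partitioning supports 2 or 3 predictor blocks")
    mats = {k: _as_matrix(v) for k, v in blocks.items()}

    subset_r2: dict[frozenset, float] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            x = np.hstack([mats[c] for c in combo])
            subset_r2[frozenset(combo)] = dbrda(d, x).adj_r2

    full = frozenset(names)
    total = subset_r2[full]
    # Moebius inversion: R(S) = sum of fractions f(T) over T intersecting S,
    # equivalently total - R(complement of T's superset); solve directly.
    fractions: dict[frozenset, float] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            t = frozenset(combo)
            # f(T) = sum_{S subseteq T} (-1)^(|T|-|S|) * [total - R(full - S)]
            val = 0.0
            for j in range(0, len(combo) + 1):
                for sub in combinations(combo, j):
                    s = frozenset(sub)
                    r_rest = subset_r2.get(full - s, 0.0) if full - s else 0.0
                    val += (-1.0) ** (len(t) - len(s)) * (total - r_rest)
            fractions[t] = val

    marginal = {n: subset_r2[frozenset([n])] for n in names}
    unique = {
        n: total - (subset_r2[full - frozenset([n])] if len(names) > 1 else 0.0)
        for n in names
    }
    check = sum(fractions.values())
    if abs(check - total) > 1e-9:
        raise AssertionError("partition fractions do not sum to the total adjusted R2")
    return VarpartResult(
        fractions=fractions,
        marginal=marginal,
        unique=unique,
        total_adj_r2=total,
        residual=1.0 - total,
        subset_adj_r2=subset_r2,
    )


# ---------------------------------------------------------------------------
# Design encodings for the colon sampling design
# ---------------------------------------------------------------------------

def _orthogonal_polynomials(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial contrasts of a numeric coordinate."""
    v = np.vander(x.astype(float), degree + 1, increasing=True)
    q, _ = np.linalg.qr(v)
    return q[:, 1: degree + 1]


def design_matrices(
    metadata: pd.DataFrame, longitudinal_degree: int = 2
) -> dict[str, np.ndarray]:
    """Standard predictor blocks for the colon design.

    The longitudinal axis (block 1..7, proximal to distal) is encoded as
    orthogonal polynomials of configurable degree (default quadratic: a
    smooth monotone trend plus curvature); the lateral axis as a mucus
    indicator; diet as treatment dummies.
    """
    out: dict[str, np.ndarray] = {}
    if "block" in metadata:
        out["longitudinal"] = _orthogonal_polynomials(
            metadata["block"].to_numpy(), longitudinal_degree
        )
    if "compartment" in metadata:
        out["lateral"] = (metadata["compartment"].to_numpy() == "mucus").astype(float)[:, None]
    if "diet" in metadata and metadata["diet"].nunique() > 1:
        out["diet"] = pd.get_dummies(metadata["diet"], drop_first=True).to_numpy(float)
    return out
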