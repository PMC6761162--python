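"""Asymmetric eigenvector maps (AEM) for directional spatial processes.

AEM builds spatial predictor variables from a *directed* site graph: an
origin node is placed upstream of the hypothesised flow, every site is
connected to the origin by a unique directed path, and the binary
site-by-edge matrix (E[i, j] = 1 when edge j lies on the path from the
origin to site i) is column-centered and decomposed by SVD.  The left
singular vectors are orthogonal spatial eigenfunctions that can be
forward-selected in a redundancy analysis of community composition;
comparing models built under opposing direction hypotheses (e.g. proximal
to distal transport versus the reverse) indicates the net direction of
influence.

Edges can be down-weighted with their distance from the origin, which makes
the leading eigenfunctions emphasise variation generated close to the
hypothesised source; this weighting is what gives opposing hypotheses
distinguishable bases on a symmetric transect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .ordination import _adjust, _center, _fit_r2

__all__ = [
    "ORIGIN",
    "AemBasis",
    "build_aem_basis",
    "chain_edges",
    "lateral_edges",
    "sample_eigenfunctions",
    "hellinger",
    "SelectionResult",
    "forward_select",
    "DirectionComparison",
    "compare_directions",
]

ORIGIN = "__origin__"


@dataclass(frozen=True)
class AemBasis:
    site_ids: tuple
    edges: tuple                      # (parent, child) pairs, origin included
    incidence: pd.DataFrame           # sites x edges, binary path membership
    weights: np.ndarray               # one weight per edge
    eigenfunctions: pd.DataFrame      # sites x k, orthonormal columns
    singular_values: np.ndarray


def chain_edges(site_ids) -> list[tuple]:
    """Directed chain through ``site_ids`` in the given (hypothesis) order."""
    ids = list(site_ids)
    return list(zip(ids[:-1], ids[1:]))


def lateral_edges(blocks, source: str = "mucus") -> tuple[list, list[tuple]]:
    """Site ids and edges for the lateral (mucus <-> lumen) hypothesis.

    Each longitudinal block contributes a two-site column; the hypothesised
    source compartment sits upstream of the other.  Returns
    ``(site_ids, edges)`` with sites named ``"<compartment>:<block>"``.
    """
    if source not in ("mucus", "lumen"):
        raise ValueError("source must be 'mucus' or 'lumen'")
    sink = "lumen" if source == "mucus" else "mucus"
    sites, edges = [], []
    for b in blocks:
        up, down = f"{source}:{b}", f"{sink}:{b}"
        sites.extend([up, down])
        edges.append((up, down))
    return sites, edges


def _edge_weights(depths: np.ndarray, weighting) -> np.ndarray:
    if isinstance(weighting, str):
        if weighting == "none":
            return np.ones_like(depths, dtype=float)
        if weighting == "linear":
            return 1.0 - depths / (depths.max() + 1.0)
        if weighting == "exponential":
            return np.exp(-(depths - 1.0) / 2.0)
        raise ValueError(f"unknown weighting {weighting!r}")
    w = np.asarray(weighting, dtype=float)
    if w.shape != depths.shape:
        raise ValueError("weight vector length must match the number of edges")
    return w


def build_aem_basis(site_ids, edges, weighting="none", sv_tol: float = 1e-10) -> AemBasis:
    """Construct the AEM eigenfunction basis for a directed site tree.

    ``edges`` are (parent, child) pairs among sites; any site without a
    parent is attached directly to the origin, which is prepended upstream.
    Each site must be reached by exactly one directed path (cycles or
    multiple parents are rejected), so the graph is a tree rooted at the
    origin.  Columns of the (optionally weighted) site-by-edge matrix are
    centered and decomposed by SVD; eigenfunctions with singular values
    above ``sv_tol`` are retained.
    """
    sites = list(site_ids)
    if len(sites) != len(set(sites)):
        raise ValueError("duplicate site ids")
    site_set = set(sites)
    parent: dict = {}
    for u, v in edges:
        if v in parent:
            raise ValueError(f"site {v!r} has more than one incoming edge")
        if v not in site_set or (u not in site_set and u != ORIGIN):
            raise ValueError(f"edge ({u!r}, {v!r}) references unknown site")
        parent[v] = u
    full_edges = []
    for s in sites:
        if s not in parent:
            parent[s] = ORIGIN
    # deterministic edge order: walk sites in given order, parents first
    depth: dict = {ORIGIN: 0}
    edge_index: dict = {}

    def resolve(site, trail=()):
        if site in depth:
            return depth[site]
        if site in trail:
            raise ValueError("directed site graph contains a cycle")
        d = resolve(parent[site], trail + (site,)) + 1
        depth[site] = d
        return d

    for s in sites:
        resolve(s)
    for s in sorted(sites, key=lambda s: (depth[s], sites.index(s))):
        e = (parent[s], s)
        edge_index[e] = len(full_edges)
        full_edges.append(e)

    n, m = len(sites), len(full_edges)
    e_mat = np.zeros((n, m))
    for i, s in enumerate(sites):
        node = s
        while node != ORIGIN:
            e_mat[i, edge_index[(parent[node], node)]] = 1.0
            node = parent[node]

    depths = np.array([depth[v] for _, v in full_edges], dtype=float)
    w = _edge_weights(depths, weighting)
    centered = _center(e_mat * w[None, :])
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = s > sv_tol
    u, s = u[:, keep], s[keep]
    eig = pd.DataFrame(u, index=sites, columns=[f"AEM{i + 1}" for i in range(u.shape[1])])
    return AemBasis(
        site_ids=tuple(sites),
        edges=tuple(full_edges),
        incidence=pd.DataFrame(e_mat, index=sites,
                               columns=[f"E{i + 1}" for i in range(m)]),
        weights=w,
        eigenfunctions=eig,
        singular_values=s,
    )


def sample_eigenfunctions(basis: AemBasis, site_of_sample) -> pd.DataFrame:
    """Expand site-level eigenfunctions to sample rows.

    Replicate dissections taken at the same site share that site's row.
    """
    sites = list(site_of_sample)
    unknown = set(sites) - set(basis.site_ids)
    if unknown:
        raise KeyError(f"samples reference unknown sites: {sorted(unknown)[:5]}")
    return basis.eigenfunctions.loc[sites].reset_index(drop=True)


def hellinger(counts: pd.DataFrame) -> np.ndarray:
    """Hellinger transform (square root of relative abundance), samples x taxa.

    ``counts`` is features x samples, the package's table orientation.
    """
    x = counts.to_numpy(dtype=float).T
    sums = x.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("samples with zero total count")
    return np.sqrt(x / sums)


# ---------------------------------------------------------------------------
# forward selection with the double stopping criterion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    selected: tuple               # candidate column names, in selection order
    trace: pd.DataFrame           # step, candidate, r2, adj_r2, pvalue, accepted
    r2: float
    adj_r2: float
    global_r2: float
    global_adj_r2: float
    global_pvalue: float


def _perm_r2(y: np.ndarray, q: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """R^2-proportional fit statistics of row-permuted ``y`` on basis ``q``."""
    out = np.empty(n_perm)
    n = y.shape[0]
    for i in range(n_perm):
        perm = rng.permutation(n)
        out[i] = np.sum((q.T @ y[perm]) ** 2)
    return out


def _orthonormal(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(_center(x))
    diag = np.abs(np.diag(r))
    return q[:, diag > 1e-10 * max(diag.max(), 1e-300)]


def forward_select(
    y,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    cap_tolerance: float = 1e-3,
) -> SelectionResult:
    """Forward selection of spatial eigenfunctions in a redundancy analysis.

    Implements the double stopping criterion: the full candidate model is
    first tested globally by permutation and selection proceeds only if it is
    significant at ``alpha``; candidates are then added greedily (largest
    gain in R^2), each gated by a residual-permutation partial test at
    ``alpha`` *and* by the requirement that the cumulative adjusted R^2 not
    exceed that of the global model.  This protocol keeps the family-wise
    type-I error of selecting any eigenfunction near ``alpha``.

    ``cap_tolerance`` loosens the adjusted-R^2 ceiling slightly: with a
    near-noise-free response a one-term model's adjusted R^2 can exceed the
    full model's by a sliver of the degrees-of-freedom correction, and a
    strict ceiling would reject the perfect candidate.
    """
    if candidates.shape[1] == 0:
        raise ValueError("no candidate eigenfunctions")
    yc = _center(np.asarray(y, dtype=float))
    n = yc.shape[0]
    if candidates.shape[0] != n:
        raise ValueError("candidates must align with the response rows")
    names = list(candidates.columns)
    xall = candidates.to_numpy(dtype=float)
    ss_total = float(np.sum(yc**2))
    if ss_total == 0:
        raise ValueError("response has zero variance")

    rng = substream(seed, "forward_select")
    q_all = _orthonormal(xall)
    k = q_all.shape[1]
    global_r2 = float(np.sum((q_all.T @ yc) ** 2)) / ss_total
    global_adj = _adjust(global_r2, n, k)
    null = _perm_r2(yc, q_all, n_perm, rng) / ss_total
    global_p = (np.sum(null >= global_r2) + 1.0) / (n_perm + 1.0)

    trace_rows: list[dict] = []
    selected: list[str] = []
    if alpha <= 0 or global_p > alpha:
        return SelectionResult(
            selected=(), trace=pd.DataFrame(trace_rows), r2=0.0, adj_r2=0.0,
            global_r2=global_r2, global_adj_r2=global_adj, global_pvalue=global_p,
        )

    remaining = list(names)
    current_r2 = 0.0
    while remaining:
        q_cur = (
            _orthonormal(candidates[selected].to_numpy(float))
            if selected
            else np.zeros((n, 0))
        )
        y_res = yc - q_cur @ (q_cur.T @ yc)
        ss_res = float(np.sum(y_res**2))
        # residualised, normalised candidate vectors
        best, best_gain, best_q = None, -np.inf, None
        for name in remaining:
            c = _center(candidates[[name]].to_numpy(float))
            c = c - q_cur @ (q_cur.T @ c)
            norm = np.linalg.norm(c)
            if norm < 1e-12:
                continue
            qc = c / norm
            gain = float(np.sum((qc.T @ y_res) ** 2))
            if gain > best_gain:
                best, best_gain, best_q = name, gain, qc
        if best is None:
            break
        new_r2 = current_r2 + best_gain / ss_total
        m_new = len(selected) + 1
        adj_new = _adjust(new_r2, n, m_new)
        null_gain = _perm_r2(y_res, best_q, n_perm, rng)
        pvalue = (np.sum(null_gain >= best_gain) + 1.0) / (n_perm + 1.0)
        accepted = pvalue <= alpha and adj_new <= global_adj + cap_tolerance
        trace_rows.append(
            {"step": len(trace_rows) + 1, "candidate": best, "r2": new_r2,
             "adj_r2": adj_new, "pvalue": pvalue, "accepted": accepted}
        )
        if not accepted:
            break
        selected.append(best)
        remaining.remove(best)
        current_r2 = new_r2

    adj = _adjust(current_r2, n, len(selected)) if selected else 0.0
    return SelectionResult(
        selected=tuple(selected),
        trace=pd.DataFrame(trace_rows),
        r2=current_r2,
        adj_r2=adj,
        global_r2=global_r2,
        global_adj_r2=global_adj,
        global_pvalue=global_p,
    )


# ---------------------------------------------------------------------------
# direction comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionComparison:
    per_hypothesis: dict          # label -> {selected, adj_r2, pvalue, ...}
    verdict: str                  # hypothesis label or "ambiguous"
    alpha: float
    delta: float

    def summary(self) -> pd.DataFrame:
        rows = [
            {"hypothesis": k, "n_selected": len(v["selected"]),
             "adj_r2": v["adj_r2"], "pvalue": v["pvalue"]}
            for k, v in self.per_hypothesis.items()
        ]
        return pd.DataFrame(rows)


AMBIGUOUS = "ambiguous"


def compare_directions(
    y,
    site_of_sample,
    hypotheses: dict,
    alpha: float = 0.05,
    n_perm: int = 999,
    delta: float = 0.02,
    seed: int = 0,
    weighting: str = "exponential",
) -> DirectionComparison:
    """Compare directional hypotheses for net influence on composition.

    ``hypotheses`` maps labels to ``(site_ids, edges)`` tuples over the same
    site set.  For each hypothesis the AEM basis is built (edge weights
    decaying with distance from the origin, which is what makes opposing
    bases distinguishable on a symmetric transect) and eigenfunctions are
    forward-selected against the (typically Hellinger-transformed)
    response.

    Because opposing AEM bases over the same sites span the same full
    site space, the *complete* selected models converge to the same fit;
    the directional signature is efficiency, not endpoint.  Hypotheses are
    therefore compared at matched model size: with k the smallest number of
    eigenfunctions selected under any non-empty hypothesis, each
    hypothesis's first k selected eigenfunctions form its comparison model,
    which is scored by adjusted R^2 and tested globally by permutation.
    The verdict names the hypothesis with the larger matched-size adjusted
    R^2 when that model is significant at ``alpha`` and beats every
    competitor by more than ``delta`` adjusted-R^2 units; otherwise the
    comparison is declared ambiguous (consistent with bidirectional
    exchange).
    """
    if len(hypotheses) < 2:
        raise ValueError("need at least two direction hypotheses to compare")
    site_sets = {k: frozenset(v[0]) for k, v in hypotheses.items()}
    if len(set(site_sets.values())) != 1:
        raise ValueError("hypotheses must cover the same site set")

    yc = _center(np.asarray(y, dtype=float))
    ss_total = float(np.sum(yc**2))
    n = yc.shape[0]
    selections: dict[str, tuple] = {}
    eigs: dict[str, pd.DataFrame] = {}
    results: dict[str, dict] = {}
    for label, (site_ids, edges) in hypotheses.items():
        basis = build_aem_basis(site_ids, edges, weighting=weighting)
        x = sample_eigenfunctions(basis, site_of_sample)
        sel = forward_select(
            y, x, alpha=alpha, n_perm=n_perm,
            seed=int(substream(seed, "compare", label).integers(2**31)),
        )
        selections[label], eigs[label] = sel, x
        results[label] = {
            "selected": sel.selected,
            "global_pvalue": sel.global_pvalue,
            "global_adj_r2": sel.global_adj_r2,
        }

    sizes = [len(s.selected) for s in selections.values() if s.selected]
    k = min(sizes) if sizes else 0
    for label, sel in selections.items():
        if sel.selected and k > 0:
            model = list(sel.selected[:k])
            q = _orthonormal(eigs[label][model].to_numpy(float))
            obs = float(np.sum((q.T @ yc) ** 2))
            adj_r2 = _adjust(obs / ss_total, n, q.shape[1])
            rng = substream(seed, "compare_global", label)
            null = _perm_r2(yc, q, n_perm, rng)
            pvalue = (np.sum(null >= obs) + 1.0) / (n_perm + 1.0)
        else:
            model, adj_r2, pvalue = [], 0.0, 1.0
        results[label].update(
            comparison_model=tuple(model), adj_r2=float(adj_r2), pvalue=float(pvalue)
        )

    ordered = sorted(results, key=lambda lbl: results[lbl]["adj_r2"], reverse=True)
    best, runner = ordered[0], ordered[1]
    margin = results[best]["adj_r2"] - results[runner]["adj_r2"]
    if results[best]["pvalue"] <= alpha and margin > delta:
        verdict = best
    else:
        verdict = AMBIGUOUS
    return DirectionComparison(
        per_hypothesis=results, verdict=verdict, alpha=alpha, delta=delta
    )
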