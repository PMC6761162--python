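"""Alpha diversity, Bray-Curtis dissimilarity, stool-similarity profiles,
block-axis interpolation and the group-comparison statistics used throughout
the pipeline.

Conventions: Shannon entropy is reported in nats (natural log), richness is
the number of features with non-zero counts, and Bray-Curtis follows
``sum |x - y| / sum (x + y)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "richness",
    "shannon",
    "alpha_diversity_table",
    "bray_curtis",
    "validate_distance_matrix",
    "similarity_to_reference",
    "grid_interpolate",
    "group_compare",
    "GroupTestResult",
]


def richness(counts) -> int:
    """Number of features with count > 0 in one sample."""
    x = np.asarray(counts)
    if x.sum() < 1:
        raise ValueError("empty sample")
    return int(np.sum(x > 0))


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p of one sample, in nats."""
    x = np.asarray(counts, dtype=float)
    n = x.sum()
    if n < 1:
        raise ValueError("empty sample")
    p = x[x > 0] / n
    return float(-np.sum(p * np.log(p)))


def alpha_diversity_table(table, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample richness and Shannon diversity, joined to sample metadata."""
    rows = {
        s: (richness(table.counts[s]), shannon(table.counts[s]))
        for s in table.sample_ids
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["richness", "shannon"])
    out.index.name = "sample_id"
    if metadata is not None:
        out = out.join(metadata, how="left")
    return out


def bray_curtis(table) -> pd.DataFrame:
    """Square Bray-Curtis dissimilarity matrix over the table's samples."""
    x = table.counts.to_numpy().T.astype(float)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    if np.any(x.sum(axis=1) == 0):
        raise ValueError("samples with zero total count")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def validate_distance_matrix(d: pd.DataFrame, atol: float = 1e-9) -> None:
    a = d.to_numpy()
    if a.shape[0] != a.shape[1] or not d.index.equals(d.columns):
        raise ValueError("distance matrix must be square with matching ids")
    if not np.allclose(a, a.T, atol=atol):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=atol):
        raise ValueError("distance matrix must have a zero diagonal")


def similarity_to_reference(
    table, metadata: pd.DataFrame, reference_type: str = "stool"
) -> pd.DataFrame:
    """Bray-Curtis distance of each dissected sample to its own mouse's
    reference sample (stool by default).

    Distances are computed within mouse only, on relative abundances so that
    libraries rarefied to different depths (stool vs. dissections) remain
    comparable.  Returns one row per non-reference sample with its spatial
    coordinates (block, compartment) attached.
    """
    md = metadata.loc[list(table.sample_ids)]
    rel = table.relative_abundance()
    rows = []
    for mouse, sub in md.groupby("mouse"):
        refs = sub.index[sub["sample_type"] == reference_type]
        if len(refs) == 0:
            raise ValueError(f"mouse {mouse!r} has no {reference_type} reference sample")
        ref_vec = rel[list(refs)].mean(axis=1).to_numpy()
        others = sub.index[sub["sample_type"] != reference_type]
        for s in others:
            v = rel[s].to_numpy()
            denom = np.sum(v + ref_vec)
            dist = float(np.sum(np.abs(v - ref_vec)) / denom) if denom > 0 else 0.0
            rows.append(
                {
                    "sample_id": s,
                    "mouse": mouse,
                    "block": sub.loc[s, "block"],
                    "compartment": sub.loc[s, "compartment"],
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def grid_interpolate(
    values: pd.Series, blocks: pd.Series, compartments: pd.Series, resolution: int = 50
) -> pd.DataFrame:
    """Linearly interpolate per-(block, compartment) means along the block axis.

    The longitudinal coordinate (block 1..7) is continuous enough to smooth;
    the lateral coordinate (mucus/lumen) is categorical, so compartments are
    kept as separate rows.  Returns a DataFrame with one row per compartment
    and ``resolution`` columns spanning the observed block range.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "block": np.asarray(blocks),
         "compartment": np.asarray(compartments)}
    ).dropna(subset=["value"])
    if df.empty:
        raise ValueError("all values missing")
    means = df.groupby(["compartment", "block"])["value"].mean()
    lo, hi = df["block"].min(), df["block"].max()
    if lo == hi:
        raise ValueError("need at least two distinct blocks")
    grid = np.linspace(lo, hi, int(resolution))
    out = {}
    for comp in sorted(df["compartment"].unique()):
        sub = means.loc[comp]
        out[comp] = np.interp(grid, sub.index.to_numpy(float), sub.to_numpy(float))
    return pd.DataFrame(out, index=grid).T


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus test plus FDR-adjusted pairwise post-hoc table."""

    method: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None
    group_sizes: dict

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.posthoc is None:
            return pd.DataFrame()
        return self.posthoc[self.posthoc["p_adjusted"] <= alpha]


def _dunn_posthoc(samples: dict) -> pd.DataFrame:
    """Dunn's z-tests on rank sums after a Kruskal-Wallis omnibus test."""
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction factor for the rank-variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    ties = np.sum(tie_counts**3 - tie_counts)
    tie_term = ties / (12.0 * (n - 1)) if n > 1 else 0.0
    offsets = np.cumsum([0] + [len(samples[g]) for g in labels])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(labels)
    }
    rows = []
    for a, b in combinations(labels, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "statistic": z, "p_raw": min(p, 1.0)})
    return pd.DataFrame(rows)


def _tukey_posthoc(samples: dict) -> pd.DataFrame:
    labels = list(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance data yields NaN stats
        res = stats.tukey_hsd(*[samples[g] for g in labels])
    rows = []
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            stat, p = float(res.statistic[i, j]), float(res.pvalue[i, j])
            if np.isnan(p):  # degenerate (constant) data: no evidence
                stat, p = 0.0, 1.0
            rows.append({"group1": a, "group2": b, "statistic": stat, "p_raw": p})
    return pd.DataFrame(rows)


def group_compare(
    values,
    groups,
    method: str = "auto",
    paired_key=None,
    normality_alpha: float = 0.05,
) -> GroupTestResult:
    """Compare a response across groups with the study's testing scheme.

    ``method='auto'`` runs one-way ANOVA with Tukey post-hoc tests when every
    group passes a Shapiro-Wilk normality check (alpha 0.05), and falls back
    to Kruskal-Wallis with Dunn post-hoc tests otherwise.  Post-hoc p-values
    are Benjamini-Hochberg adjusted within the pairwise family.  With
    ``paired_key`` and exactly two groups a paired t-test on matched
    observations is run instead (no post-hoc table).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must align")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {g: values[groups == g] for g in labels}

    if paired_key is not None:
        if len(labels) != 2:
            raise ValueError("paired comparison requires exactly two groups")
        key = np.asarray(paired_key)
        a = pd.Series(values[groups == labels[0]], index=key[groups == labels[0]])
        b = pd.Series(values[groups == labels[1]], index=key[groups == labels[1]])
        common = a.index.intersection(b.index)
        if len(common) < 2 or len(common) != len(a) or len(common) != len(b):
            raise ValueError("paired mode requires fully matched pairs")
        t, p = stats.ttest_rel(a.loc[common], b.loc[common])
        return GroupTestResult(
            method="paired_t",
            statistic=float(t),
            pvalue=float(p),
            posthoc=None,
            group_sizes={g: int(len(samples[g])) for g in labels},
        )

    for g in labels:
        if len(samples[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")

    if method == "auto":
        normal = True
        for g in labels:
            x = samples[g]
            if len(x) < 3 or np.ptp(x) == 0:
                continue  # Shapiro needs n >= 3 and non-constant data
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if stats.shapiro(x).pvalue < normality_alpha:
                    normal = False
                    break
        method = "anova" if normal else "kruskal"

    if method == "anova":
        grand = values.mean()
        ss_between = sum(len(samples[g]) * (samples[g].mean() - grand) ** 2 for g in labels)
        if ss_between == 0:
            statistic, pvalue = 0.0, 1.0
        else:
            statistic, pvalue = stats.f_oneway(*[samples[g] for g in labels])
        posthoc = _tukey_posthoc(samples)
    elif method == "kruskal":
        try:
            statistic, pvalue = stats.kruskal(*[samples[g] for g in labels])
        except ValueError:  # all values identical
            statistic, pvalue = 0.0, 1.0
        posthoc = _dunn_posthoc(samples)
    else:
        raise ValueError(f"unknown method {method!r}")

    posthoc["p_adjusted"] = stats.false_discovery_control(
        posthoc["p_raw"].to_numpy(), method="bh"
    )
    posthoc["test"] = "tukey" if method == "anova" else "dunn"
    return GroupTestResult(
        method=method,
        statistic=float(statistic),
        pvalue=float(pvalue),
        posthoc=posthoc,
        group_sizes={g: int(len(samples[g])) for g in labels},
    )
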