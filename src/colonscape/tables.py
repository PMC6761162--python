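"""ASV count-table container, I/O and quality control.

The unit of analysis is an integer count matrix of amplicon sequence
variants (features, rows) by samples (columns).  Laser-capture dissections
yield very low-biomass samples, so quality control revolves around three
steps: identifying reagent contaminants by their enrichment in negative
controls, removing them, and subsampling libraries to a common depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

__all__ = [
    "AsvTable",
    "ContaminantReport",
    "read_table",
    "write_table",
    "prevalence_contaminant_test",
    "remove_features",
    "rarefy",
    "goods_coverage",
]


@dataclass(frozen=True)
class AsvTable:
    """Non-negative integer count matrix, features x samples.

    ``counts`` is a pandas DataFrame whose index holds feature identifiers
    and whose columns hold sample identifiers.  Both axes must be unique and
    all entries must be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if not isinstance(c, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        if c.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if c.size:
            values = c.to_numpy()
            if not np.issubdtype(values.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(values < 0):
                raise ValueError("negative counts")
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("non-integer counts")
        object.__setattr__(self, "counts", c.astype(np.int64))

    # -- convenience accessors -------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> pd.Series:
        """Library size per sample."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Columns scaled to sum to one (columns with zero sum stay zero)."""
        sums = self.counts.sum(axis=0).replace(0, np.nan)
        return (self.counts / sums).fillna(0.0)

    def select_samples(self, sample_ids) -> "AsvTable":
        return AsvTable(self.counts.loc[:, list(sample_ids)])


def read_table(path) -> AsvTable:
    """Read a feature table from TSV (first column ``feature_id``)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    try:
        frame = frame.astype(np.int64)
    except ValueError as exc:  # non-numeric or float-with-fraction cells
        raise ValueError(f"count table at {path} has non-integer entries") from exc
    frame.index.name = None
    return AsvTable(frame)


def write_table(table: AsvTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ContaminantReport:
    """Per-feature output of the prevalence-based contaminant test.

    ``frame`` has one row per feature with columns ``prevalence_control``,
    ``prevalence_true`` (presence fractions), ``n_present_control``,
    ``score`` (one-sided exact tail probability) and ``is_contaminant``.
    """

    frame: pd.DataFrame
    threshold: float
    contaminant_ids: pd.Index = field(init=False)

    def __post_init__(self) -> None:
        flagged = self.frame.index[self.frame["is_contaminant"]]
        object.__setattr__(self, "contaminant_ids", flagged)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "feature_id"
        out.to_csv(path)


def prevalence_contaminant_test(
    table: AsvTable, is_control, threshold: float = 0.1
) -> ContaminantReport:
    """Flag reagent contaminants by their prevalence in negative controls.

    For each feature a 2x2 presence table (control vs. true sample, present
    vs. absent, presence meaning count > 0) is summarised by the one-sided
    exact hypergeometric tail probability of observing at least as many
    control samples containing the feature, given its overall prevalence.
    Features whose score falls below ``threshold`` (default 0.1) are flagged.

    The exact test is preferred over a chi-squared approximation because
    dissection studies typically carry only a handful of controls.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    flags = np.asarray(is_control, dtype=bool)
    if flags.shape[0] != table.shape[1]:
        raise ValueError("is_control length must match the number of samples")
    n_control = int(flags.sum())
    n_true = int((~flags).sum())
    if n_control == 0 or n_true == 0:
        raise ValueError("need at least one control and one true sample")

    present = table.counts.to_numpy() > 0
    k_control = present[:, flags].sum(axis=1)
    k_true = present[:, ~flags].sum(axis=1)
    k_total = k_control + k_true
    n_total = n_control + n_true

    # P(X >= k_control) for X ~ Hypergeom(N=n_total, K=k_total, n=n_control)
    score = stats.hypergeom.sf(k_control - 1, n_total, k_total, n_control)
    score = np.clip(score, 0.0, 1.0)
    flagged = score < threshold

    frame = pd.DataFrame(
        {
            "prevalence_control": k_control / n_control,
            "prevalence_true": k_true / n_true,
            "n_present_control": k_control,
            "n_present_true": k_true,
            "score": score,
            "is_contaminant": flagged,
        },
        index=table.feature_ids,
    )
    return ContaminantReport(frame=frame, threshold=float(threshold))


def remove_features(table: AsvTable, feature_ids) -> tuple[AsvTable, pd.Series]:
    """Drop ``feature_ids`` from the table.

    Returns the filtered table and, per sample, the fraction of reads that
    the removed features carried.
    """
    ids = pd.Index(feature_ids)
    unknown = ids.difference(table.feature_ids)
    if len(unknown):
        raise KeyError(f"unknown feature ids: {list(unknown[:5])}")
    removed = table.counts.loc[ids]
    totals = table.counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        removed_fraction = (removed.sum(axis=0) / totals).fillna(0.0)
    kept = table.counts.drop(index=ids)
    return AsvTable(kept), removed_fraction.rename("removed_read_fraction")


def rarefy(table: AsvTable, depth: int, seed: int) -> tuple[AsvTable, list]:
    """Subsample every library to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads cannot be subsampled and are
    dropped; their ids are returned alongside the rarefied table.  A single
    seeded draw is used per sample (no averaging over repeated draws) so that
    downstream analyses stay deterministic.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.sample_sums()
    keep = sums.index[sums >= depth]
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    out = {}
    for sample in keep:
        col = table.counts[sample].to_numpy()
        if col.sum() == depth:
            out[sample] = col
        else:
            rng = substream(seed, "rarefy", str(sample))
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    frame = pd.DataFrame(out, index=table.feature_ids, columns=keep)
    if frame.empty:
        frame = pd.DataFrame(index=table.feature_ids, columns=keep, dtype=np.int64)
    return AsvTable(frame.fillna(0).astype(np.int64)), dropped


def goods_coverage(counts) -> float:
    """Good's coverage 1 - f1/N of a single sample.

    ``f1`` is the number of features observed exactly once and ``N`` the
    library size; the statistic estimates the fraction of the community
    captured by the library.
    """
    x = np.asarray(counts)
    n = x.sum()
    if n < 1:
        raise ValueError("empty sample")
    f1 = int(np.sum(x == 1))
    return 1.0 - f1 / float(n)
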