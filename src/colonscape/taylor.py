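"""Taylor's power-law quantification of spatial patchiness.

Taylor's law relates the variance of a taxon's abundance across sampling
sites to its mean, v = a * m^b; on a log-log plot the taxa of a community
fall on a line whose slope b measures aggregation.  b = 1 corresponds to
Poisson (random) placement, b approaching 2 to strongly patchy, clumped
distributions.  Fits are computed per stratum (by default per mouse and
compartment) on rarefied counts, since the law is defined on numbers of
individuals per unit area rather than on relative abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TaylorFit", "taylor_fit", "taylor_by_stratum"]


@dataclass(frozen=True)
class TaylorFit:
    slope: float            # b in v = a * m^b
    intercept: float        # log10(a)
    r2: float
    n_taxa: int
    n_sites: int
    stratum: str


def taylor_fit(counts: pd.DataFrame, min_prevalence: int = 3, stratum: str = "") -> TaylorFit:
    """Fit Taylor's power law across the taxa of one stratum.

    ``counts`` is features x sampling sites (the stratum's samples).  For
    every taxon present in at least ``min_prevalence`` sites, the mean and
    variance of its counts across sites are computed; ordinary least squares
    of log10 variance on log10 mean over taxa with positive mean and
    variance yields the slope.  Zero-variance taxa have no defined log
    variance and are excluded (reflected in ``n_taxa``).
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("a stratum needs at least three sampling sites")
    prevalence = (x > 0).sum(axis=1)
    x = x[prevalence >= min_prevalence]
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    ok = (m > 0) & (v > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than three usable taxa for the Taylor fit")
    res = stats.linregress(np.log10(m[ok]), np.log10(v[ok]))
    return TaylorFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_taxa=int(ok.sum()),
        n_sites=int(counts.shape[1]),
        stratum=stratum,
    )


def taylor_by_stratum(
    table,
    metadata: pd.DataFrame,
    stratum_keys: tuple = ("mouse", "compartment"),
    min_prevalence: int = 3,
    sample_type: str | None = "lcm",
) -> pd.DataFrame:
    """One Taylor fit per stratum, e.g. per mouse x compartment.

    Strata that do not meet the fit preconditions are skipped with a
    warning.  Returns a DataFrame with the stratum keys, slope, intercept,
    r2 and taxon/site bookkeeping; slope comparisons across compartments or
    diets are done downstream with :func:`colonscape.diversity.group_compare`.
    """
    md = metadata.loc[list(table.sample_ids)]
    if sample_type is not None and "sample_type" in md:
        md = md[md["sample_type"] == sample_type]
    rows = []
    for key, sub in md.groupby(list(stratum_keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key)
        stratum_counts = table.counts[list(sub.index)]
        try:
            fit = taylor_fit(stratum_counts, min_prevalence=min_prevalence, stratum=label)
        except ValueError as exc:
            warnings.warn(f"skipping stratum {label}: {exc}", stacklevel=2)
            continue
        row = dict(zip(stratum_keys, key))
        row.update(
            slope=fit.slope, intercept=fit.intercept, r2=fit.r2,
            n_taxa=fit.n_taxa, n_sites=fit.n_sites, stratum=label,
        )
        rows.append(row)
    if not rows:
        raise ValueError("no stratum met the Taylor-fit preconditions")
    return pd.DataFrame(rows)
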