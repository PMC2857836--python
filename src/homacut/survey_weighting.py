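"""Census post-stratification weights and weighted summary statistics.

The survey sample is reweighted so that its age-decade x sex composition
matches known census population shares: the weight of every subject in
stratum *s* is proportional to (census share of s) / (sample share of s),
rescaled to average 1 over the cohort so weighted and unweighted sample
sizes stay comparable.

Weighted estimators are closed-form: mean with an effective-sample-size SEM
(n_eff = (sum w)^2 / sum w^2, a reliability-weight approximation rather
than a design-based complex-survey variance), prevalence, product-moment
correlation, and an interpolated weighted percentile (a Hyndman-Fan type-7
generalization; tied values are aggregated, so integer weights are exactly
equivalent to repeating observations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
    NamedColumnError,
)

#: Age-decade bands (inclusive bounds, years) of the survey population.
AGE_BANDS: tuple[tuple[int, int], ...] = ((25, 34), (35, 44), (45, 54), (55, 64))

#: Default census table: adult (25-64) age-decade x sex population shares
#: patterned on the 2006 national census of Iran (young-skewed pyramid,
#: near-even sex ratio). Synthetic working values, not transcribed census
#: microdata.
DEFAULT_CENSUS_ROWS: tuple[tuple[str, str, float], ...] = (
    ("25-34", "male", 0.1805),
    ("25-34", "female", 0.1820),
    ("35-44", "male", 0.1350),
    ("35-44", "female", 0.1365),
    ("45-54", "male", 0.1025),
    ("45-54", "female", 0.1040),
    ("55-64", "male", 0.0795),
    ("55-64", "female", 0.0800),
)


def age_band(age) -> np.ndarray:
    """Map ages (years) to decade-band labels like '25-34'. Vectorized."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    out = np.full(age.shape, "", dtype=object)
    for lo, hi in AGE_BANDS:
        out[(age >= lo) & (age <= hi)] = f"{lo}-{hi}"
    return out


@dataclass(frozen=True)
class CensusStrata:
    """Census age-band x sex population shares.

    ``table`` has columns age_band, sex, proportion; proportions must be
    strictly positive and sum to 1 within 1e-9.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            DEFAULT_CENSUS_ROWS, columns=["age_band", "sex", "proportion"]
        )
    )

    def __post_init__(self):
        t = self.table
        for col in ("age_band", "sex", "proportion"):
            if col not in t.columns:
                raise NamedColumnError(f"census table lacks column {col!r}")
        p = t["proportion"].to_numpy(dtype=float)
        if not (p > 0).all():
            raise InvalidArgumentError("census proportions must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"census proportions must sum to 1, got {p.sum():.12f}"
            )
        if t.duplicated(["age_band", "sex"]).any():
            raise InvalidArgumentError("duplicate census strata")

    @classmethod
    def from_file(cls, path, sep: str | None = None) -> "CensusStrata":
        if sep is None:
            with open(path, "r", encoding="utf-8") as fh:
                sep = "\t" if "\t" in fh.readline() else ","
        return cls(pd.read_csv(path, sep=sep))

    def labels(self) -> pd.Series:
        """'band/sex' label per census stratum, aligned with proportions."""
        return self.table["age_band"].astype(str) + "/" + self.table["sex"].astype(str)


def stratum_labels(ages, sexes) -> np.ndarray:
    """'band/sex' label per subject."""
    bands = age_band(ages)
    sexes = np.atleast_1d(np.asarray(sexes, dtype=object))
    return np.array([f"{b}/{s}" for b, s in zip(bands, sexes)], dtype=object)


def poststratification_weights(
    cohort: pd.DataFrame, census: CensusStrata | None = None
) -> np.ndarray:
    """Post-stratification weights against census age x sex shares, mean 1.

    Every record must fall in a census stratum. A census stratum with no
    sampled member is dropped from the normalization with a warning.
    """
    census = census or CensusStrata()
    labels = stratum_labels(cohort["age"].to_numpy(), cohort["sex"].to_numpy())
    census_share = dict(zip(census.labels(), census.table["proportion"]))
    unknown = sorted(set(labels) - set(census_share))
    if unknown:
        raise InvalidArgumentError(f"records outside census strata: {unknown}")
    n = len(labels)
    counts = pd.Series(labels).value_counts()
    empty = sorted(set(census_share) - set(counts.index))
    if empty:
        warnings.warn(
            f"census strata absent from sample, omitted from normalization: {empty}",
            stacklevel=2,
        )
    ratio = {s: census_share[s] / (counts[s] / n) for s in counts.index}
    w = np.array([ratio[lab] for lab in labels], dtype=float)
    return w / w.mean()


# ---------------------------------------------------------------------------
# Weighted estimators


def _values_weights(values, weights):
    x = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise InvalidArgumentError("values and weights must be 1-D and equal length")
    if len(x) == 0:
        raise InsufficientDataError("empty sample")
    if not (w > 0).all():
        raise InvalidArgumentError("weights must be strictly positive")
    return x, w


def weighted_mean_sem(values, weights=None) -> tuple[float, float]:
    """Weighted mean and its standard error.

    SEM uses the weighted variance with Kish effective sample size
    n_eff = (sum w)^2 / sum w^2; with equal weights this is exactly the
    ordinary mean and s/sqrt(n).
    """
    x, w = _values_weights(values, weights)
    if len(x) < 2:
        raise InsufficientDataError("weighted_mean_sem needs n >= 2")
    sw = w.sum()
    mean = float(np.dot(w, x) / sw)
    neff = sw * sw / np.dot(w, w)
    var_pop = float(np.dot(w, (x - mean) ** 2) / sw)
    if neff <= 1:
        raise InsufficientDataError("effective sample size <= 1")
    var = var_pop * neff / (neff - 1.0)
    return mean, float(np.sqrt(var / neff))


def weighted_prevalence(labels, weights=None) -> float:
    """Weighted proportion of true labels."""
    lab = np.asarray(labels, dtype=bool).astype(float)
    x, w = _values_weights(lab, weights)
    return float(np.dot(w, x) / w.sum())


def weighted_percentile(values, weights=None, p=50.0):
    """Weighted percentile(s) by interpolation of the weighted empirical CDF.

    Count semantics, generalizing numpy's default linear-interpolation
    percentile: tied values are merged (weights summed) into distinct sorted
    values v_1 < ... < v_k with weights w_j and cumulative weights C_j; each
    value occupies the flat quantile block

        [(C_j - w_j) / (W - u),  (C_j - u) / (W - u)],   u = min_j w_j,

    with linear interpolation between consecutive blocks. With equal weights
    on tie-free data this reproduces ``numpy.percentile`` exactly; with
    integer weights it equals the same estimator applied to the expanded
    multiset (each value repeated weight times), and matches numpy on the
    expanded multiset whenever some weight equals 1. p may be scalar or
    array-like, in percent.
    """
    x, w = _values_weights(values, weights)
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p_arr < 0) | (p_arr > 100)) or np.any(~np.isfinite(p_arr)):
        raise InvalidArgumentError("percentile p must lie in [0, 100]")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    uniq, start = np.unique(xs, return_index=True)
    wagg = np.add.reduceat(ws, start)
    if len(uniq) == 1:
        out = np.full(p_arr.shape, uniq[0])
        return float(out[0]) if np.isscalar(p) or np.ndim(p) == 0 else out
    C = np.cumsum(wagg)
    W = C[-1]
    u = wagg.min()
    denom = W - u
    block_lo = (C - wagg) / denom
    block_hi = (C - u) / denom
    xp = np.empty(2 * len(uniq))
    xp[0::2] = block_lo
    xp[1::2] = block_hi
    fp = np.repeat(uniq, 2)
    out = np.interp(p_arr / 100.0, xp, fp)
    return float(out[0]) if np.isscalar(p) or np.ndim(p) == 0 else out


def weighted_pearson(x, y, weights=None) -> float:
    """Weighted product-moment correlation in [-1, 1].

    Requires n >= 3 and non-constant x and y. With equal weights this is the
    ordinary Pearson correlation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise InvalidArgumentError("x and y must have the same length")
    xv, w = _values_weights(xv, weights)
    if len(xv) < 3:
        raise InsufficientDataError("weighted_pearson needs n >= 3")
    sw = w.sum()
    mx = np.dot(w, xv) / sw
    my = np.dot(w, yv) / sw
    cov = np.dot(w, (xv - mx) * (yv - my)) / sw
    vx = np.dot(w, (xv - mx) ** 2) / sw
    vy = np.dot(w, (yv - my) ** 2) / sw
    if vx == 0 or vy == 0:
        raise DegenerateInputError("constant input has no defined correlation")
    return float(cov / np.sqrt(vx * vy))


def weighted_stratum_shares(cohort: pd.DataFrame, weights) -> pd.Series:
    """Weighted share of each sampled age x sex stratum (diagnostics).

    After post-stratification these reproduce the census proportions of the
    sampled strata (renormalized if any census stratum is unsampled).
    """
    labels = stratum_labels(cohort["age"].to_numpy(), cohort["sex"].to_numpy())
    w = np.asarray(weights, dtype=float)
    s = pd.Series(w).groupby(pd.Series(labels)).sum()
    return s / w.sum()
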