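"""Group summaries, two-group tests and least-squares regression.

Undefined values (NaN) are excluded from summaries and dropped pairwise in
regressions — a record missing one pool's value still contributes its
other pools.

The ``variable accessor`` convention used by :func:`resolve_variable`
names the per-(record, pool) quantities the regression screen and group
summaries can address:

- index names (``tex86``, ``ri1``, ``ri2``, ``methane_index``,
  ``pct_gdgt2``, ``ratio_2_3``, ``ratio_0_cren``, ``ratio_2_cren``,
  ``bit``) — taken from the record's stored index set for that pool, or
  computed from its stored profile;
- fractional abundances (``pct_g0`` .. ``pct_g4``, ``pct_cren``,
  ``pct_cren_iso``) — percent fields of the (normalized) profile;
- ``iso_conc`` — isoprenoid GDGT concentration for the pool (ng/L);
- ``gene_ratio`` — MG-II/total-archaea 16S copy ratio (pool-independent).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import indices as _ix
from .dataset import Dataset, SampleRecord, normalize_profile

__all__ = [
    "GroupSummary",
    "TTestResult",
    "RegressionResult",
    "gene_ratio",
    "resolve_variable",
    "group_summary",
    "welch_t_test",
    "ols_regression",
    "paired_station_correlation",
    "PROFILE_VARIABLES",
    "INDEX_VARIABLES",
]

INDEX_VARIABLES = (
    "tex86", "ri1", "ri2", "methane_index", "pct_gdgt2",
    "ratio_2_3", "ratio_0_cren", "ratio_2_cren", "bit",
)
PROFILE_VARIABLES = {
    "pct_g0": "g0", "pct_g1": "g1", "pct_g2": "g2", "pct_g3": "g3",
    "pct_g4": "g4", "pct_cren": "cren", "pct_cren_iso": "cren_iso",
}


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics of one variable."""

    group_key: tuple
    n: int
    mean: float
    sd: float  # sample SD (n-1); NaN when n < 2
    sd_pop: float  # population SD (n)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS fit of y on x with a two-sided slope t-test."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def gene_ratio(r: SampleRecord) -> float:
    """[MG-II 16S] / [Archaea 16S] copy ratio; NaN when unavailable.

    A ratio above 1 (MG-II copies exceeding total archaeal copies) is
    physically inconsistent but can arise from qPCR primer biases; it
    warns rather than errors.
    """
    if r.mgii_16s is None or r.archaea_16s is None or r.archaea_16s <= 0:
        return math.nan
    ratio = r.mgii_16s / r.archaea_16s
    if ratio > 1:
        warnings.warn(
            f"{r.sample_id}: MG-II 16S exceeds total archaeal 16S (ratio {ratio:.3g})",
            stacklevel=2,
        )
    return ratio


def resolve_variable(record: SampleRecord, variable: str, pool: str) -> float:
    """Value of a named variable for one record and pool; NaN if absent."""
    if variable == "gene_ratio":
        return gene_ratio(record)
    if variable in ("archaea_16s", "mgii_16s", "depth", "temperature", "salinity", "ph"):
        v = getattr(record, variable)
        return math.nan if v is None else float(v)
    if variable == "iso_conc":
        return record.iso_conc.get(pool, math.nan)
    if variable in PROFILE_VARIABLES:
        prof = record.profiles.get(pool)
        if prof is None:
            return math.nan
        return getattr(normalize_profile(prof), PROFILE_VARIABLES[variable])
    if variable in INDEX_VARIABLES:
        ix = record.indices.get(pool)
        if ix is not None and not math.isnan(getattr(ix, variable, math.nan)):
            return getattr(ix, variable)
        prof = record.profiles.get(pool)
        if prof is None:
            return math.nan
        b = record.br_profiles.get(pool)
        return getattr(_ix.compute_index_set(prof, b), variable)
    raise KeyError(f"unknown variable {variable!r}")


def group_summary(
    ds: Dataset,
    group_by: str | tuple[str, ...],
    variable: str,
    pool: str = "CL",
) -> list[GroupSummary]:
    """Mean and SD of a variable per metadata group.

    ``group_by`` names SampleRecord metadata attributes (e.g.
    ``"water_type"`` or ``("water_type", "station")``).  Records whose
    variable is undefined are excluded from that group's n; groups with no
    defined values are omitted (with a warning if that empties the
    result).
    """
    keys = (group_by,) if isinstance(group_by, str) else tuple(group_by)
    groups: dict[tuple, list[float]] = {}
    for r in ds:
        v = resolve_variable(r, variable, pool)
        if math.isnan(v):
            continue
        groups.setdefault(tuple(getattr(r, k) for k in keys), []).append(v)
    if not groups:
        warnings.warn(
            f"no defined values of {variable!r} [{pool}] in any group", stacklevel=2
        )
        return []
    out = []
    for key in sorted(groups):
        vals = np.asarray(groups[key], dtype=float)
        n = vals.size
        out.append(
            GroupSummary(
                group_key=key + (pool, variable),
                n=n,
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if n >= 2 else math.nan,
                sd_pop=float(vals.std(ddof=0)),
            )
        )
    return out


def welch_t_test(a, b) -> TTestResult:
    """Welch's unequal-variance two-sided t-test.

    ``equal_var=True`` recovers Student's pooled test for sensitivity
    checks via :func:`scipy.stats.ttest_ind` directly.  Degenerate
    zero-variance inputs short-circuit: equal means give (0, 1), unequal
    means give (±inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(a.size + b.size - 2), 1.0)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()),
                           float(a.size + b.size - 2), 0.0)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def ols_regression(x, y) -> RegressionResult:
    """OLS of y on x; R² and a two-sided t-test on the slope (n-2 df).

    Pairs with an undefined (NaN) member are dropped; requires >= 3
    complete pairs and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope is not identifiable")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=int(n),
    )


def paired_station_correlation(
    ds: Dataset,
    variable: str = "tex86",
    pool: str = "CL",
    pairing: str = "station-mean",
) -> tuple[RegressionResult, str]:
    """Regress sediment values on water-column (SPM) values per station.

    Pairing strategies:

    - ``station-mean``: each station's sediment value against the mean of
      its SPM values;
    - ``surface-only``: against the shallowest SPM sample only;
    - ``per-sample``: every SPM sample paired with its station's sediment
      value.

    Returns the fit and the strategy actually used (recorded so reported
    correlations are reproducible).
    """
    if pairing not in ("station-mean", "surface-only", "per-sample"):
        raise ValueError(f"unknown pairing strategy {pairing!r}")
    sed: dict[str, float] = {}
    spm: dict[str, list[tuple[float, float]]] = {}  # station -> [(depth, value)]
    for r in ds:
        v = resolve_variable(r, variable, pool)
        if math.isnan(v):
            continue
        if r.water_type == "sediment":
            sed[r.station] = v
        else:
            d = r.depth if r.depth is not None else math.inf
            spm.setdefault(r.station, []).append((d, v))
    xs, ys = [], []
    for station, sed_val in sed.items():
        if station not in spm:
            continue
        vals = spm[station]
        if pairing == "station-mean":
            xs.append(float(np.mean([v for _, v in vals])))
            ys.append(sed_val)
        elif pairing == "surface-only":
            xs.append(min(vals)[1])
            ys.append(sed_val)
        else:
            for _, v in vals:
                xs.append(v)
                ys.append(sed_val)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 SPM-sediment pairs, got {len(xs)}")
    return ols_regression(xs, ys), pairing
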