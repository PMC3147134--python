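"""Validation statistics for volumetry: percent error, stratified summaries
and interobserver agreement.

Measurement tables are plain pandas DataFrames with the columns

    object, config, method, operator, isocontour_pct, true_mL, measured_mL,
    error_pct

(`method` is ``spect`` or ``spect_ct``; ``error_pct`` may be NA when a
measurement failed).  Summaries average the *absolute* percent errors per
(operator, method, stratum), with strata defined on the true volume:
all objects, >= 16 mL, and >= 473 mL (both inclusive).

Interobserver agreement is reported as Bland-Altman bias and 95% limits of
agreement together with Lin's concordance correlation coefficient (CCC),
whose conventional qualitative bands are >= 0.8 excellent, 0.6-0.8 good,
0.4-0.6 poor, < 0.4 very poor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_STRATA",
    "AgreementResult",
    "percent_error",
    "summarize",
    "bland_altman",
    "lin_ccc",
]

#: (label, minimum true volume in mL) — inclusive lower bounds.
DEFAULT_STRATA = (("all", 0.0), (">=16 mL", 16.0), (">=473 mL", 473.0))


def percent_error(measured_mL: float, true_mL: float) -> float:
    """Signed percent error of a measured volume: 100 * (measured - true) / true."""
    if true_mL <= 0:
        raise ValueError("true volume must be > 0")
    return 100.0 * (measured_mL - true_mL) / true_mL


def summarize(records: pd.DataFrame, strata=DEFAULT_STRATA) -> pd.DataFrame:
    """Stratified mean +/- SD of absolute percent errors.

    One row per (operator, method, stratum): n, mean_abs_error_pct and the
    sample standard deviation (n-1 denominator; NaN when n == 1).  Records
    with missing ``error_pct`` are dropped (and logged); a stratum with no
    usable record is still emitted with n = 0 so it cannot vanish silently.
    """
    required = {"operator", "method", "true_mL", "error_pct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    n_na = int(records["error_pct"].isna().sum())
    if n_na:
        logger.info("summarize: dropping %d record(s) with missing error", n_na)
    usable = records.dropna(subset=["error_pct"])

    rows = []
    for (op, method), group in records.groupby(["operator", "method"], sort=True):
        g = usable[(usable["operator"] == op) & (usable["method"] == method)]
        for label, vmin in strata:
            errs = g.loc[g["true_mL"] >= vmin, "error_pct"].abs().to_numpy(float)
            n = errs.size
            if n == 0:
                logger.warning("summarize: empty stratum %r for operator=%s method=%s",
                               label, op, method)
            rows.append({
                "operator": op,
                "method": method,
                "stratum": label,
                "n": n,
                "mean_abs_error_pct": float(errs.mean()) if n else np.nan,
                "sd_abs_error_pct": float(errs.std(ddof=1)) if n > 1 else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman bias/limits plus Lin's concordance coefficient."""

    n: int
    bias: float
    loa_lower: float
    loa_upper: float
    concordance: float

    def __post_init__(self):
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")

    @property
    def band(self) -> str:
        c = self.concordance
        if c >= 0.8:
            return "excellent"
        if c >= 0.6:
            return "good"
        if c >= 0.4:
            return "poor"
        return "very poor"


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient of two paired samples.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), population moments.
    Symmetric in its arguments; equals 1 iff the pairs are identical.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D samples required")
    if np.array_equal(x, y):
        return 1.0
    mx, my = x.mean(), y.mean()
    sxy = np.mean((x - mx) * (y - my))
    denom = x.var() + y.var() + (mx - my) ** 2
    if denom == 0:
        return 0.0
    return float(2.0 * sxy / denom)


def bland_altman(op1: pd.Series, op2: pd.Series) -> AgreementResult:
    """Interobserver agreement between two operators' paired measurements.

    ``op1`` and ``op2`` are measured volumes indexed by object identity; the
    index sets must match (unpaired objects are reported in the error).
    Differences are operator1 - operator2; the limits of agreement are
    bias +/- 1.96 SD (sample SD) of the differences.
    """
    only1 = op1.index.difference(op2.index)
    only2 = op2.index.difference(op1.index)
    if len(only1) or len(only2):
        raise ValueError(
            f"mismatched object sets: only operator 1 has {list(only1)}; "
            f"only operator 2 has {list(only2)}"
        )
    op2 = op2.reindex(op1.index)
    mask = op1.notna() & op2.notna()
    x = op1[mask].to_numpy(float)
    y = op2[mask].to_numpy(float)
    if x.size < 3:
        raise ValueError("at least 3 complete pairs are required")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        n=int(x.size),
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        concordance=lin_ccc(x, y),
    )
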