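"""Agreement statistics: ICC, Bland–Altman, coefficient of variation.

The study design behind this package compares CBO index measurements
between two blinded raters and between four staining/microscopy
techniques on the same 21 samples. The statistics used for that
comparison are implemented here:

* the two-way random-effects ICC for **consistency**, **average
  measures** — ICC = (MS_R − MS_E)/MS_R from the two-way ANOVA without
  replication — with its F-based 95% confidence interval and one-sided
  p-value;
* Bland–Altman bias and limits of agreement at bias ± 2·SD of the
  paired differences (the ±2 convention, not 1.96);
* the coefficient of variation CV% = 100 · SEmeas / mean with
  SEmeas = s_pooled · sqrt(1 − ICC), the standard error of measurement
  consistent with an ICC-based reliability analysis;
* index histograms and a pairwise report table mirroring the two-rater
  and six-technique-pair layouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInput,
    LengthMismatch,
    TooFewPoints,
    TooFewSubjects,
    UnpairedSamples,
    ZeroMean,
    ZeroVariance,
)
from .io_config import logger


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RaterMatrix:
    """n samples × k raters/methods table of mean indices."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise LengthMismatch("rater matrix must be 2D")
        if np.isnan(v).any():
            raise UnpairedSamples("rater matrix has missing cells")
        if len(self.row_ids) != v.shape[0] or len(self.col_ids) != v.shape[1]:
            raise LengthMismatch("id lists do not match matrix shape")
        self.values = v

    @classmethod
    def from_array(cls, values: np.ndarray) -> "RaterMatrix":
        v = np.asarray(values, dtype=np.float64)
        return cls(
            values=v,
            row_ids=[f"s{i+1}" for i in range(v.shape[0])],
            col_ids=[f"r{j+1}" for j in range(v.shape[1])],
        )


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray  # per-point (x+y)/2, for plotting
    diffs: np.ndarray  # per-point x − y


@dataclass(frozen=True)
class CvResult:
    cv_percent: float
    se_meas: float
    grand_mean: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def icc_consistency_average(
    m: RaterMatrix | np.ndarray, alpha: float = 0.05
) -> IccResult:
    """Two-way random-effects ICC, consistency, average measures.

    From the two-way ANOVA without replication (rows = subjects,
    columns = raters): ICC = (MS_R − MS_E)/MS_R where MS_R is the
    between-subjects mean square and MS_E the residual mean square.
    F = MS_R/MS_E on (n−1, (n−1)(k−1)) df gives the one-sided p-value
    for H0: ICC = 0 and the CI [1 − 1/F_L, 1 − 1/F_U] with
    F_L = F / F_{α/2;df1,df2} and F_U = F · F_{α/2;df2,df1}.
    """
    if isinstance(m, np.ndarray):
        m = RaterMatrix.from_array(m)
    v = m.values
    n, k = v.shape
    if n < 2:
        raise TooFewSubjects(f"need ≥ 2 subjects, got {n}")
    if k < 2:
        raise TooFewSubjects(f"need ≥ 2 raters, got {k}")
    if n < 5:
        logger.warning("ICC computed on only %d subjects; CI will be very wide", n)
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((v - grand) ** 2).sum()
    # cancellation can leave a tiny negative residual for perfectly
    # consistent columns; clamp, and treat a negligible residual as exact
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    ms_r = ss_rows / df1
    ms_e = ss_err / df2
    if ms_r <= 0:
        raise ZeroVariance("between-subject mean square is zero")
    if ms_e <= 1e-12 * ms_r:
        # columns identical up to additive constants: perfect consistency
        return IccResult(
            icc=1.0, ci_low=1.0, ci_high=1.0,
            f_value=np.inf, df1=df1, df2=df2, p_value=np.nextafter(0.0, 1.0),
        )
    f = ms_r / ms_e
    icc = (ms_r - ms_e) / ms_r
    p = float(stats.f.sf(f, df1, df2))
    fl = f / stats.f.isf(alpha / 2.0, df1, df2)
    fu = f * stats.f.isf(alpha / 2.0, df2, df1)
    return IccResult(
        icc=float(icc),
        ci_low=float(1.0 - 1.0 / fl),
        ci_high=float(1.0 - 1.0 / fu),
        f_value=float(f),
        df1=df1,
        df2=df2,
        p_value=max(p, np.nextafter(0.0, 1.0)),
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias and ±2 SD limits of agreement of paired measurements.

    ``d_i = x_i − y_i``; bias = mean(d); sd_diff is the sample standard
    deviation (n − 1); limits are bias ± 2·sd_diff — the interval
    expected to contain ≈95% of differences for Gaussian d.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise LengthMismatch(f"paired series differ: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise TooFewPoints("need ≥ 2 paired points")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 2.0 * sd,
        loa_high=bias + 2.0 * sd,
        n=int(x.size),
        means=(x + y) / 2.0,
        diffs=d,
    )


def coefficient_of_variation(m: RaterMatrix | np.ndarray) -> CvResult:
    """CV% = 100 · SEmeas / grand mean, with SEmeas = s_pooled·√(1 − ICC).

    ``s_pooled`` is the standard deviation of all n·k values; the ICC is
    the consistency/average-measures ICC of the same matrix. CV is
    invariant to scaling the whole matrix by a positive constant.
    """
    if isinstance(m, np.ndarray):
        m = RaterMatrix.from_array(m)
    grand_mean = float(m.values.mean())
    if grand_mean <= 0:
        raise ZeroMean("grand mean must be positive for CV of index data")
    icc = icc_consistency_average(m).icc
    s_pooled = float(m.values.std(ddof=1))
    se_meas = s_pooled * np.sqrt(max(1.0 - icc, 0.0))
    return CvResult(
        cv_percent=float(100.0 * se_meas / grand_mean),
        se_meas=float(se_meas),
        grand_mean=grand_mean,
    )


def index_histogram(values, bin_width: float = 0.05, origin: float = 0.0):
    """Counts over half-open bins [origin + i·w, origin + (i+1)·w).

    Returns a list of (bin_center, count) for non-empty bins; the total
    count equals the number of inputs (edge values go to the right bin).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EmptyInput("no values to histogram")
    if not (0.0 < bin_width <= 1.0):
        raise EmptyInput("bin_width must lie in (0, 1]")
    idx = np.floor((values - origin) / bin_width).astype(int)
    out = []
    for i in sorted(set(idx.tolist())):
        center = origin + (i + 0.5) * bin_width
        out.append((float(center), int((idx == i).sum())))
    return out


def histogram(values, bin_width: float = 0.05, origin: float = 0.0, ax=None):
    """Plot an index histogram (matplotlib); returns the axis.

    Plumbing-level convenience mirroring the per-technique index
    distribution figures; the counting is delegated to
    :func:`index_histogram`.
    """
    import matplotlib.pyplot as plt

    bins = index_histogram(values, bin_width=bin_width, origin=origin)
    if ax is None:
        _, ax = plt.subplots()
    centers = [b[0] for b in bins]
    counts = [b[1] for b in bins]
    ax.bar(centers, counts, width=bin_width * 0.95, color="#4878a8")
    ax.set_xlabel("CBO index")
    ax.set_ylabel("count")
    return ax


def _wide_table(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Pivot a measurement table to sample_id × column layout."""
    key = {"interrater": "rater", "intertechnique": "technique"}[mode]
    if key not in df.columns:
        # already wide: first column is sample_id, the rest are raters/techniques
        return df.set_index(df.columns[0])
    value_col = "index" if "index" in df.columns else "mean_index"
    per_sample = df.groupby(["sample_id", key])[value_col].mean().unstack(key)
    return per_sample


def reliability_report(
    measurements: str | pd.DataFrame,
    mode: str = "interrater",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise agreement table over all rater or technique columns.

    For every pair of columns the report holds one row with the ICC
    (95% CI, one-sided p), Bland–Altman bias and limits, and CV%
    (SEmeas) — mirroring the published two-rater and six-pair layouts.
    Samples must be present in every column.
    """
    if mode not in ("interrater", "intertechnique"):
        raise EmptyInput(f"unknown mode {mode!r}")
    df = pd.read_csv(measurements) if not isinstance(measurements, pd.DataFrame) else measurements
    wide = _wide_table(df, mode)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise UnpairedSamples(f"samples missing in some columns: {missing}")
    cols = list(wide.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            pair = wide[[a, b]].to_numpy()
            icc = icc_consistency_average(
                RaterMatrix(pair, [str(r) for r in wide.index], [str(a), str(b)]),
                alpha=alpha,
            )
            ba = bland_altman(wide[a].to_numpy(), wide[b].to_numpy())
            cv = coefficient_of_variation(pair)
            rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "n": pair.shape[0],
                    "icc": icc.icc,
                    "ci_low": icc.ci_low,
                    "ci_high": icc.ci_high,
                    "p": icc.p_value,
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "cv_percent": cv.cv_percent,
                    "se_meas": cv.se_meas,
                }
            )
    return pd.DataFrame(rows)


def bland_altman_plot(x, y, ax=None, label: str = ""):
    """Difference-vs-mean plot with bias and ±2 SD limits drawn."""
    import matplotlib.pyplot as plt

    res = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(res.means, res.diffs, s=18, color="#333333")
    ax.axhline(res.bias, color="#4878a8")
    for lim in (res.loa_low, res.loa_high):
        ax.axhline(lim, linestyle="--", color="#a85048")
    ax.axhspan(res.loa_low, res.loa_high, alpha=0.08, color="#a85048")
    ax.set_xlabel("mean of the two measurements")
    ax.set_ylabel("difference")
    if label:
        ax.set_title(label)
    return ax
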