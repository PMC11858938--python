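"""Criterion-validity statistics for paired measurement systems.

Implements the agreement battery used to validate a camera-based gait
system against a reference motion-capture system: intraclass correlation
coefficients in the Shrout-Fleiss forms (one-way random, two-way random
absolute-agreement, two-way mixed consistency; single and average
measures) with F-based 95% confidence intervals (McGraw-Wong), Cronbach's
alpha, ordinary-least-squares agreement regression with fixed/proportional
bias flags, qualitative classification bands, between-system mean
differences, and SEM/MDC.

A useful structural identity, visible wherever both statistics are
reported side by side: ICC(3,k) is algebraically identical to Cronbach's
alpha for every complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError, ValidationError

__all__ = [
    "MeasurementMatrix",
    "ICCResult",
    "RegressionResult",
    "AgreementReport",
    "anova_mean_squares",
    "icc",
    "cronbach_alpha",
    "agreement_regression",
    "bias_flags",
    "classify",
    "diff_of_means",
    "sem_mdc",
    "agreement_report",
    "format_p",
]

ICC_FORMS = ("icc1", "icc1k", "icc2", "icc2k", "icc3", "icc3k")


@dataclass(frozen=True)
class MeasurementMatrix:
    """n subjects x k systems of paired measurements (no missing cells)."""

    values: np.ndarray
    measurement_name: str = ""
    units: str = ""
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValidationError("measurement matrix must be 2-D")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValidationError(f"need n >= 2 and k >= 2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError(
                "matrix has non-finite cells; apply listwise deletion first")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "MeasurementMatrix":
        """Build from a wide table, listwise-deleting incomplete rows."""
        clean = df.dropna(axis=0, how="any")
        return cls(clean.to_numpy(dtype=float),
                   row_labels=tuple(map(str, clean.index)),
                   col_labels=tuple(map(str, clean.columns)), **kw)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def anova_mean_squares(values: np.ndarray) -> dict:
    """Two-way and one-way ANOVA mean squares of an n x k matrix.

    Returns MSR (between rows), MSC (between columns), MSE (two-way
    residual) and MSW (one-way within-row) with their degrees of freedom.
    """
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    return {
        "MSR": ss_rows / (n - 1),
        "MSC": ss_cols / (k - 1),
        "MSE": ss_err / ((n - 1) * (k - 1)),
        "MSW": ss_within / (n * (k - 1)),
        "df_rows": n - 1,
        "df_cols": k - 1,
        "df_err": (n - 1) * (k - 1),
        "df_within": n * (k - 1),
    }


@dataclass(frozen=True)
class ICCResult:
    form: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    k: int


def _sb(x: float, k: int) -> float:
    """Spearman-Brown step-up from a single- to a k-average measure."""
    return k * x / (1.0 + (k - 1) * x)


def icc(m: MeasurementMatrix, form: str = "icc2k", alpha: float = 0.05) -> ICCResult:
    """Shrout-Fleiss intraclass correlation with 95% CI and p-value.

    Forms: ``icc1``/``icc1k`` (one-way random), ``icc2``/``icc2k``
    (two-way random, absolute agreement), ``icc3``/``icc3k`` (two-way
    mixed, consistency); the ``k`` suffix denotes average measures.  The
    p-value tests H0: ICC = 0 via the corresponding ANOVA F test.
    """
    if form not in ICC_FORMS:
        raise StatisticsError(f"unknown ICC form {form!r}")
    ms = anova_mean_squares(m.values)
    n, k = m.n, m.k
    MSR, MSC, MSE, MSW = ms["MSR"], ms["MSC"], ms["MSE"], ms["MSW"]
    if MSR <= 0:
        raise StatisticsError("zero between-row variance: ICC undefined")
    q = 1.0 - alpha / 2.0

    if form in ("icc1", "icc1k"):
        denom, df2 = MSW, ms["df_within"]
    else:
        denom, df2 = MSE, ms["df_err"]
    df1 = ms["df_rows"]

    if denom == 0.0:
        # zero error mean square: F is infinite, p = 0; the point
        # estimates below remain well defined (a column offset still
        # penalizes the absolute-agreement and one-way forms)
        F, p = np.inf, 0.0
    else:
        F = MSR / denom
        p = float(stats.f.sf(F, df1, df2))

    if form == "icc1":
        est = (MSR - MSW) / (MSR + (k - 1) * MSW)
    elif form == "icc1k":
        est = (MSR - MSW) / MSR
    elif form == "icc2":
        est = (MSR - MSE) / (MSR + (k - 1) * MSE + k * (MSC - MSE) / n)
    elif form == "icc2k":
        est = (MSR - MSE) / (MSR + (MSC - MSE) / n)
    elif form == "icc3":
        est = (MSR - MSE) / (MSR + (k - 1) * MSE)
    else:  # icc3k
        est = (MSR - MSE) / MSR

    if form in ("icc1", "icc1k", "icc3", "icc3k"):
        if np.isinf(F):
            lo = hi = est
        else:
            FL = F / stats.f.ppf(q, df1, df2)
            FU = F * stats.f.ppf(q, df2, df1)
            if form.endswith("k"):
                lo, hi = 1.0 - 1.0 / FL, 1.0 - 1.0 / FU
            else:
                lo = (FL - 1.0) / (FL + k - 1.0)
                hi = (FU - 1.0) / (FU + k - 1.0)
    else:
        # two-way random: Satterthwaite df for the column/error mixture
        r2 = (MSR - MSE) / (MSR + (k - 1) * MSE + k * (MSC - MSE) / n)
        one_minus = max(1.0 - r2, 1e-15)
        a = k * r2 / (n * one_minus)
        b = 1.0 + k * r2 * (n - 1) / (n * one_minus)
        num = (a * MSC + b * MSE) ** 2
        den = (a * MSC) ** 2 / (k - 1) + (b * MSE) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else ms["df_err"]
        F1 = stats.f.ppf(q, df1, v)
        F2 = stats.f.ppf(q, v, df1)
        lo = (n * (MSR - F1 * MSE)
              / (F1 * (k * MSC + (k * n - k - n) * MSE) + n * MSR))
        hi = (n * (F2 * MSR - MSE)
              / (k * MSC + (k * n - k - n) * MSE + n * F2 * MSR))
        if form == "icc2k":
            lo, hi = _sb(lo, k), _sb(hi, k)
    lo, hi = min(lo, est), max(hi, est)
    return ICCResult(form, float(est), float(lo), float(hi), p, n, k)


def cronbach_alpha(m: MeasurementMatrix) -> float:
    """Cronbach's alpha (ddof=1 sample variances).

    ``alpha = k/(k-1) * (1 - sum_i var(col_i) / var(row sums))``; equal to
    ICC(3,k) for every complete matrix.
    """
    x = m.values
    k = m.k
    var_total = np.var(x.sum(axis=1), ddof=1)
    if var_total == 0:
        raise StatisticsError("zero total variance: alpha undefined")
    var_items = np.var(x, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - var_items / var_total))


@dataclass(frozen=True)
class RegressionResult:
    B: float
    constant: float
    b_ci_low: float
    b_ci_high: float
    const_ci_low: float
    const_ci_high: float
    p: float
    r: float
    r2: float
    n: int


def agreement_regression(x, y, alpha: float = 0.05) -> RegressionResult:
    """OLS of the reference system on the evaluated system: y = c + B x.

    ``x`` is the evaluated (camera) system, ``y`` the reference.  CIs use
    the t distribution with n-2 df; r is the Pearson correlation and
    R^2 = r^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise StatisticsError("agreement regression needs n >= 3")
    if np.var(x) == 0:
        raise StatisticsError("constant x: regression undefined")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return RegressionResult(
        B=float(res.slope),
        constant=float(res.intercept),
        b_ci_low=float(res.slope - tcrit * res.stderr),
        b_ci_high=float(res.slope + tcrit * res.stderr),
        const_ci_low=float(res.intercept - tcrit * res.intercept_stderr),
        const_ci_high=float(res.intercept + tcrit * res.intercept_stderr),
        p=float(res.pvalue),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        n=n,
    )


def bias_flags(reg: RegressionResult) -> dict:
    """Fixed/proportional bias from the regression CIs.

    Proportional bias: the 95% CI for the slope excludes 1.  Fixed bias:
    the 95% CI for the intercept excludes 0.
    """
    return {
        "proportional": not (reg.b_ci_low <= 1.0 <= reg.b_ci_high),
        "fixed": not (reg.const_ci_low <= 0.0 <= reg.const_ci_high),
    }


#: Qualitative bands per scale; intervals are lower-closed [a, b).
_BANDS = {
    "icc": ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"),
            (np.inf, "excellent")),
    "r": ((0.2, "negligible"), (0.4, "small"), (0.7, "medium"),
          (np.inf, "large")),
    # alternative convention kept available via scale="r_alt"
    "r_alt": ((0.1, "negligible"), (0.3, "small"), (0.5, "medium"),
              (np.inf, "large")),
    "r2": ((0.04, "negligible"), (0.16, "small"), (0.5, "medium"),
           (np.inf, "large")),
}


def classify(value: float, scale: str = "icc") -> str:
    """Qualitative label for an agreement statistic.

    Scales: ``icc`` (poor/moderate/good/excellent), ``r`` and ``r_alt``
    (correlation-size bands), ``r2`` (determination-size bands), ``alpha``
    (acceptable at >= 0.7).  Boundary values fall in the upper band.
    """
    if not np.isfinite(value):
        raise ValidationError("cannot classify a non-finite value")
    if scale == "alpha":
        return "acceptable" if value >= 0.7 else "unacceptable"
    try:
        bands = _BANDS[scale]
    except KeyError:
        raise StatisticsError(f"unknown classification scale {scale!r}") from None
    for upper, label in bands:
        if value < upper:
            return label
    return bands[-1][1]  # pragma: no cover


def diff_of_means(mean_camera: float, mean_reference: float) -> float:
    """Between-system difference, camera minus reference, in native units."""
    if not (np.isfinite(mean_camera) and np.isfinite(mean_reference)):
        raise ValidationError("means must be finite")
    return float(mean_camera - mean_reference)


def sem_mdc(sd: float, icc_value: float) -> dict:
    """Standard error of measurement and 95% minimal detectable change.

    ``SEM = sd * sqrt(1 - ICC)``; ``MDC95 = 1.96 * sqrt(2) * SEM``.
    """
    if not (0.0 <= icc_value <= 1.0):
        raise StatisticsError(f"ICC {icc_value} outside [0, 1]")
    if sd < 0:
        raise StatisticsError("sd must be non-negative")
    sem = sd * np.sqrt(1.0 - icc_value)
    return {"SEM": float(sem), "MDC95": float(1.96 * np.sqrt(2.0) * sem)}


def format_p(p: float) -> str:
    """p to 3 decimals, '<0.001' below."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class AgreementReport:
    """Full criterion-validity report for one measurement."""

    measurement_name: str
    units: str
    icc: dict = field(default_factory=dict)          # form -> ICCResult
    alpha: float = np.nan
    regression: RegressionResult | None = None
    bias: dict = field(default_factory=dict)
    bands: dict = field(default_factory=dict)
    diff: float = np.nan
    sem_mdc: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat dict mirroring the validation-table column layout."""
        reg = self.regression
        row = {
            "measurement": self.measurement_name,
            "units": self.units,
            "B": reg.B,
            "constant": reg.constant,
            "b_ci": f"{reg.b_ci_low:.3f} to {reg.b_ci_high:.3f}",
            "p": format_p(reg.p),
            "r2": reg.r2,
            "diff": self.diff,
            "alpha": self.alpha,
            "fixed_bias": self.bias.get("fixed"),
            "proportional_bias": self.bias.get("proportional"),
        }
        for form, res in self.icc.items():
            row[form] = res.estimate
            row[f"{form}_ci"] = f"{res.ci_low:.3f} to {res.ci_high:.3f}"
            row[f"{form}_p"] = format_p(res.p)
        for key, label in self.bands.items():
            row[f"band_{key}"] = label
        row.update(self.sem_mdc)
        return row


def agreement_report(
    m: MeasurementMatrix,
    camera_col: int = 0,
    reference_col: int = 1,
    forms: tuple[str, ...] = ("icc1k", "icc2k", "icc3k"),
) -> AgreementReport:
    """Run the full battery on one paired-measurement matrix.

    The regression uses the evaluated (camera) column as the independent
    variable and the reference column as the dependent one.
    """
    rep = AgreementReport(m.measurement_name, m.units)
    for form in forms:
        rep.icc[form] = icc(m, form)
    rep.alpha = cronbach_alpha(m)
    x = m.values[:, camera_col]
    y = m.values[:, reference_col]
    rep.regression = agreement_regression(x, y)
    rep.bias = bias_flags(rep.regression)
    rep.diff = diff_of_means(float(np.mean(x)), float(np.mean(y)))
    primary = rep.icc.get("icc2k") or next(iter(rep.icc.values()))
    rep.bands = {
        "icc": classify(primary.estimate, "icc"),
        "r": classify(abs(rep.regression.r), "r"),
        "r2": classify(rep.regression.r2, "r2"),
        "alpha": classify(rep.alpha, "alpha"),
    }
    pooled_sd = float(np.std(m.values.mean(axis=1), ddof=1))
    icc_for_sem = float(np.clip(primary.estimate, 0.0, 1.0))
    rep.sem_mdc = sem_mdc(pooled_sd, icc_for_sem)
    return rep
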