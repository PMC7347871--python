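"""qPCR absolute quantification and mitotype ratio estimation.

A qPCR standard curve is the ordinary least-squares fit of quantification
cycle (Cq) on log10 input copies over a dilution series; its slope gives
the amplification efficiency ``E = 10^(-1/slope) - 1`` (100% = perfect
doubling, the usual QC window being 90-110%).  Inverting the curve turns
replicate Cq measurements into absolute copy numbers with t-based
confidence intervals, from which per-sample mtDNA/nDNA loads and M/F
mitotype ratios follow.  Read-count ratios from shotgun sequencing provide
an independent, length-normalised estimate of the same heteroplasmy ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DilutionSeries",
    "StandardCurve",
    "SampleQuant",
    "RatioEstimate",
    "fit_standard_curve",
    "quantify_sample",
    "ratio_with_ci",
    "ngs_ratio",
]

DETECTION_CUTOFF_CQ = 35.0


@dataclass
class DilutionSeries:
    """Known-copy dilution points with replicate Cq values for one target."""

    target: str
    points: list[tuple[float, list[float]]]  # (known copies, replicate Cqs)
    n_experiments: int = 1

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("need at least 3 dilution points")
        for copies, reps in self.points:
            if copies <= 0:
                raise ValueError("copy numbers must be positive")
            if len(reps) < 1:
                raise ValueError("each point needs at least one replicate")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, target: str) -> "DilutionSeries":
        """Build from a long table with columns target, copies, cq."""
        sub = df[df["target"] == target]
        pts = [
            (float(c), list(map(float, g["cq"])))
            for c, g in sub.groupby("copies", sort=True)
        ]
        nexp = int(sub["experiment"].nunique()) if "experiment" in sub else 1
        return cls(target, pts, n_experiments=nexp)


@dataclass
class StandardCurve:
    """Fitted calibration line ``Cq = intercept_cq + slope * log10(copies)``."""

    target: str
    slope: float
    intercept_cq: float
    r_squared: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    n_points: int = 0
    residual_sd: float = float("nan")

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def qc_pass(self) -> bool:
        return 0.90 <= self.efficiency <= 1.10

    def copies_from_cq(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept_cq) / self.slope)

    def cq_from_copies(self, copies: float) -> float:
        return self.intercept_cq + self.slope * math.log10(copies)

    def summary(self) -> str:
        lines = [
            f"Standard curve: {self.target}",
            f"  Cq = {self.intercept_cq:.4f} {self.slope:+.4f} * log10(copies)",
            f"  efficiency {100 * self.efficiency:.1f}%"
            f" ({'pass' if self.qc_pass else 'FAIL'} 90-110% QC)",
            f"  R^2 = {self.r_squared:.4f}  (n = {self.n_points})",
        ]
        return "\n".join(lines)


@dataclass
class SampleQuant:
    """Absolute copy estimate for one sample x target."""

    sample_id: str
    tissue: str
    target: str
    mean_cq: float
    copies: float
    ci_low: float
    ci_high: float
    n_replicates: int
    cq_se: float
    curve: StandardCurve
    below_detection: bool = False


@dataclass
class RatioEstimate:
    numerator_target: str
    denominator_target: str
    ratio: float
    ci_low: float
    ci_high: float
    below_detection: bool = False
    note: str = ""


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """OLS of Cq on log10(copies), replicates pooled across experiments.

    Errors out when the dilution points span fewer than two decades or the
    fitted slope is non-negative (amplification must reduce Cq as template
    increases).
    """
    x, y = [], []
    for copies, reps in series.points:
        for cq in reps:
            x.append(math.log10(copies))
            y.append(cq)
    xs = sorted({round(v, 9) for v in x})
    if xs[-1] - xs[0] < 2.0:
        raise ValueError("dilution series must span at least two decades")
    X = sm.add_constant(np.asarray(x))
    fit = sm.OLS(np.asarray(y), X).fit()
    intercept, slope = fit.params
    if slope >= 0:
        raise ValueError(f"{series.target}: positive standard-curve slope")
    return StandardCurve(
        target=series.target,
        slope=float(slope),
        intercept_cq=float(intercept),
        r_squared=float(fit.rsquared),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        n_points=len(y),
        residual_sd=float(np.sqrt(fit.scale)),
    )


def _cq_interval(reps: Sequence[float], level: float = 0.95) -> tuple[float, float, int]:
    """(mean, standard error of the mean via t, n) for replicate Cqs."""
    arr = np.asarray(reps, dtype=float)
    n = len(arr)
    mean = float(arr.mean())
    if n < 2:
        return mean, 0.0, n
    se = float(arr.std(ddof=1) / math.sqrt(n))
    return mean, se, n


def quantify_sample(
    cq_replicates: Sequence[float],
    curve: StandardCurve,
    sample_id: str = "",
    tissue: str = "",
    ci_level: float = 0.95,
    detection_cutoff: float = DETECTION_CUTOFF_CQ,
) -> SampleQuant:
    """Invert the standard curve for a set of replicate Cq values.

    The confidence interval is a t-interval on the mean Cq propagated
    through the (monotone) inversion; with a single replicate the interval
    collapses to the point estimate.  Replicates at or beyond the detection
    cutoff mark the sample as below detection.
    """
    if len(cq_replicates) == 0:
        raise ValueError("no replicates")
    mean, se, n = _cq_interval(cq_replicates)
    copies = curve.copies_from_cq(mean)
    if n >= 2 and se > 0:
        tq = stats.t.ppf(0.5 + ci_level / 2, df=n - 1)
        lo_cq, hi_cq = mean + tq * se, mean - tq * se  # higher Cq = fewer copies
        ci = sorted((curve.copies_from_cq(lo_cq), curve.copies_from_cq(hi_cq)))
    else:
        ci = [copies, copies]
    return SampleQuant(
        sample_id=sample_id,
        tissue=tissue,
        target=curve.target,
        mean_cq=mean,
        copies=copies,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        n_replicates=n,
        cq_se=se,
        curve=curve,
        below_detection=bool(mean >= detection_cutoff),
    )


def ratio_with_ci(
    num: SampleQuant, den: SampleQuant, ci_level: float = 0.95
) -> RatioEstimate:
    """Copy-number ratio of two targets in the same sample.

    The interval propagates both replicate-Cq t-intervals through their
    curves on the log10 scale (delta method): ``var(log10 ratio) =
    (se_num/slope_num)^2 + (se_den/slope_den)^2`` with a Welch-Satterthwaite
    t quantile.  A below-detection numerator yields a one-sided upper bound
    (the true ratio lies between zero and it); a below-detection denominator
    is undefined and flagged.
    """
    if num.sample_id and den.sample_id and num.sample_id != den.sample_id:
        raise ValueError("ratio requires measurements from the same sample")
    if den.below_detection:
        return RatioEstimate(
            num.target, den.target, float("nan"), float("nan"), float("nan"),
            below_detection=True, note="denominator below detection",
        )
    ratio = num.copies / den.copies
    v_num = (num.cq_se / num.curve.slope) ** 2
    v_den = (den.cq_se / den.curve.slope) ** 2
    var_log = v_num + v_den
    if var_log == 0:
        lo = hi = ratio
    else:
        # Welch-Satterthwaite effective degrees of freedom
        df = var_log**2 / (
            (v_num**2 / max(num.n_replicates - 1, 1) if v_num else 0)
            + (v_den**2 / max(den.n_replicates - 1, 1) if v_den else 0)
        )
        tq = stats.t.ppf(0.5 + ci_level / 2, df=df)
        half = tq * math.sqrt(var_log)
        lo, hi = ratio * 10**-half, ratio * 10**half
    if num.below_detection:
        return RatioEstimate(
            num.target, den.target, ratio, 0.0, hi,
            below_detection=True, note="numerator below detection; upper bound",
        )
    return RatioEstimate(num.target, den.target, ratio, lo, hi)


def ngs_ratio(
    reads_m: int,
    reads_f: int,
    len_m: float,
    len_f: float,
    ci_level: float = 0.95,
    bootstrap_reps: int = 10_000,
    seed: int | None = None,
) -> RatioEstimate:
    """Length-normalised M/F mitogenome ratio from mapped read counts.

    ``ratio = (reads_M/len_M) / (reads_F/len_F)``; the interval resamples
    the binomial read split (parametric bootstrap, percentile interval).
    Zero denominator reads yield a one-sided lower bound.
    """
    if len_m <= 0 or len_f <= 0:
        raise ValueError("genome lengths must be positive")
    total = reads_m + reads_f
    if total <= 0:
        raise ValueError("no reads")
    norm = len_f / len_m
    if reads_f == 0:
        # lower bound from a one-read pseudo-count
        bound = (reads_m / len_m) / (1.0 / len_f)
        return RatioEstimate(
            "M", "F", float("inf"), bound, float("inf"),
            below_detection=True, note="no F reads; lower bound",
        )
    ratio = (reads_m / len_m) / (reads_f / len_f)
    rng = np.random.default_rng(seed)
    draws_m = rng.binomial(total, reads_m / total, size=bootstrap_reps)
    draws_f = total - draws_m
    with np.errstate(divide="ignore"):
        reps = (draws_m / draws_f) * norm
    alpha = 1 - ci_level
    lo, hi = np.quantile(reps[np.isfinite(reps)], [alpha / 2, 1 - alpha / 2])
    return RatioEstimate("M", "F", float(ratio), float(lo), float(hi))


# ---------------------------------------------------------------------------
# table-level driver


def quantify_table(
    dilutions: pd.DataFrame,
    samples: pd.DataFrame,
    detection_cutoff: float = DETECTION_CUTOFF_CQ,
) -> tuple[dict[str, StandardCurve], pd.DataFrame]:
    """Fit one curve per target and quantify every sample x target group.

    ``dilutions``: columns target, copies, cq (optionally experiment).
    ``samples``: columns sample_id, tissue, target, cq.
    Returns the fitted curves and a tidy per-sample table of copy estimates.
    """
    curves = {
        t: fit_standard_curve(DilutionSeries.from_frame(dilutions, t))
        for t in sorted(dilutions["target"].unique())
    }
    rows = []
    for (sid, tissue, target), grp in samples.groupby(
        ["sample_id", "tissue", "target"], sort=True
    ):
        q = quantify_sample(
            list(grp["cq"]), curves[target], sample_id=str(sid), tissue=str(tissue),
            detection_cutoff=detection_cutoff,
        )
        rows.append(
            {
                "sample_id": q.sample_id,
                "tissue": q.tissue,
                "target": q.target,
                "mean_cq": q.mean_cq,
                "copies": q.copies,
                "ci_low": q.ci_low,
                "ci_high": q.ci_high,
                "cq_se": q.cq_se,
                "n_replicates": q.n_replicates,
                "below_detection": q.below_detection,
            }
        )
    return curves, pd.DataFrame(rows)
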