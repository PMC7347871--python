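"""Sperm mtDNA copy-number extrapolation model.

Male mantle tissue of a DUI mussel mixes somatic cells (carrying F-type
mtDNA) with spermatozoa (carrying M-type mtDNA).  If sperm are homoplasmic
for the M type, the M-mtDNA/nDNA load of a tissue sample is linear in its
somatic fraction, itself proxied by F-mtDNA/nDNA.  Regressing y = M/nDNA
on x = F/nDNA across male-mantle samples and extrapolating to x = 0
(pure sperm) estimates the number of M mitogenome copies per sperm cell;
dividing by the assumed number of mitochondria per sperm cell (five, the
usual count for bivalve sperm) gives copies per mitochondrion.

The model object follows the statsmodels convention: build it from data,
call :meth:`SpermCopyModel.fit`, inspect the returned
:class:`SpermCopyResults` (estimates, intervals, ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TissuePoint", "SpermCopyModel", "SpermCopyResults", "fit_sperm_model"]


@dataclass(frozen=True)
class TissuePoint:
    """One male-mantle sample: F- and M-mtDNA loads per nuclear genome."""

    sample_id: str
    x: float  # F-mtDNA / nDNA
    y: float  # M-mtDNA / nDNA

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("copy loads must be non-negative")


class SpermCopyModel:
    """OLS model ``M/nDNA = intercept + slope * F/nDNA`` over tissue points.

    Parameters
    ----------
    points:
        Tissue points; below-detection M measurements should be excluded
        upstream (they are dropped here with a warning when flagged via
        ``exclude``).
    weights:
        Optional inverse-variance weights (weighted fit); default is the
        unweighted fit matching the plain trend-line convention.
    """

    def __init__(
        self,
        points: Sequence[TissuePoint],
        weights: Sequence[float] | None = None,
    ):
        pts = list(points)
        if len(pts) < 3:
            raise ValueError("need at least 3 points")
        xs = np.array([p.x for p in pts])
        if np.allclose(xs, xs[0]):
            raise ValueError("x values must vary")
        self.points = pts
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x_col: str = "F_per_nDNA",
        y_col: str = "M_per_nDNA",
        tissue_col: str = "tissue",
        require_tissue: str = "male_mantle",
        exclude_below_detection: bool = True,
    ) -> "SpermCopyModel":
        """Build from a tidy table, enforcing the male-mantle tissue label.

        Female-mantle rows are rejected: the mixture argument only holds for
        the tissue that actually contains sperm.
        """
        if tissue_col in df.columns:
            other = set(df[tissue_col]) - {require_tissue}
            if other:
                raise ValueError(
                    f"model accepts only {require_tissue!r} rows; found {sorted(other)}"
                )
        use = df
        if exclude_below_detection and "below_detection" in df.columns:
            n_drop = int(df["below_detection"].sum())
            if n_drop:
                warnings.warn(
                    f"excluding {n_drop} below-detection point(s)", stacklevel=2
                )
            use = df[~df["below_detection"]]
        pts = [
            TissuePoint(str(r.get("sample_id", i)), float(r[x_col]), float(r[y_col]))
            for i, r in use.reset_index(drop=True).iterrows()
        ]
        return cls(pts)

    def fit(self, ci_level: float = 0.95) -> "SpermCopyResults":
        x = np.array([p.x for p in self.points])
        y = np.array([p.y for p in self.points])
        X = sm.add_constant(x)
        if self.weights is None:
            res = sm.OLS(y, X).fit()
        else:
            res = sm.WLS(y, X, weights=self.weights).fit()
        ci = res.conf_int(alpha=1 - ci_level)
        return SpermCopyResults(
            model=self,
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            intercept_se=float(res.bse[0]),
            slope_se=float(res.bse[1]),
            intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
            slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
            r_squared=float(res.rsquared),
            n_points=len(self.points),
            ci_level=ci_level,
            _sm_results=res,
        )


@dataclass
class SpermCopyResults:
    """Fitted sperm copy-number model: estimates, intervals, diagnostics."""

    model: SpermCopyModel
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    r_squared: float
    n_points: int
    ci_level: float
    _sm_results: object = None
    n_mitochondria_assumed: int = 5

    @property
    def copies_per_sperm(self) -> float:
        """The y-axis intercept: M-mtDNA copies in a pure sperm cell."""
        return self.intercept

    @property
    def intercept_se_band(self) -> tuple[float, float]:
        """Intercept +/- one standard error (the plotted uncertainty band)."""
        return (self.intercept - self.intercept_se, self.intercept + self.intercept_se)

    def copies_per_mitochondrion(self, n_mito: int | None = None) -> float:
        """M-mtDNA copies per sperm mitochondrion given an assumed count."""
        if n_mito is None:
            n_mito = self.n_mitochondria_assumed
        if n_mito < 1:
            raise ValueError("need at least one mitochondrion")
        self.n_mitochondria_assumed = n_mito
        return self.intercept / n_mito

    def predict(self, x: Sequence[float]) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        lo, hi = self.intercept_se_band
        cm = self.intercept / self.n_mitochondria_assumed
        pct = int(round(self.ci_level * 100))
        lines = [
            "Sperm M-mtDNA copy-number model (OLS, M/nDNA ~ F/nDNA)",
            f"  n points            : {self.n_points}",
            f"  slope               : {self.slope:.4f} (SE {self.slope_se:.4f})",
            f"  intercept           : {self.intercept:.4f} (SE {self.intercept_se:.4f})",
            f"  intercept +/- 1 SE  : ({lo:.2f}, {hi:.2f})",
            f"  intercept {pct}% CI    : ({self.intercept_ci[0]:.2f},"
            f" {self.intercept_ci[1]:.2f})",
            f"  R^2                 : {self.r_squared:.4f}",
            f"  copies per sperm    : {self.intercept:.2f}",
            f"  copies/mitochondrion: {cm:.2f}"
            f" (assuming {self.n_mitochondria_assumed} mitochondria/sperm)",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the tissue points with the fitted extrapolation line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.array([p.x for p in self.model.points])
        y = np.array([p.y for p in self.model.points])
        ax.scatter(x, y, color="k", s=18)
        grid = np.linspace(0, x.max() * 1.05, 50)
        ax.plot(grid, self.predict(grid), color="tab:blue")
        lo, hi = self.intercept_se_band
        ax.errorbar([0], [self.intercept], yerr=[[self.intercept - lo], [hi - self.intercept]],
                    fmt="o", color="tab:red", capsize=4)
        ax.set_xlabel("F-mtDNA / nDNA")
        ax.set_ylabel("M-mtDNA / nDNA")
        return ax


def fit_sperm_model(
    points: Sequence[TissuePoint], ci_level: float = 0.95
) -> SpermCopyResults:
    """Functional shortcut: build the model and fit in one call."""
    return SpermCopyModel(points).fit(ci_level=ci_level)
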