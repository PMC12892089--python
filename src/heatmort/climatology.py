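"""Per-region temperature climatology and the relative-risk curve.

The exposure model is a regionally parameterized quadratic relative-risk
(RR) curve anchored at the optimal temperature OT (the minimum-mortality
temperature, operationalized as the 84th percentile of daily mean
temperature over a reference window):

    RR(T) = 1 + A(SMT) * (T - OT)^2 + B(SMT) * (T - OT)    for T > OT
    RR(T) = 1                                              for T <= OT

where SMT is the region's summer (June–September) mean temperature over
the same window, and A and B are affine functions of SMT,

    A(SMT) = a_s * SMT + a_i,       B(SMT) = b_s * SMT + b_i,

so that cooler regions (lower SMT, with slopes a_s, b_s < 0) get steeper
risk curves — the generalized-fit structure of multi-city US studies.
RR is floored at 1: only the heat branch is modelled, and a coefficient
set that would dip below 1 above OT is clamped rather than allowed to
produce negative attributable deaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .config import RunConfig

__all__ = [
    "RiskCoefficients",
    "empirical_quantile",
    "relative_risk",
    "TemperatureClimatology",
    "build_climatology",
]


@dataclass(frozen=True)
class RiskCoefficients:
    """Constants of the SMT-parameterized risk curve.

    ``a_s``/``a_i`` are the slope and intercept of the quadratic
    coefficient A(SMT); ``b_s``/``b_i`` those of the linear coefficient
    B(SMT). Units: A in RR per °C², B in RR per °C, slopes additionally
    per °C of SMT. The composite A and B are the ground truth of the
    curve; signs are fixed by the coefficient source and never
    re-derived.
    """

    a_s: float
    a_i: float
    b_s: float
    b_i: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("a_s", "a_i", "b_s", "b_i"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite risk coefficient {name}")

    def quad_coef(self, smt: float | np.ndarray) -> np.ndarray:
        """A(SMT), the quadratic coefficient (RR per °C²)."""
        return self.a_s * np.asarray(smt, dtype=float) + self.a_i

    def lin_coef(self, smt: float | np.ndarray) -> np.ndarray:
        """B(SMT), the linear coefficient (RR per °C)."""
        return self.b_s * np.asarray(smt, dtype=float) + self.b_i

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RiskCoefficients":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            a_s=float(raw["a_s"]),
            a_i=float(raw["a_i"]),
            b_s=float(raw["b_s"]),
            b_i=float(raw["b_i"]),
            provenance=str(raw.get("provenance", "unspecified")),
        )

    @classmethod
    def default(cls) -> "RiskCoefficients":
        """Package default coefficient set (see data/coefficients.yaml)."""
        ref = resources.files("heatmort.data").joinpath("coefficients.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def empirical_quantile(values, q: float) -> float:
    """Linear-interpolation empirical quantile.

    With sorted values x_(1..n) and h = (n - 1) q + 1, returns
    x_floor(h) + (h - floor(h)) * (x_floor(h)+1 - x_floor(h)).

    Raises on empty or non-finite input and on q outside (0, 1).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empirical_quantile: empty input")
    if not np.all(np.isfinite(arr)):
        raise ValueError("empirical_quantile: non-finite values")
    if not 0.0 < q < 1.0:
        raise ValueError(f"empirical_quantile: q={q} outside (0, 1)")
    return float(np.quantile(arr, q, method="linear"))


def relative_risk(T, ot: float, smt: float, coeffs: RiskCoefficients):
    """Evaluate RR(T) for one region (vectorized over T).

    RR = 1 + A(SMT)·(T−OT)² + B(SMT)·(T−OT) above OT, 1 at or below OT,
    floored at 1.
    """
    T = np.asarray(T, dtype=float)
    if not (np.isfinite(ot) and np.isfinite(smt)):
        raise ValueError("non-finite OT or SMT")
    dt = np.where(T > ot, T - ot, 0.0)
    rr = 1.0 + coeffs.quad_coef(smt) * dt**2 + coeffs.lin_coef(smt) * dt
    rr = np.maximum(rr, 1.0)
    return rr if rr.ndim else float(rr)


class TemperatureClimatology(BaseEstimator):
    """Per-region OT / SMT / extreme-threshold climatology.

    Fit on a long-format daily temperature table (columns ``region_id``,
    ``date``, ``value`` in °C). For each region, over the reference
    window:

    * ``OT``  — the ``ot_quantile`` (default 0.84) empirical quantile of
      daily mean temperature, the operational minimum-mortality
      temperature;
    * ``P95`` — the ``extreme_quantile`` (default 0.95) quantile, the
      extreme-heat threshold;
    * ``SMT`` — the mean over summer-month days, which sets the local
      steepness of the risk curve.

    By default the OT/P95 quantiles are taken over *all* calendar days
    of the window (``quantile_days="summer"`` restricts them to summer).

    Attributes
    ----------
    climatology_ : pandas.DataFrame indexed by region_id with columns
        OT, SMT, P95, n_days; regions with no data in the window are
        excluded with a warning.
    """

    def __init__(
        self,
        ot_quantile: float = 0.84,
        extreme_quantile: float = 0.95,
        window: tuple[int, int] = (2010, 2023),
        summer_months: tuple[int, ...] = (6, 7, 8, 9),
        quantile_days: str = "all",
        coefficients: RiskCoefficients | None = None,
    ):
        self.ot_quantile = ot_quantile
        self.extreme_quantile = extreme_quantile
        self.window = window
        self.summer_months = summer_months
        self.quantile_days = quantile_days
        self.coefficients = coefficients

    @classmethod
    def from_config(cls, config: RunConfig, coefficients: RiskCoefficients | None = None):
        return cls(
            ot_quantile=config.ot_quantile,
            extreme_quantile=config.extreme_quantile,
            window=config.climatology_window,
            summer_months=config.summer_months,
            quantile_days=config.quantile_days,
            coefficients=coefficients,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "TemperatureClimatology":
        if not 0.0 < self.ot_quantile < self.extreme_quantile < 1.0:
            raise ValueError("require 0 < ot_quantile < extreme_quantile < 1")
        temps = X
        dates = pd.to_datetime(temps["date"])
        lo, hi = self.window
        in_window = (dates.dt.year >= lo) & (dates.dt.year <= hi)
        is_summer = dates.dt.month.isin(self.summer_months)
        rows = {}
        for region, grp in temps.assign(
            _win=in_window, _summer=is_summer
        ).groupby("region_id", sort=True):
            win = grp[grp["_win"]]
            vals = win["value"].dropna()
            summer_vals = win.loc[win["_summer"], "value"].dropna()
            if vals.empty or summer_vals.empty:
                warnings.warn(
                    f"region {region!r}: no data in climatology window "
                    f"{lo}-{hi}; excluded",
                    stacklevel=2,
                )
                continue
            qvals = summer_vals if self.quantile_days == "summer" else vals
            ot = empirical_quantile(qvals, self.ot_quantile)
            p95 = empirical_quantile(qvals, self.extreme_quantile)
            if not ot < p95:
                warnings.warn(
                    f"region {region!r}: OT ({ot:.2f}) is not below the "
                    f"extreme threshold ({p95:.2f}); degenerate distribution",
                    stacklevel=2,
                )
            rows[region] = {
                "OT": ot,
                "SMT": float(summer_vals.mean()),
                "P95": p95,
                "n_days": int(len(vals)),
            }
        if not rows:
            raise ValueError("no region had data inside the climatology window")
        self.climatology_ = pd.DataFrame.from_dict(rows, orient="index").rename_axis(
            "region_id"
        )
        self.window_ = (lo, hi)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "climatology_"):
            raise NotFittedError(
                "TemperatureClimatology instance is not fitted yet; call fit first"
            )

    def _coeffs(self) -> RiskCoefficients:
        return self.coefficients if self.coefficients is not None else RiskCoefficients.default()

    def relative_risk(self, region_id: str, T):
        """RR(T) for a fitted region."""
        self._check_fitted()
        row = self.climatology_.loc[region_id]
        return relative_risk(T, row["OT"], row["SMT"], self._coeffs())

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Append an ``rr`` column to a long-format temperature table."""
        self._check_fitted()
        out = X.copy()
        coeffs = self._coeffs()
        rr = np.full(len(out), np.nan)
        for region, idx in out.groupby("region_id", sort=False).indices.items():
            if region not in self.climatology_.index:
                continue
            row = self.climatology_.loc[region]
            rr[idx] = relative_risk(
                out["value"].to_numpy()[idx], row["OT"], row["SMT"], coeffs
            )
        out["rr"] = rr
        return out


def build_climatology(
    temps: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`TemperatureClimatology` and
    return its per-region table."""
    est = TemperatureClimatology.from_config(config or RunConfig())
    return est.fit(temps).climatology_
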