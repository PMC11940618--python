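"""Vehicle normalization and censored logistic concentration–response fitting.

The modelling core of the package.  Raw well luminescence is first expressed
as percent-of-vehicle viability within each (cell source, drug) series; a
decreasing logistic

    v(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill)

with the top asymptote fixed at 100 % is then fitted to the replicate-level
points by bounded nonlinear least squares on the log10 concentration axis.
Points of departure (EC50: 50 % viability; IC10: 90 % viability) are solved
in closed form on the fitted curve, and reported as right-censored bounds
("> c_max tested") whenever the effect level is not reached within the
tested range or the response is flat.

The fixed top reflects that the data are vehicle-anchored by construction,
and keeps the 3 remaining parameters identifiable on a 7-point series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._censored import CensoredValue

__all__ = [
    "NormalizationError",
    "InsufficientDataError",
    "normalize_to_vehicle",
    "DoseResponseModel",
    "DoseResponseResults",
    "derive_pod",
    "invert_logistic",
    "fit_screen",
]

TOP_DEFAULT = 100.0
HILL_BOUNDS = (0.1, 10.0)


class NormalizationError(ValueError):
    """Raised when vehicle wells are missing or unusable."""


class InsufficientDataError(ValueError):
    """Raised when too few distinct nonzero concentrations are available."""


def normalize_to_vehicle(
    records: pd.DataFrame,
    group_by: tuple[str, ...] = ("cell_source", "drug"),
    signal_col: str = "signal",
    concentration_col: str = "concentration_uM",
) -> pd.DataFrame:
    """Convert raw well signals to percent-of-vehicle viability.

    Within each group, viability_i = 100 × signal_i / mean(vehicle signals),
    where vehicle wells are those with concentration 0.  Vehicle wells are
    retained with their own normalized values (they average 100 by
    construction).

    Raises
    ------
    NormalizationError
        If a group has no vehicle wells, or their mean signal is not
        positive.
    """
    if records.empty:
        raise NormalizationError("no records to normalize")
    if not np.isfinite(records[signal_col]).all():
        raise ValueError("non-finite signal values")
    if (records[concentration_col] < 0).any():
        raise ValueError("negative concentrations")

    out = []
    for key, grp in records.groupby(list(group_by), sort=True):
        vehicle = grp.loc[grp[concentration_col] == 0, signal_col]
        if vehicle.empty:
            raise NormalizationError(f"no vehicle wells for group {key}")
        vmean = float(vehicle.mean())
        if vmean <= 0:
            raise NormalizationError(f"non-positive vehicle mean for group {key}")
        g = grp.copy()
        g["viability"] = 100.0 * g[signal_col] / vmean
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _logistic(c: np.ndarray, top: float, bottom: float, ec50: float, hill: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    ratio = np.zeros_like(c)
    nz = c > 0
    ratio[nz] = np.power(c[nz] / ec50, hill)
    return bottom + (top - bottom) / (1.0 + ratio)


def invert_logistic(
    top: float, bottom: float, ec50: float, hill: float, viability_threshold: float
) -> float | None:
    """Closed-form solution of v(c) = threshold for the decreasing logistic.

    Returns None when the curve never crosses the threshold (bottom ≥
    threshold or threshold ≥ top).
    """
    if not 0 < viability_threshold < 100:
        raise ValueError(f"viability threshold must be in (0, 100), got {viability_threshold}")
    if bottom >= viability_threshold or viability_threshold >= top:
        return None
    return ec50 * ((top - viability_threshold) / (viability_threshold - bottom)) ** (1.0 / hill)


@dataclass(frozen=True)
class DoseResponseResults:
    """Fitted logistic parameters and censoring-aware PODs for one series.

    Produced by :meth:`DoseResponseModel.fit`.  ``bse`` holds asymptotic
    standard errors for (bottom, log10 ec50, hill) from the least-squares
    Jacobian; NaN when the information matrix is singular (e.g. flat data).
    """

    cell_source: str
    drug: str
    top: float
    bottom: float
    ec50: float
    hill: float
    bse: dict[str, float]
    sse: float
    nobs: int
    aic: float
    fit_ok: bool
    c_max_tested: float

    def predict(self, c) -> np.ndarray:
        """Fitted viability (%) at concentration(s) ``c`` in µM."""
        return _logistic(np.asarray(c, dtype=float), self.top, self.bottom, self.ec50, self.hill)

    def pod(self, viability_threshold: float) -> CensoredValue:
        """POD at the given viability threshold (% of vehicle); see derive_pod."""
        return derive_pod(self, viability_threshold, self.c_max_tested)

    @property
    def ec50_pod(self) -> CensoredValue:
        """Concentration of 50 % viability, censored at the highest tested dose."""
        return self.pod(50.0)

    @property
    def ic10_pod(self) -> CensoredValue:
        """Concentration of a 10 % viability decrease (90 % of vehicle)."""
        return self.pod(90.0)

    @property
    def residual_sse(self) -> float:
        return self.sse

    def summary(self) -> str:
        lines = [
            f"Logistic concentration-response fit: {self.cell_source} / {self.drug}",
            "=" * 64,
            f"{'nobs':<22}{self.nobs:>12d}    {'fit ok':<12}{str(self.fit_ok):>8}",
            f"{'SSE':<22}{self.sse:>12.4g}    {'AIC':<12}{self.aic:>8.2f}",
            "-" * 64,
            f"{'param':<12}{'estimate':>14}{'std err':>14}",
            f"{'top (fixed)':<12}{self.top:>14.4g}{'--':>14}",
            f"{'bottom':<12}{self.bottom:>14.4g}{self.bse['bottom']:>14.4g}",
            f"{'ec50 (µM)':<12}{self.ec50:>14.4g}{self.bse['log10_ec50']:>14.4g}",
            f"{'hill':<12}{self.hill:>14.4g}{self.bse['hill']:>14.4g}",
            "-" * 64,
            f"{'EC50 POD (µM)':<22}{str(self.ec50_pod):>12}",
            f"{'IC10 POD (µM)':<22}{str(self.ic10_pod):>12}",
        ]
        return "\n".join(lines)


class DoseResponseModel:
    """Decreasing logistic viability model for one (cell source, drug) series.

    Parameters
    ----------
    concentration : array-like of float
        Concentrations in µM.  Vehicle wells (0) may be present; they anchor
        normalization only and are excluded from the fit.
    viability : array-like of float
        Percent-of-vehicle viability, replicate level.
    top : float
        Fixed upper asymptote (default 100, the vehicle anchor).
    cell_source, drug : str
        Identifiers carried through to the results.
    """

    def __init__(
        self,
        concentration,
        viability,
        top: float = TOP_DEFAULT,
        cell_source: str = "",
        drug: str = "",
    ):
        c = np.asarray(concentration, dtype=float)
        v = np.asarray(viability, dtype=float)
        if c.shape != v.shape:
            raise ValueError("concentration and viability must have the same length")
        if not (np.isfinite(c).all() and np.isfinite(v).all()):
            raise ValueError("non-finite inputs")
        if (c < 0).any():
            raise ValueError("negative concentrations")
        mask = c > 0
        self.conc = c[mask]
        self.viab = v[mask]
        if np.unique(self.conc).size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct nonzero concentrations, got {np.unique(self.conc).size}"
            )
        self.top = float(top)
        self.cell_source = cell_source
        self.drug = drug
        self.c_max_tested = float(self.conc.max())
        self.c_min_tested = float(self.conc.min())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        concentration_col: str = "concentration_uM",
        viability_col: str = "viability",
        **kwargs,
    ) -> "DoseResponseModel":
        """Build from a normalized long-format frame (one series)."""
        return cls(df[concentration_col].to_numpy(), df[viability_col].to_numpy(), **kwargs)

    # ---- fitting ---------------------------------------------------------

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        bottom, log_ec50, hill = theta
        return _logistic(self.conc, self.top, bottom, 10.0**log_ec50, hill) - self.viab

    def fit(self) -> DoseResponseResults:
        """Bounded multi-start nonlinear least squares.

        Five deterministic starts with log-spaced EC50 guesses spanning the
        tested range guard against local minima on steep or shallow curves.
        A fit is rejected (``fit_ok`` False, PODs censored) when the fitted
        bottom exceeds 90 % or the logistic does not beat the flat
        no-response model (v ≡ top) by AIC.
        """
        lo_e = np.log10(self.c_min_tested / 10.0)
        hi_e = np.log10(self.c_max_tested * 10.0)
        bounds = (
            np.array([0.0, lo_e, HILL_BOUNDS[0]]),
            np.array([self.top, hi_e, HILL_BOUNDS[1]]),
        )
        bottom0 = float(np.clip(self.viab.min(), 0.0, self.top))
        starts = [
            np.array([bottom0, e, 1.0])
            for e in np.linspace(np.log10(self.c_min_tested), np.log10(self.c_max_tested), 5)
        ]

        best = None
        for x0 in starts:
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=bounds, method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        n = self.conc.size
        sse_flat = float(np.sum((self.viab - self.top) ** 2))
        aic_flat = _aic(sse_flat, n, k=0)

        if best is None:
            nanbse = {"bottom": np.nan, "log10_ec50": np.nan, "hill": np.nan}
            return DoseResponseResults(
                self.cell_source, self.drug, self.top, self.top, np.nan, np.nan,
                nanbse, sse_flat, n, aic_flat, False, self.c_max_tested,
            )

        bottom, log_ec50, hill = best.x
        sse = float(2.0 * best.cost)
        aic = _aic(sse, n, k=3)
        fit_ok = bool(best.success) and bottom <= 90.0 and aic < aic_flat

        return DoseResponseResults(
            cell_source=self.cell_source,
            drug=self.drug,
            top=self.top,
            bottom=float(bottom),
            ec50=float(10.0**log_ec50),
            hill=float(hill),
            bse=_jacobian_bse(best.jac, sse, n),
            sse=sse,
            nobs=n,
            aic=aic,
            fit_ok=fit_ok,
            c_max_tested=self.c_max_tested,
        )


def _aic(sse: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to a constant; guard sse=0 (perfect fit).
    sse = max(sse, np.finfo(float).tiny)
    return n * np.log(sse / n) + 2 * k


def _jacobian_bse(jac: np.ndarray, sse: float, n: int) -> dict[str, float]:
    names = ("bottom", "log10_ec50", "hill")
    dof = max(n - jac.shape[1], 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (sse / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return dict(zip(names, se))


def derive_pod(
    fit: DoseResponseResults,
    viability_threshold: float,
    c_max_tested: float | None = None,
) -> CensoredValue:
    """POD at a viability threshold, right-censored at the tested range.

    Solves v(c) = threshold in closed form on the fitted curve.  Returns a
    censored bound "> c_max_tested" when the fit was rejected, the curve
    never reaches the threshold (bottom ≥ threshold), or the solution lies
    above the highest tested concentration.
    """
    cmax = fit.c_max_tested if c_max_tested is None else float(c_max_tested)
    if not 0 < viability_threshold < 100:
        raise ValueError(f"viability threshold must be in (0, 100), got {viability_threshold}")
    if not fit.fit_ok:
        return CensoredValue(cmax, censored=True)
    c = invert_logistic(fit.top, fit.bottom, fit.ec50, fit.hill, viability_threshold)
    if c is None or c > cmax:
        return CensoredValue(cmax, censored=True)
    return CensoredValue(float(c), censored=False)


def fit_screen(
    normalized: pd.DataFrame,
    group_by: tuple[str, str] = ("cell_source", "drug"),
) -> pd.DataFrame:
    """Fit every (cell source, drug) series of a normalized viability frame.

    Returns a POD table with one row per series: fitted parameters, EC50 and
    IC10 PODs with censoring flags, and fit diagnostics.
    """
    rows = []
    for (cs, dr), grp in normalized.groupby(list(group_by), sort=True):
        model = DoseResponseModel.from_dataframe(grp, cell_source=cs, drug=dr)
        res = model.fit()
        ec50_pod, ic10_pod = res.ec50_pod, res.ic10_pod
        rows.append(
            {
                "cell_source": cs,
                "drug": dr,
                "top": res.top,
                "bottom": res.bottom,
                "ec50_fit": res.ec50,
                "hill": res.hill,
                "fit_ok": res.fit_ok,
                "sse": res.sse,
                "ec50_pod_uM": ec50_pod.value,
                "ec50_censored": ec50_pod.censored,
                "ic10_pod_uM": ic10_pod.value,
                "ic10_censored": ic10_pod.censored,
            }
        )
    return pd.DataFrame(rows)
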