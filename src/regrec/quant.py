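"""Quantification math for binding and growth experiments.

Three tools:

* :func:`fit_4pl` — least-squares fit of the four-parameter logistic
  ``y = c + (d - c) / (1 + (x/e)^b)`` with the asymptotes fixed at
  ``c = 0`` and ``d = 1`` (the drc-package convention for quantified EMSA
  titrations).  ``e`` is the EC50; the sign of the slope ``b`` encodes
  orientation: ``b < 0`` for responses that rise with concentration
  (protein titrations, fraction of probe shifted) and ``b > 0`` for
  responses that fall (effector titrations, shift ratio with/without
  effector).

* :func:`empirical_auc` — trapezoidal area under an OD-vs-time growth
  curve, no baseline subtraction.

* :func:`affinity_expression_correlation` — Pearson correlation between
  operator EC50s and expression fold changes of the cognate genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    """4PL fit failed to converge or data are degenerate."""


class DegenerateDataError(ValueError):
    """Responses carry no information (all at one asymptote, zero variance...)."""


@dataclass
class TitrationCurve:
    """Dose-response data: strictly increasing positive x, responses in [0, 1]."""

    x: np.ndarray
    y: np.ndarray
    orientation: str = "auto"  # 'increasing' | 'decreasing' | 'auto'

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size < 4:
            raise ValueError("need >= 4 titration points")
        if self.x.size != self.y.size:
            raise ValueError("x and y length mismatch")
        if np.any(self.x <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class FourPLFit:
    """Result of a fixed-asymptote 4PL fit (c=0, d=1)."""

    b: float
    e: float
    c: float = 0.0
    d: float = 1.0
    sse: float = 0.0
    e_ci: tuple[float, float] = (float("nan"), float("nan"))
    n: int = 0

    def predict(self, x) -> np.ndarray:
        return four_pl(np.asarray(x, dtype=float), self.b, self.e, self.c, self.d)


@dataclass
class GrowthCurve:
    """OD600 readings over time (hours)."""

    t: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.t.size < 2:
            raise ValueError("need >= 2 time points")
        if self.t.size != self.od.size:
            raise ValueError("t and od length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be >= 0")


@dataclass(frozen=True)
class AffinityExpressionPair:
    """One probe's EC50 (nM) and the cognate gene's expression fold change."""

    probe: str
    ec50: float
    fc: float

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")


def four_pl(x, b, e, c=0.0, d=1.0):
    """The four-parameter logistic y = c + (d - c) / (1 + (x/e)^b)."""
    x = np.asarray(x, dtype=float)
    return c + (d - c) / (1.0 + (x / e) ** b)


def fit_4pl(curve: TitrationCurve) -> FourPLFit:
    """Fit the fixed-asymptote 4PL to a titration curve.

    Initialization: ``e`` at the concentration whose response is nearest
    0.5, ``|b| = 1`` with the sign implied by the orientation.  If the
    first attempt fails to converge, a small grid of alternative starts is
    tried before giving up.  The 95% CI on ``e`` comes from the linearized
    covariance of the least-squares solution.
    """
    x, y = curve.x, curve.y
    if np.allclose(y, y[0]):
        raise DegenerateDataError("constant responses; EC50 unidentifiable")
    if np.all(y <= 0.02) or np.all(y >= 0.98):
        raise DegenerateDataError("responses pinned at one asymptote")

    orientation = curve.orientation
    if orientation == "auto":
        orientation = "increasing" if np.polyfit(np.log(x), y, 1)[0] >= 0 else "decreasing"
    b_sign = -1.0 if orientation == "increasing" else 1.0

    # condition on a dimensionless concentration axis
    x_scale = float(np.exp(np.mean(np.log(x))))
    u = x / x_scale

    def residuals(theta):
        b, log_e = theta
        return four_pl(u, b, np.exp(log_e)) - y

    e0 = u[int(np.argmin(np.abs(y - 0.5)))]
    starts = [(b_sign * 1.0, np.log(e0))]
    for mag in (0.5, 2.0, 4.0):
        for e_alt in (e0, float(np.median(u))):
            starts.append((b_sign * mag, np.log(e_alt)))

    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(residuals, theta0, method="lm",
                                         max_nfev=10000)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-14:
            break
    if best is None:
        raise FitError("4PL fit did not converge from any start")

    b_hat, log_e_hat = best.x
    e_hat = float(np.exp(log_e_hat)) * x_scale
    resid = best.fun
    sse = float(resid @ resid)

    # linearized covariance; var(log e) -> CI on e via the delta method
    dof = max(x.size - 2, 1)
    s2 = sse / dof
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se_log_e = float(np.sqrt(max(cov[1, 1], 0.0)))
        tq = stats.t.ppf(0.975, dof)
        ci = (e_hat * float(np.exp(-tq * se_log_e)),
              e_hat * float(np.exp(tq * se_log_e)))
    except np.linalg.LinAlgError:
        ci = (float("nan"), float("nan"))

    return FourPLFit(b=float(b_hat), e=e_hat, sse=sse, e_ci=ci, n=int(x.size))


def empirical_auc(curve: GrowthCurve) -> float:
    """Trapezoidal integral of OD over time (OD*h), no baseline subtraction."""
    return float(np.trapezoid(curve.od, curve.t))


def affinity_expression_correlation(
    pairs: list[AffinityExpressionPair],
    log_ec50: bool = False,
    log2_fc: bool = False,
) -> tuple[float, float]:
    """Pearson r (and two-sided t-test p) between EC50s and fold changes.

    Variables are used as given by default; ``log_ec50``/``log2_fc`` apply
    log10 / log2 transforms first.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    ec = np.array([p.ec50 for p in pairs], dtype=float)
    fc = np.array([p.fc for p in pairs], dtype=float)
    if log_ec50:
        ec = np.log10(ec)
    if log2_fc:
        if np.any(fc <= 0):
            raise ValueError("fold changes must be positive for log2 transform")
        fc = np.log2(fc)
    if np.allclose(ec, ec[0]) or np.allclose(fc, fc[0]):
        raise DegenerateDataError("zero variance; correlation undefined")
    r, p = stats.pearsonr(ec, fc)
    return float(r), float(p)
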