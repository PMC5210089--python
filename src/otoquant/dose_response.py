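"""Four-parameter logistic dose–response fitting and EC50 estimation.

The model is

    y(d) = bottom + (top - bottom) / (1 + (d / EC50)^hill)

with ``hill > 0`` meaning the response falls from ``top`` toward
``bottom`` as dose rises (hair-cell survival under an ototoxin); dose 0
is evaluated as the limit, avoiding log-dose singularities.  Fitting is
bounded least squares with multi-starts over the hill sign and
log-spaced EC50 initials; the EC50 confidence interval comes from a
seeded case-resampling bootstrap (resampling replicates within dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateFitError
from .synthetic_data import four_pl

_N_STARTS_PER_SIGN = 4


@dataclass
class SigmoidFit:
    top: float
    bottom: float
    ec50_um: float
    hill: float
    rss: float
    converged: bool
    ci_ec50: tuple[float, float] | None = None
    message: str = ""


def _prepare(data: pd.DataFrame | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        doses = data["dose_um"].to_numpy(dtype=float)
        resp = data["survival_pct"].to_numpy(dtype=float)
    else:
        doses, resp = (np.asarray(a, dtype=float) for a in data)
    if (doses < 0).any():
        raise ValueError("doses must be non-negative")
    if len(np.unique(doses)) < 4:
        raise ValueError("at least 4 distinct doses required for a 4PL fit")
    return doses, resp


def _fit_once(
    doses: np.ndarray,
    resp: np.ndarray,
    p0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    fixed: dict[str, float],
):
    names = ["top", "bottom", "log_ec50", "hill"]
    free_idx = [i for i, n in enumerate(names) if n not in fixed]

    def unpack(theta: np.ndarray) -> np.ndarray:
        full = p0.copy()
        full[free_idx] = theta
        for n, v in fixed.items():
            full[names.index(n)] = math.log(v) if n == "log_ec50" else v
        return full

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, bottom, log_ec50, hill = unpack(theta)
        return four_pl(doses, top, bottom, math.exp(log_ec50), hill) - resp

    res = least_squares(
        residuals,
        p0[free_idx],
        bounds=(bounds[0][free_idx], bounds[1][free_idx]),
        method="trf",
    )
    return unpack(res.x), float(np.sum(res.fun**2)), res.success


def fit_sigmoid(
    data: pd.DataFrame | tuple,
    constraints: dict[str, float] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> SigmoidFit:
    """Least-squares 4PL fit with multi-start initialization.

    Parameters
    ----------
    data
        Tidy table with columns ``dose_um, survival_pct`` (replicate rows),
        or a ``(doses, responses)`` pair.
    constraints
        Optional fixed parameters, e.g. ``{"top": 100, "bottom": 0}`` for
        the constrained fit; the free fit is the default.
    n_boot
        Bootstrap resamples for the EC50 percentile CI; 0 skips the CI.
    seed
        Seed for the bootstrap resampling.

    A flat response is not identifiable: the returned fit has
    ``converged=False`` and NaN EC50.
    """
    doses, resp = _prepare(data)
    fixed = dict(constraints or {})
    if float(np.ptp(resp)) == 0.0:
        return SigmoidFit(
            top=float(resp[0]), bottom=float(resp[0]), ec50_um=math.nan,
            hill=math.nan, rss=0.0, converged=False,
            message="flat response: EC50 not identifiable",
        )

    pos = doses[doses > 0]
    lo_d, hi_d = float(pos.min()), float(pos.max())
    lower = np.array([0.0, 0.0, math.log(lo_d / 100.0), -10.0])
    upper = np.array([200.0, 100.0, math.log(hi_d * 100.0), 10.0])
    top0, bottom0 = float(resp.max()), float(resp.min())
    ec50_inits = np.exp(np.linspace(math.log(lo_d), math.log(hi_d), _N_STARTS_PER_SIGN))

    best = None
    for hill0 in (2.0, -2.0):
        for e0 in ec50_inits:
            p0 = np.array([top0, max(bottom0, 0.0), math.log(e0), hill0])
            p0 = np.clip(p0, lower, upper)
            try:
                params, rss, ok = _fit_once(doses, resp, p0, (lower, upper), fixed)
            except Exception:  # singular start; other starts cover it
                continue
            if ok and (best is None or rss < best[1]):
                best = (params, rss)
    if best is None:
        raise DegenerateFitError("no multi-start converged")
    params, rss = best
    fit = SigmoidFit(
        top=float(params[0]),
        bottom=float(params[1]),
        ec50_um=float(math.exp(params[2])),
        hill=float(params[3]),
        rss=rss,
        converged=True,
    )
    if n_boot > 0:
        fit.ci_ec50 = _bootstrap_ci(
            doses, resp, params, (lower, upper), fixed, n_boot, seed, ci_level
        )
    return fit


def _bootstrap_ci(
    doses: np.ndarray,
    resp: np.ndarray,
    p_hat: np.ndarray,
    bounds,
    fixed: dict[str, float],
    n_boot: int,
    seed: int | None,
    ci_level: float,
) -> tuple[float, float]:
    """Residual-bootstrap percentile CI for EC50.

    Residuals from the point fit are pooled, resampled with replacement
    and added back onto the fitted curve, and the model is refit (warm
    start).  With only a handful of replicates per dose the residual
    bootstrap tracks the sampling distribution better than resampling
    cases within dose.  The percentile interval is taken on log-EC50.
    """
    rng = np.random.default_rng(seed)
    top, bottom, log_ec50, hill = p_hat
    fitted = four_pl(doses, top, bottom, math.exp(log_ec50), hill)
    residuals = resp - fitted
    ests = []
    for _ in range(n_boot):
        y = fitted + rng.choice(residuals, size=len(residuals), replace=True)
        try:
            params, _, ok = _fit_once(doses, y, p_hat.copy(), bounds, fixed)
        except Exception:
            continue
        if ok:
            ests.append(params[2])  # log-EC50
    if len(ests) < max(20, n_boot // 10):
        return (math.nan, math.nan)
    a = 100 * (1 - ci_level) / 2
    lo, hi = np.percentile(ests, [a, 100 - a])
    return (math.exp(lo), math.exp(hi))


def predict(fit: SigmoidFit, dose_um: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted curve; dose 0 returns the hill-sign limit."""
    if not fit.converged:
        raise DegenerateFitError("cannot predict from a non-converged fit")
    out = four_pl(np.atleast_1d(np.asarray(dose_um, dtype=float)),
                  fit.top, fit.bottom, fit.ec50_um, fit.hill)
    return float(out[0]) if np.isscalar(dose_um) else out


def time_course_summary(
    table: pd.DataFrame,
    control_day: float | None = None,
) -> pd.DataFrame:
    """Mean ± SEM survival per cell type per day.

    ``table`` columns: ``day, cell_type, survival_pct`` with replicate
    rows.  ``control_day``, when given, must be present (the baseline the
    time course is anchored to).  Single-replicate cells get a missing
    SEM, flagged in the ``sem_missing`` column.
    """
    required = {"day", "cell_type", "survival_pct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table["day"].nunique() < 2:
        raise ValueError("at least 2 time points required")
    if control_day is not None and control_day not in set(table["day"]):
        raise ValueError(f"control day {control_day} missing from table")
    g = table.groupby(["cell_type", "day"])["survival_pct"]
    out = g.agg(mean="mean", n="count", sd=lambda s: s.std(ddof=1)).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out["sem_missing"] = out["n"] < 2
    out.loc[out["sem_missing"], "sem"] = np.nan
    return out.drop(columns="sd")
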