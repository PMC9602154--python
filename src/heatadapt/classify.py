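"""Count-of-criteria classification and univariate logistic fits.

Each pooled observation is scored against the three cut-point rules (heart
rate, sweat rate, thermal sensation); the number of criteria met (0-3) is
the classifier score, and improvement is predicted when the count reaches a
threshold ``k`` (default 2, the "two or three variables" rule).

The univariate logistic fits mirror the single-variable screening step:
improvement regressed on the binary indicator of one rule being met.  Both
Cox-Snell and Nagelkerke pseudo-R2 are reported because either may be the
"r2" printed by statistics packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cutpoints import CutpointRule
from .errors import ConfigurationError, DataError

__all__ = [
    "CLASSIFICATION_COLUMNS",
    "LogisticFit",
    "count_criteria",
    "fit_univariate_logistic",
]

CLASSIFICATION_COLUMNS = (
    "participant_id",
    "induction",
    "hr_met",
    "sr_met",
    "ts_met",
    "criteria_met",
    "predicted_improved",
)

_MET_COLUMN = {"d_hr": "hr_met", "d_sr": "sr_met", "d_ts": "ts_met"}


def _rules_by_variable(rules) -> dict[str, CutpointRule]:
    by_var: dict[str, CutpointRule] = {}
    for rule in rules:
        if rule.variable in by_var:
            raise ConfigurationError(f"duplicate rule for {rule.variable}")
        by_var[rule.variable] = rule
    missing = set(_MET_COLUMN) - set(by_var)
    if missing:
        raise ConfigurationError(f"missing rule(s) for {sorted(missing)}")
    return by_var


def count_criteria(
    observations: pd.DataFrame,
    rules,
    k: int = 2,
) -> pd.DataFrame:
    """Apply the three rules to every observation and count criteria met.

    ``rules`` must cover ``d_hr``, ``d_sr``, ``d_ts`` exactly once, each with
    its own side and boundary strictness.  ``predicted_improved`` is
    ``criteria_met >= k``.
    """
    if not 0 <= k <= 3:
        raise ConfigurationError(f"count threshold k must lie in 0..3, got {k}")
    by_var = _rules_by_variable(rules)
    out = observations[["participant_id", "induction"]].copy()
    for var, col in _MET_COLUMN.items():
        out[col] = by_var[var].is_met(observations[var].to_numpy())
    out["criteria_met"] = (
        out["hr_met"].astype(int) + out["sr_met"].astype(int) + out["ts_met"].astype(int)
    )
    out["predicted_improved"] = out["criteria_met"] >= k
    return out[list(CLASSIFICATION_COLUMNS)]


@dataclass(frozen=True)
class LogisticFit:
    """Univariate binary logistic fit of improvement on one rule indicator."""

    variable: str
    intercept: float
    slope: float
    wald_p: float
    pseudo_r2_cox_snell: float
    pseudo_r2_nagelkerke: float
    converged: bool


def fit_univariate_logistic(
    observations: pd.DataFrame, rule: CutpointRule
) -> LogisticFit:
    """Fit improved ~ 1 + I(rule met) by maximum likelihood.

    Newton iterations to gradient tolerance 1e-8, at most 100 iterations.
    Complete separation yields ``converged=False`` (the slope is unbounded)
    rather than an exception.
    """
    y = np.asarray(observations["improved"], dtype=float)
    if len(y) < 10:
        raise DataError("logistic fit needs at least 10 observations")
    if y.min() == y.max():
        raise DataError("logistic fit needs both outcome classes present")
    x = rule.is_met(observations[rule.variable].to_numpy()).astype(float)
    X = sm.add_constant(x, has_constant="add")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=False
            )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return LogisticFit(
            variable=rule.variable,
            intercept=float("nan"),
            slope=float("nan"),
            wald_p=float("nan"),
            pseudo_r2_cox_snell=float("nan"),
            pseudo_r2_nagelkerke=float("nan"),
            converged=False,
        )

    n = len(y)
    ll1, ll0 = res.llf, res.llnull
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else 0.0
    converged = bool(res.mle_retvals.get("converged", False)) and np.all(
        np.isfinite(res.params)
    ) and np.abs(res.params).max() < 30
    return LogisticFit(
        variable=rule.variable,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        wald_p=float(res.pvalues[1]),
        pseudo_r2_cox_snell=float(max(cox_snell, 0.0)),
        pseudo_r2_nagelkerke=float(min(max(nagelkerke, 0.0), 1.0)),
        converged=converged,
    )
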