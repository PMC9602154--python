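"""Single-split entropy-minimizing cut-point search.

For one predictor delta at a time (``d_hr``, ``d_sr``, or ``d_ts``) the
search scans candidate thresholds, partitions the pooled observations into a
favorable and an unfavorable side, and scores each split by the information
gain of the binary improvement label:

    H(p)      = -p log2 p - (1 - p) log2 (1 - p)          (bits)
    H_split   = (n_L / n) H(p_L) + (n_R / n) H(p_R)
    gain      = H(p_parent) - H_split

Only depth-1 splits are considered.  The favorable side of each variable is
fixed a priori by the physiological sign convention (heart rate and thermal
sensation fall with adaptation, sweat rate rises) rather than searched.

Two selection policies are provided.  ``max_ppv_min_support`` reproduces the
published balance between improvement probability and support: among
candidates whose favorable side holds at least ``ceil(min_support_fraction *
n_total)`` observations it maximizes the favorable-side improvement
probability, breaking ties toward larger support and then toward the
threshold nearest zero.  ``max_info_gain`` is the plain entropy criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "CutpointRule",
    "SplitCandidate",
    "PUBLISHED_RULES",
    "FAVORABLE_SIDE",
    "binary_entropy",
    "evaluate_split",
    "enumerate_candidates",
    "select_cutpoint",
    "search_cutpoint",
    "candidate_table",
]

_RULE_VARIABLES = ("d_hr", "d_sr", "d_ts")

#: favorable direction per predictor, fixed by the sign convention
FAVORABLE_SIDE = {"d_hr": "below", "d_sr": "above", "d_ts": "below"}


@dataclass(frozen=True)
class CutpointRule:
    """A threshold rule on one predictor delta.

    ``favorable_side`` names the side on which an observation *meets* the
    rule; ``strict`` controls the boundary (strict: the threshold itself does
    not meet the rule).
    """

    variable: str
    threshold: float
    favorable_side: str = "below"
    strict: bool = True

    def __post_init__(self):
        if self.variable not in _RULE_VARIABLES:
            raise ConfigurationError(
                f"rule variable must be one of {_RULE_VARIABLES}, got {self.variable!r}"
            )
        if self.favorable_side not in ("below", "above"):
            raise ConfigurationError("favorable_side must be 'below' or 'above'")

    def is_met(self, values):
        """Vectorized membership test for the favorable side."""
        v = np.asarray(values, dtype=float)
        if self.favorable_side == "below":
            out = v < self.threshold if self.strict else v <= self.threshold
        else:
            out = v > self.threshold if self.strict else v >= self.threshold
        return bool(out) if np.isscalar(values) else out

    def describe(self) -> str:
        op = {
            ("below", True): "<",
            ("below", False): "<=",
            ("above", True): ">",
            ("above", False): ">=",
        }[(self.favorable_side, self.strict)]
        return f"{self.variable} {op} {self.threshold:g}"


#: the published rules: HR < -13 bpm, SR > 0.3 L/h, TS <= -0.5
PUBLISHED_RULES = (
    CutpointRule("d_hr", -13.0, "below", strict=True),
    CutpointRule("d_sr", 0.3, "above", strict=True),
    CutpointRule("d_ts", -0.5, "below", strict=False),
)


@dataclass(frozen=True)
class SplitCandidate:
    """One candidate threshold with its split statistics."""

    threshold: float
    n_favorable: int
    n_total: int
    p_improved_favorable: float
    parent_entropy: float
    weighted_child_entropy: float
    info_gain: float


def binary_entropy(p: float) -> float:
    """Shannon entropy of a Bernoulli(p) label, in bits; H(0) = H(1) = 0."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"probability must lie in [0, 1], got {p}")
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def _sides(values: np.ndarray, threshold: float, favorable_side: str, strict: bool):
    if favorable_side == "below":
        fav = values < threshold if strict else values <= threshold
    elif favorable_side == "above":
        fav = values > threshold if strict else values >= threshold
    else:
        raise ConfigurationError("favorable_side must be 'below' or 'above'")
    return fav


def evaluate_split(
    observations: pd.DataFrame,
    variable: str,
    threshold: float,
    favorable_side: str = "below",
    strict: bool = True,
) -> SplitCandidate:
    """Score one threshold on one predictor.

    The favorable side may be empty; the candidate is still returned with the
    weighted child entropy computed over the single non-empty side (gain 0).
    """
    values = np.asarray(observations[variable], dtype=float)
    labels = np.asarray(observations["improved"], dtype=bool)
    if len(values) < 2:
        raise DataError("evaluate_split needs at least 2 observations")
    if not np.all(np.isfinite(values)):
        raise DataError(f"non-finite values in {variable}")

    fav = _sides(values, threshold, favorable_side, strict)
    n_total = len(values)
    n_fav = int(fav.sum())
    p_parent = labels.mean()
    parent_h = binary_entropy(float(p_parent))

    child_h = 0.0
    for mask in (fav, ~fav):
        n_side = int(mask.sum())
        if n_side == 0:
            continue
        p_side = float(labels[mask].mean())
        child_h += (n_side / n_total) * binary_entropy(p_side)

    p_fav = float(labels[fav].mean()) if n_fav else float("nan")
    gain = parent_h - child_h
    if gain < 0:  # guard fp dust; information gain is provably >= 0
        gain = 0.0
    return SplitCandidate(
        threshold=float(threshold),
        n_favorable=n_fav,
        n_total=n_total,
        p_improved_favorable=p_fav,
        parent_entropy=parent_h,
        weighted_child_entropy=child_h,
        info_gain=gain,
    )


def enumerate_candidates(
    observations: pd.DataFrame,
    variable: str,
    favorable_side: str | None = None,
    strict: bool = True,
    grid_step: float | None = None,
) -> list[SplitCandidate]:
    """Evaluate every candidate threshold for one predictor.

    With ``grid_step`` unset, thresholds are midpoints between consecutive
    distinct sorted values (the exhaustive scan: every distinct partition of
    the data appears exactly once).  With ``grid_step`` set, thresholds form
    a regular grid from the observed minimum to maximum at that step.
    """
    if favorable_side is None:
        favorable_side = FAVORABLE_SIDE[variable]
    values = np.unique(np.asarray(observations[variable], dtype=float))
    if not np.all(np.isfinite(values)):
        raise DataError(f"non-finite values in {variable}")
    if len(values) < 2:
        return []
    if grid_step is None:
        thresholds = (values[:-1] + values[1:]) / 2.0
    else:
        if grid_step <= 0:
            raise ConfigurationError("grid_step must be > 0")
        lo, hi = values[0], values[-1]
        n_steps = int(round((hi - lo) / grid_step))
        thresholds = np.round(lo + grid_step * np.arange(n_steps + 1), 10)
    return [
        evaluate_split(observations, variable, float(t), favorable_side, strict)
        for t in thresholds
    ]


def select_cutpoint(
    candidates: Sequence[SplitCandidate],
    variable: str,
    favorable_side: str | None = None,
    strict: bool = True,
    policy: str = "max_ppv_min_support",
    min_support_fraction: float = 0.25,
) -> tuple[CutpointRule, pd.DataFrame]:
    """Choose one cut-point from a candidate scan.

    Returns the chosen rule together with the full candidate table so the
    probability/support trade-off can be audited.
    """
    if not candidates:
        raise DataError("no candidates to select from")
    table = candidate_table(candidates, variable)
    if favorable_side is None:
        favorable_side = FAVORABLE_SIDE[variable]

    if policy == "max_ppv_min_support":
        if not 0.0 <= min_support_fraction <= 1.0:
            raise ConfigurationError("min_support_fraction must lie in [0, 1]")
        n_total = candidates[0].n_total
        floor = math.ceil(min_support_fraction * n_total)
        eligible = [c for c in candidates if c.n_favorable >= floor]
        if not eligible:
            raise DataError(
                f"no candidate has favorable support >= {floor} "
                f"(min_support_fraction={min_support_fraction}); lower the fraction"
            )
        best = min(
            eligible,
            key=lambda c: (-c.p_improved_favorable, -c.n_favorable, abs(c.threshold)),
        )
    elif policy == "max_info_gain":
        eligible = [c for c in candidates if c.n_favorable > 0]
        if not eligible:
            eligible = list(candidates)
        best = min(
            eligible,
            key=lambda c: (-c.info_gain, -c.n_favorable, abs(c.threshold)),
        )
    else:
        raise ConfigurationError(f"unknown selection policy {policy!r}")

    rule = CutpointRule(variable, best.threshold, favorable_side, strict)
    return rule, table


def search_cutpoint(
    observations: pd.DataFrame,
    variable: str,
    favorable_side: str | None = None,
    strict: bool = True,
    grid_step: float | None = None,
    policy: str = "max_ppv_min_support",
    min_support_fraction: float = 0.25,
) -> tuple[CutpointRule, pd.DataFrame]:
    """Enumerate and select in one call (convenience wrapper)."""
    candidates = enumerate_candidates(
        observations, variable, favorable_side, strict, grid_step
    )
    return select_cutpoint(
        candidates, variable, favorable_side, strict, policy, min_support_fraction
    )


def candidate_table(
    candidates: Iterable[SplitCandidate], variable: str
) -> pd.DataFrame:
    """Candidate scan as a tidy table (export header documented)."""
    return pd.DataFrame(
        [
            {
                "variable": variable,
                "threshold": c.threshold,
                "n_favorable": c.n_favorable,
                "n_total": c.n_total,
                "p_improved": c.p_improved_favorable,
                "parent_entropy": c.parent_entropy,
                "child_entropy": c.weighted_child_entropy,
                "info_gain": c.info_gain,
            }
            for c in candidates
        ]
    )
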