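"""Per-participant adaptation deltas for the three induction contrasts.

The three contrasts span the induction timeline (baseline trial ``a``,
post-acclimatization trial ``b``, post-acclimation trial ``c``):

* ``HAz``  adaptations = b - a   (outdoor summer-training acclimatization)
* ``HA``   adaptations = c - b   (five-day laboratory acclimation)
* ``DHE``  adaptations = c - a   (dual heat exposure, both in sequence)

All three contrasts from the same participant are pooled into a single
observation set, so a complete participant contributes exactly three rows.
By construction ``d_DHE = d_HAz + d_HA`` holds exactly for every variable
on the quantized stored phase values.

Sign convention: negative deltas of heart rate, thermal sensation, and
rectal temperature, and positive deltas of sweat rate, indicate improvement.
An observation is labelled ``improved`` when end-of-trial rectal temperature
dropped (``d_trec < -tolerance``; ties are not improved).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PHASES
from .errors import ConfigurationError, DataError, DataFormatError

__all__ = [
    "INDUCTIONS",
    "OBSERVATION_COLUMNS",
    "CONTRASTS",
    "label_improvement",
    "compute_deltas",
    "write_observations",
    "read_observations",
]

INDUCTIONS = ("HAz", "HA", "DHE")

#: induction -> (post phase, pre phase)
CONTRASTS = {
    "HAz": ("post_haz", "baseline"),
    "HA": ("post_ha", "post_haz"),
    "DHE": ("post_ha", "baseline"),
}

OBSERVATION_COLUMNS = (
    "participant_id",
    "induction",
    "d_hr",
    "d_sr",
    "d_ts",
    "d_trec",
    "improved",
)

_DELTA_OF = {
    "d_hr": "hr_peak",
    "d_sr": "sweat_rate",
    "d_ts": "ts_peak",
    "d_trec": "trec_end",
}


def label_improvement(d_trec, tolerance: float = 0.0):
    """True iff rectal temperature dropped by more than ``tolerance`` degC.

    Strict inequality: ``d_trec == -tolerance`` is *not* improved.  Accepts
    scalars or arrays.
    """
    if tolerance < 0:
        raise ConfigurationError("improvement tolerance must be >= 0")
    arr = np.asarray(d_trec, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("d_trec must be finite to label improvement")
    out = arr < -tolerance
    return bool(out) if np.isscalar(d_trec) else out


def compute_deltas(
    records: pd.DataFrame,
    tolerance: float = 0.0,
    allow_partial: bool = False,
) -> pd.DataFrame:
    """Convert a trial table into pooled per-contrast delta observations.

    Parameters
    ----------
    records
        Trial table with one row per (participant, phase).
    tolerance
        Improvement margin in degC passed to :func:`label_improvement`.
    allow_partial
        If False (default) every participant must have all three phases;
        otherwise partial participants contribute only the contrasts whose
        two phases are both present.
    """
    if records.duplicated(subset=["participant_id", "phase"]).any():
        raise DataError("duplicate (participant, phase) rows in trial table")
    by_key = {
        (r.participant_id, r.phase): r for r in records.itertuples(index=False)
    }
    pids = list(dict.fromkeys(records["participant_id"]))
    incomplete = [
        pid for pid in pids if any((pid, phase) not in by_key for phase in PHASES)
    ]
    if incomplete and not allow_partial:
        raise DataError(
            "participants missing a phase: "
            + ", ".join(str(p) for p in sorted(incomplete))
            + " (pass allow_partial=True to keep their computable contrasts)"
        )

    rows = []
    for pid in pids:
        for induction in INDUCTIONS:
            post, pre = CONTRASTS[induction]
            if (pid, post) not in by_key or (pid, pre) not in by_key:
                continue
            r_post, r_pre = by_key[(pid, post)], by_key[(pid, pre)]
            vals = {
                delta_col: round(
                    float(getattr(r_post, var)) - float(getattr(r_pre, var)), 10
                )
                for delta_col, var in _DELTA_OF.items()
            }
            vals["participant_id"] = pid
            vals["induction"] = induction
            vals["improved"] = label_improvement(vals["d_trec"], tolerance)
            rows.append(vals)
    out = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    # stable order: participant, then HAz/HA/DHE
    order = {ind: i for i, ind in enumerate(INDUCTIONS)}
    out = out.sort_values(
        ["participant_id", "induction"], key=lambda s: s.map(order) if s.name == "induction" else s
    ).reset_index(drop=True)
    return out


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    """Write a delta-observation table as comma-delimited text."""
    missing = set(OBSERVATION_COLUMNS) - set(obs.columns)
    if missing:
        raise DataFormatError(f"observation table missing columns {sorted(missing)}")
    obs[list(OBSERVATION_COLUMNS)].to_csv(path, index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a delta-observation table written by :func:`write_observations`."""
    df = pd.read_csv(path, dtype={"participant_id": str, "induction": str})
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df.loc[~df["induction"].isin(INDUCTIONS), "induction"]
    if len(bad):
        raise DataFormatError(f"{path}: unknown induction value(s) {sorted(set(bad))}")
    df["improved"] = df["improved"].astype(bool)
    return df[list(OBSERVATION_COLUMNS)]
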