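"""ROC/AUC computation and hindcast validation against fossil records.

The AUC estimator is the Mann–Whitney pair statistic with mid-rank tie
handling: the mean over all (present, absent) record pairs of
``[score_present > score_absent] + ½·[score_present = score_absent]``.
Hindcast validation extracts the predicted probability of presence at
each fossil record's grid cell and scores it against the recorded
presence/absence label, per period and pooled across periods.

Fossil tables are pandas DataFrames with columns ``lon``, ``lat``,
``period``, ``label`` (0/1) and optionally ``record_class``
(pollen | macrofossil | midden | synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .raster import RasterGrid

__all__ = ["auc", "ValidationResult", "validate_hindcast"]


def auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equals the Mann–Whitney U statistic normalised by the number of
    (positive, negative) pairs, with ties counted one half.  Raises
    ``ValueError`` when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError(
            "AUC requires at least one presence and one absence record; "
            f"got {n1} presences and {n0} absences"
        )
    ranks = rankdata(scores)  # mid-ranks
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ValidationResult:
    """Outcome of a hindcast validation run."""

    pooled_auc: float
    per_period_auc: dict[str, float]
    n_used: dict[str, int]
    n_dropped: dict[str, int]
    notes: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for period in sorted(self.per_period_auc):
            rows.append({
                "period": period,
                "auc": self.per_period_auc[period],
                "n_used": self.n_used.get(period, 0),
                "n_dropped": self.n_dropped.get(period, 0),
            })
        rows.append({
            "period": "pooled",
            "auc": self.pooled_auc,
            "n_used": sum(self.n_used.values()),
            "n_dropped": sum(self.n_dropped.values()),
        })
        return pd.DataFrame(rows)


def validate_hindcast(surfaces: dict[str, RasterGrid],
                      fossils: pd.DataFrame) -> ValidationResult:
    """Score period probability surfaces against fossil-type records.

    For each record the probability at its containing cell of the
    matching period surface is extracted; records outside the grid or on
    nodata (e.g. ice-masked) cells are dropped and counted.  AUC is
    computed per period (NaN when a period retains a single class) and
    pooled by concatenating all (score, label) pairs.
    """
    required = {"lon", "lat", "period", "label"}
    missing = required - set(fossils.columns)
    if missing:
        raise ValueError(f"fossil table missing columns: {sorted(missing)}")
    periods = fossils["period"].unique()
    absent = [p for p in periods if p not in surfaces]
    if absent:
        raise ValueError(f"no surface supplied for period(s): {absent}")

    notes: list[str] = []
    per_auc: dict[str, float] = {}
    n_used: dict[str, int] = {}
    n_dropped: dict[str, int] = {}
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for period in periods:
        sub = fossils[fossils["period"] == period]
        surf = surfaces[period]
        rows, cols, inside = surf.index_of(
            sub["lon"].to_numpy(), sub["lat"].to_numpy()
        )
        scores = np.where(inside, surf.data[rows, cols], np.nan)
        keep = inside & ~np.isnan(scores)
        n_used[period] = int(keep.sum())
        n_dropped[period] = int((~keep).sum())
        if n_dropped[period]:
            notes.append(
                f"{period}: dropped {n_dropped[period]} record(s) outside "
                "the grid or on nodata cells"
            )
        labels = sub["label"].to_numpy()[keep]
        scores = scores[keep]
        all_scores.append(scores)
        all_labels.append(labels)
        try:
            per_auc[period] = auc(scores, labels)
        except ValueError:
            per_auc[period] = float("nan")
            notes.append(f"{period}: single-class after drops, AUC undefined")

    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    if scores.size == 0:
        raise ValueError("all fossil records were dropped; nothing to validate")
    pooled = auc(scores, labels)
    return ValidationResult(pooled, per_auc, n_used, n_dropped, notes)
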