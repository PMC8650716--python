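"""Scoring of the Hamburg Quality of Life Questionnaire in Multiple Sclerosis.

The HAQUAMS is an MS-specific, self-reported health-related quality of life
(HRQoL) instrument with five subscales -- fatigue (4 items), lower limb
mobility (5 items), upper limb mobility (5 items), social functions (6 items)
and mood-related symptoms (8 items) -- each item answered on an ordinal 1-5
scale.  A subscale score is the arithmetic mean of its items, the total score
is the arithmetic mean of the five subscale scores, and *low* scores indicate
*high* quality of life.  Longitudinal change is scored as T1 - T0, so a
positive change means worsening.

Items are assumed to be pre-oriented (higher = worse); no reverse-coding is
applied here.  Missing items are not imputed: a subscale with any missing item
is treated as missing.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Number of items per subscale, in canonical reporting order.
ITEM_COUNTS: Mapping[str, int] = {
    "fatigue": 4,
    "lower_limb": 5,
    "upper_limb": 5,
    "social": 6,
    "mood": 8,
}

SUBSCALES: tuple[str, ...] = tuple(ITEM_COUNTS)
SCALES: tuple[str, ...] = SUBSCALES + ("total",)
TIMEPOINTS: tuple[str, ...] = ("T0", "T1")

VALUE_MIN, VALUE_MAX = 1, 5


class HaquamsSchemaError(ValueError):
    """Raised when item counts or subscale sets do not match the instrument."""


class HaquamsValueError(ValueError):
    """Raised for out-of-range item values."""


class MissingTimepointError(KeyError):
    """Raised when a change score is requested but a timepoint is absent."""


def score_subscale(subscale: str, items: Sequence[float]) -> float:
    """Score one subscale for one participant/timepoint.

    Parameters
    ----------
    subscale
        One of :data:`SUBSCALES`.
    items
        The item responses; the length must equal the instrument's item count
        for this subscale and every value must lie in [1, 5].

    Returns
    -------
    float
        Arithmetic mean of the item values (in [1, 5]; higher = worse).
    """
    if subscale not in ITEM_COUNTS:
        raise HaquamsSchemaError(f"unknown subscale {subscale!r}")
    items = np.asarray(items, dtype=float)
    expected = ITEM_COUNTS[subscale]
    if items.ndim != 1 or items.size != expected:
        raise HaquamsSchemaError(
            f"subscale {subscale!r} requires {expected} items, got {items.size}"
        )
    if np.isnan(items).any():
        raise HaquamsValueError(f"subscale {subscale!r} has missing item values")
    if (items < VALUE_MIN).any() or (items > VALUE_MAX).any():
        raise HaquamsValueError(
            f"item values for {subscale!r} outside [{VALUE_MIN}, {VALUE_MAX}]"
        )
    return float(items.mean())


def total_score(subscale_scores: Mapping[str, float] | Sequence[float]) -> float:
    """Total HRQoL score: the mean across the five subscale scores."""
    if isinstance(subscale_scores, Mapping):
        missing = set(SUBSCALES) - set(subscale_scores)
        extra = set(subscale_scores) - set(SUBSCALES)
        if missing or extra:
            raise HaquamsSchemaError(
                f"expected exactly subscales {sorted(SUBSCALES)}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        values = np.asarray([subscale_scores[s] for s in SUBSCALES], dtype=float)
    else:
        values = np.asarray(list(subscale_scores), dtype=float)
        if values.size != len(SUBSCALES):
            raise HaquamsSchemaError(
                f"expected {len(SUBSCALES)} subscale scores, got {values.size}"
            )
    if np.isnan(values).any():
        raise HaquamsValueError("missing subscale score")
    return float(values.mean())


def delta_score(score_t1: float, score_t0: float) -> float:
    """Longitudinal change score T1 - T0 (positive = worsening HRQoL)."""
    if score_t1 is None or score_t0 is None or np.isnan(score_t1) or np.isnan(score_t0):
        raise MissingTimepointError("both timepoints are required for a change score")
    return float(score_t1) - float(score_t0)


def score_items(items: pd.DataFrame) -> pd.DataFrame:
    """Score an item-level long table into a wide per-scale score table.

    Parameters
    ----------
    items
        Long-format frame with columns ``participant_id``, ``timepoint``
        (T0/T1), ``subscale``, ``item_index`` (1-based) and ``value``.

    Returns
    -------
    pandas.DataFrame
        One row per (participant_id, timepoint) with one column per subscale
        plus ``total``.
    """
    required = {"participant_id", "timepoint", "subscale", "item_index", "value"}
    missing_cols = required - set(items.columns)
    if missing_cols:
        raise HaquamsSchemaError(f"item table lacks columns {sorted(missing_cols)}")
    bad_tp = set(items["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise HaquamsSchemaError(f"unknown timepoints {sorted(bad_tp)}")

    rows = []
    for (pid, tp), grp in items.groupby(["participant_id", "timepoint"], sort=True):
        scores: dict[str, float] = {}
        for subscale, sub in grp.groupby("subscale"):
            vals = sub.sort_values("item_index")["value"].to_numpy()
            scores[str(subscale)] = score_subscale(str(subscale), vals)
        row = {"participant_id": pid, "timepoint": tp}
        row.update({s: scores[s] for s in SUBSCALES if s in scores})
        row["total"] = total_score({s: scores[s] for s in SUBSCALES})
        rows.append(row)
    out = pd.DataFrame(rows, columns=["participant_id", "timepoint", *SCALES])
    return out


def delta_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-participant change scores (T1 - T0) for every scale.

    ``scores`` is the wide output of :func:`score_items` containing both
    timepoints for each participant.
    """
    wide = scores.set_index(["participant_id", "timepoint"])
    t0 = wide.xs("T0", level="timepoint")
    try:
        t1 = wide.xs("T1", level="timepoint")
    except KeyError as err:
        raise MissingTimepointError("no T1 rows in score table") from err
    missing = set(t0.index).symmetric_difference(t1.index)
    if missing:
        raise MissingTimepointError(
            f"participants lacking one timepoint: {sorted(missing)}"
        )
    delta = (t1 - t0).loc[t0.index]
    delta.columns = [f"delta_{c}" for c in delta.columns]
    return delta.reset_index()


def read_items_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)
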