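"""Decision layer I of the agitation (AIA) detection framework.

Three scoring primitives feed the hierarchical detector:

* an expert decision score ``D_CS`` counting how many physiological
  observations fall strictly outside their clinical thresholds;
* per-sensor normal/abnormal labelling of hourly motion aggregates, with
  the normal range estimated by the skewness-adjusted box-plot (medcouple
  fences of Hubert & Vandervieren) on historical data — hourly sensor
  counts are strongly right-skewed, so symmetric Tukey fences over-flag;
* median-absolute-deviation (MAD) flagging used to seed candidate AIA
  event windows.

Each sensor's two labels are globally unique single characters, so the
per-hour concatenation of a group's labels forms a composite symbol that
decodes unambiguously back into per-sensor states; the per-day strings of
composite symbols (S_G2, S_G3) are the observation sequences consumed by
the group HMMs in decision layer II.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "expert_decision_score",
    "medcouple",
    "adjusted_boxplot_bounds",
    "LabelSet",
    "assign_labelsets",
    "fit_labelsets",
    "categorise",
    "decode_symbol",
    "mad_flag",
]


def expert_decision_score(
    observations: Mapping[str, float],
    thresholds: Mapping[str, tuple[float, float]],
) -> int:
    """Count observations strictly outside their clinical thresholds.

    The score starts at 0 and is incremented once per vital whose
    observation O_i satisfies ``O_i < T_iL or O_i > T_iH``; a value exactly
    on a threshold is in range.  Missing (NaN) observations are skipped;
    an observed vital without configured thresholds is a configuration
    error.
    """
    score = 0
    for vital, value in observations.items():
        if vital not in thresholds:
            raise KeyError(f"no clinical thresholds configured for vital {vital!r}")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        lo, hi = thresholds[vital]
        if lo >= hi:
            raise ValueError(f"thresholds for {vital!r} must satisfy lower < upper")
        if value < lo or value > hi:
            score += 1
    return score


def medcouple(sample: Sequence[float]) -> float:
    """Robust skewness in [-1, 1]: the median of the pairwise kernel

        h(x_i, x_j) = ((x_j - m) - (m - x_i)) / (x_j - x_i)

    over pairs with ``x_i <= m <= x_j`` and ``x_i != x_j``, where m is the
    sample median.  0 for symmetric samples, positive for right skew; the
    O(n^2) kernel evaluation is fine at the sample sizes involved (a few
    thousand hourly points).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if len(x) < 3:
        raise ValueError("medcouple needs at least 3 observations")
    m = float(np.median(x))
    lower = x[x <= m]
    upper = x[x >= m]
    xi = lower[:, None]
    xj = upper[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = ((xj - m) - (m - xi)) / (xj - xi)
    h = h[xj != xi]
    if h.size == 0:
        warnings.warn("degenerate sample (all values equal); medcouple set to 0",
                      stacklevel=2)
        return 0.0
    return float(np.median(h))


def adjusted_boxplot_bounds(sample: Sequence[float]) -> tuple[float, float]:
    """Skewness-adjusted outlier fences (B_xl, B_xu).

    With quartiles Q1, Q3 (linear interpolation), IQR = Q3 - Q1 and
    medcouple MC:

        MC >= 0:  [Q1 - 1.5 e^(-4 MC) IQR,  Q3 + 1.5 e^(3 MC) IQR]
        MC <  0:  [Q1 - 1.5 e^(-3 MC) IQR,  Q3 + 1.5 e^(4 MC) IQR]

    For a symmetric sample (MC = 0) these are exactly Tukey's fences.
    A zero IQR collapses the fences to [Q1, Q3] with a warning.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("adjusted box-plot needs at least 4 observations")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("zero interquartile range; fences collapse to [Q1, Q3]",
                      stacklevel=2)
        return float(q1), float(q3)
    mc = medcouple(x)
    if mc >= 0:
        lo = q1 - 1.5 * math.exp(-4.0 * mc) * iqr
        hi = q3 + 1.5 * math.exp(3.0 * mc) * iqr
    else:
        lo = q1 - 1.5 * math.exp(-3.0 * mc) * iqr
        hi = q3 + 1.5 * math.exp(4.0 * mc) * iqr
    return float(lo), float(hi)


@dataclass(frozen=True)
class LabelSet:
    """A sensor's two globally unique labels and its normal range."""

    sensor_id: str
    normal_label: str
    abnormal_label: str
    bounds: tuple[float, float]

    def label(self, p_x: float) -> str:
        lo, hi = self.bounds
        return self.normal_label if lo <= p_x <= hi else self.abnormal_label


def assign_labelsets(sensor_ids: Sequence[str]) -> dict[str, tuple[str, str]]:
    """Deterministically assign disjoint (normal, abnormal) label pairs."""
    letters = string.ascii_lowercase + string.ascii_uppercase
    if 2 * len(sensor_ids) > len(letters):
        raise ValueError("too many sensors for single-character labels")
    return {s: (letters[2 * i], letters[2 * i + 1])
            for i, s in enumerate(sorted(sensor_ids))}


def fit_labelsets(
    features: pd.DataFrame,
    sensors: Sequence[str] | None = None,
) -> dict[str, LabelSet]:
    """Learn each sensor's normal range from historical hourly aggregates.

    `features` is the long-form hourly table (``sensor_id, p_x`` columns at
    minimum) restricted to the training window; per sensor the adjusted
    box-plot fences of its hourly P_x sample become the label bounds.
    """
    if sensors is None:
        sensors = sorted(features["sensor_id"].unique())
    pairs = assign_labelsets(sensors)
    labelsets = {}
    for sensor in sensors:
        sample = features.loc[features["sensor_id"] == sensor, "p_x"].to_numpy()
        if sample.size < 4:
            raise ValueError(f"not enough training hours for sensor {sensor!r}")
        normal, abnormal = pairs[sensor]
        labelsets[sensor] = LabelSet(sensor, normal, abnormal,
                                     adjusted_boxplot_bounds(sample))
    return labelsets


def categorise(
    features: pd.DataFrame,
    labelsets: Mapping[str, LabelSet],
) -> pd.DataFrame:
    """Map hourly aggregates to per-group composite label symbols.

    For each sensor-hour the aggregate P_x gets the sensor's normal label
    when it lies inside its bounds (inclusive) and the abnormal label
    otherwise; within each group and hour, the member sensors' labels are
    concatenated in fixed (sorted sensor id) order into one composite
    symbol.  Returns a DataFrame ``group, day, hour, symbol`` — one row per
    group-hour, day-ordered, i.e. the sequences S_G2 and S_G3 in long form.
    """
    missing = set(features["sensor_id"].unique()) - set(labelsets)
    if missing:
        raise KeyError(f"sensor(s) without a label set: {sorted(missing)}")

    feats = features.sort_values(["group", "day", "hour", "sensor_id"]).copy()
    feats["label"] = [
        labelsets[s].label(v) for s, v in zip(feats["sensor_id"], feats["p_x"])
    ]
    out = (
        feats.groupby(["group", "day", "hour"], sort=True)["label"]
        .agg("".join)
        .rename("symbol")
        .reset_index()
    )
    return out


def decode_symbol(
    symbol: str, labelsets: Mapping[str, LabelSet], sensor_order: Sequence[str]
) -> dict[str, str]:
    """Invert a composite symbol into per-sensor states ("normal"/"abnormal").

    Well-defined because label sets are disjoint across sensors and the
    concatenation order is fixed.
    """
    if len(symbol) != len(sensor_order):
        raise ValueError("symbol length does not match the sensor order")
    states = {}
    for ch, sensor in zip(symbol, sensor_order):
        ls = labelsets[sensor]
        if ch == ls.normal_label:
            states[sensor] = "normal"
        elif ch == ls.abnormal_label:
            states[sensor] = "abnormal"
        else:
            raise ValueError(f"label {ch!r} does not belong to sensor {sensor!r}")
    return states


def mad_flag(series: Sequence[float], k: float = 3.0,
             center: float | None = None, mad: float | None = None) -> np.ndarray:
    """Median-absolute-deviation outlier flags.

    Flags x_i when ``|x_i - median| > k * MAD / 0.6745`` (the 0.6745 factor
    makes MAD consistent with the standard deviation under normality).
    With a degenerate MAD of zero, anything differing from the median is
    flagged.  `center` and `mad` may be supplied to apply a threshold
    learned on historical data to new values.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3 and (center is None or mad is None):
        raise ValueError("need at least 3 observations to estimate the MAD")
    med = float(np.median(x)) if center is None else float(center)
    scale = float(np.median(np.abs(x - med))) if mad is None else float(mad)
    dev = np.abs(x - med)
    if scale == 0:
        warnings.warn("zero MAD; flagging any value different from the median",
                      stacklevel=2)
        return dev > 0
    return dev > k * scale / 0.6745
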