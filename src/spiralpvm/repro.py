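"""Inter-study reproducibility: signed differences and Bland-Altman analysis.

Reproducibility of a parameter measured on two occasions is summarized as
the mean +/- SD of the signed differences (day 2 minus day 1, SD with n-1
denominator) and as Bland-Altman agreement (bias +/- 2 SD limits). TTP
reproducibility is reported on three scales: raw ms from the R-wave,
percent of systole/diastole, and fixed-length ms obtained from the percent
differences through the affine rule (avg_systole/100 or avg_diastole/100 ms
per percentage point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .curves import (
    DEFAULT_CONSTANTS,
    NormalizationConstants,
    peak_class,
    ttp_fixed_difference,
)


@dataclass(frozen=True)
class PairedParameterSet:
    """One parameter measured on the same subjects on two occasions."""

    parameter: str
    value_day1: np.ndarray
    value_day2: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "value_day1", np.asarray(self.value_day1, float))
        object.__setattr__(self, "value_day2", np.asarray(self.value_day2, float))
        if self.value_day1.shape != self.value_day2.shape:
            raise ValueError("day-1 and day-2 arrays must have equal length")


def _diffs(pairs) -> np.ndarray:
    if isinstance(pairs, PairedParameterSet):
        d1, d2 = pairs.value_day1, pairs.value_day2
    else:
        arr = np.asarray(pairs, dtype=float)
        d1, d2 = arr[:, 0], arr[:, 1]
    if len(d1) < 2:
        raise ValueError("need at least 2 pairs")
    return d2 - d1


def signed_differences(pairs):
    """Mean and SD (n-1 denominator) of day2 - day1 differences."""
    d = _diffs(pairs)
    return float(np.mean(d)), float(np.std(d, ddof=1))


def bland_altman(pairs):
    """Per-pair means/differences with bias and bias +/- 2 SD limits."""
    if isinstance(pairs, PairedParameterSet):
        d1, d2 = pairs.value_day1, pairs.value_day2
    else:
        arr = np.asarray(pairs, dtype=float)
        d1, d2 = arr[:, 0], arr[:, 1]
    if len(d1) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = d2 - d1
    means = (d1 + d2) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return {
        "means": means,
        "differences": diffs,
        "bias": bias,
        "sd": sd,
        "upper_limit": bias + 2.0 * sd,
        "lower_limit": bias - 2.0 * sd,
    }


def reproducibility_table(
    day1_tables: dict,
    day2_tables: dict,
    constants: NormalizationConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Mean +/- SD signed differences for every peak parameter.

    `day1_tables`/`day2_tables` map subject id -> per-peak summary frame
    (as produced by `curves.summarize_peaks`, one row per peak with
    amplitude_cm_s, ttp_ms and ttp_percent columns). Subjects missing from
    either day are excluded with a warning. Fixed-length ms differences are
    derived from the percent differences through the affine rule and
    rounded half-away-from-zero to one decimal, as are all summary entries.
    """
    common = sorted(set(day1_tables) & set(day2_tables))
    dropped = sorted(set(day1_tables) ^ set(day2_tables))
    if dropped:
        warnings.warn(f"unmatched subjects excluded: {dropped}", stacklevel=2)
    if len(common) < 2:
        raise ValueError("need at least 2 matched subjects")

    def pivot(tables, column):
        frames = []
        for sid in common:
            df = tables[sid].set_index("peak")[[column]].rename(columns={column: sid})
            frames.append(df)
        return pd.concat(frames, axis=1)

    rows = []
    for column, label in (
        ("amplitude_cm_s", "amplitude_cm_s"),
        ("ttp_ms", "ttp_ms"),
        ("ttp_percent", "ttp_percent"),
    ):
        wide1 = pivot(day1_tables, column)
        wide2 = pivot(day2_tables, column)
        peaks = wide1.index.intersection(wide2.index)
        for peak in peaks:
            v1 = wide1.loc[peak].to_numpy(float)
            v2 = wide2.loc[peak].to_numpy(float)
            ok = np.isfinite(v1) & np.isfinite(v2)
            if ok.sum() < 2:
                continue
            mean, sd = signed_differences(np.column_stack([v1[ok], v2[ok]]))
            rows.append(
                {
                    "peak": peak,
                    "quantity": label,
                    "n": int(ok.sum()),
                    "mean_diff": round_half_away(mean, 2),
                    "sd_diff": round_half_away(sd, 2),
                }
            )
            if label == "ttp_percent":
                klass = peak_class(peak.split("_")[0])
                rows.append(
                    {
                        "peak": peak,
                        "quantity": "ttp_fixed_ms",
                        "n": int(ok.sum()),
                        "mean_diff": round_half_away(
                            ttp_fixed_difference(mean, klass, constants), 1
                        ),
                        "sd_diff": round_half_away(
                            ttp_fixed_difference(sd, klass, constants), 1
                        ),
                    }
                )
    return pd.DataFrame(rows)
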