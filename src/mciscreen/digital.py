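"""Cleaning and featurization of VR-derived digital cognitive parameters.

Two timing parameters are recorded per participant and task: the total
time spent on the test and the duration of the speech recording, both in
seconds.  Cleaning imputes missing values with the column mean, flags and
winsorizes outliers on a robust (median/MAD) z-scale, and checks the
consistency rule that the recording cannot outlast the test.  Outliers
are capped rather than dropped so every participant stays available for
leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureVector

__all__ = ["clean_digital", "extract_digital_features", "CleaningReport", "DIGITAL_FEATURES"]

DIGITAL_FEATURES = ("total_test_time", "recording_duration")

_MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian data


@dataclass
class CleaningReport:
    """Every cell cleaning touched, with the reason and both values."""

    entries: list[dict]

    def to_frame(self) -> pd.DataFrame:
        cols = ["row", "column", "action", "original", "new"]
        return pd.DataFrame(self.entries, columns=cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def clean_digital(
    table: pd.DataFrame,
    outlier_z: float = 3.0,
    group_cols: tuple[str, ...] | None = ("group", "task_id"),
) -> tuple[pd.DataFrame, CleaningReport]:
    """Clean a digital-parameter table (one row per participant x task).

    * Missing values are imputed with the mean of the non-missing values,
      computed within ``group_cols`` strata when those columns are present
      (avoids pulling one group's central tendency into the other); pass
      ``group_cols=None`` for a pooled mean.
    * Values whose robust z-score |x - median| / (1.4826 * MAD) exceeds
      ``outlier_z`` are flagged and winsorized to the threshold (a zero
      MAD falls back to mean/std).
    * Rows with recording_duration > total_test_time get a consistency
      flag (reported, values untouched).

    Cleaning is idempotent and never changes non-missing, in-range cells.
    """
    if table.empty:
        raise ValueError("empty digital-parameter table")
    out = table.copy()
    entries: list[dict] = []

    strata: list[np.ndarray]
    if group_cols and all(c in out.columns for c in group_cols):
        keys = out[list(group_cols)].astype(str).agg("|".join, axis=1)
        strata = [np.flatnonzero((keys == k).to_numpy()) for k in keys.unique()]
    else:
        strata = [np.arange(len(out))]

    for col in DIGITAL_FEATURES:
        if col not in out.columns:
            raise ValueError(f"missing column {col!r}")
        x = pd.to_numeric(out[col], errors="coerce").to_numpy(dtype=float)
        for rows in strata:
            vals = x[rows]
            present = ~np.isnan(vals)
            if not present.any():
                raise ValueError(f"column {col!r}: all values missing in one stratum")
            mean_val = vals[present].mean()
            for i in rows[np.isnan(x[rows])]:
                entries.append(
                    {"row": int(i), "column": col, "action": "imputed_mean",
                     "original": np.nan, "new": float(mean_val)}
                )
                x[i] = mean_val
            vals = x[rows]
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            scale = _MAD_SCALE * mad if mad > 0 else vals.std(ddof=0)
            if scale <= 0:
                continue
            z = (vals - med) / scale
            # strict tolerance keeps re-cleaning already-capped values a no-op
            for j in np.flatnonzero(np.abs(z) > outlier_z * (1 + 1e-9)):
                i = rows[j]
                capped = med + np.sign(z[j]) * outlier_z * scale
                entries.append(
                    {"row": int(i), "column": col, "action": "winsorized_outlier",
                     "original": float(x[i]), "new": float(capped)}
                )
                x[i] = capped
        out[col] = x

    bad = out["recording_duration"] > out["total_test_time"]
    for i in np.flatnonzero(bad.to_numpy()):
        entries.append(
            {"row": int(i), "column": "recording_duration",
             "action": "consistency_flag_recording_exceeds_test",
             "original": float(out["recording_duration"].iloc[i]),
             "new": float(out["recording_duration"].iloc[i])}
        )
    return out, CleaningReport(entries)


def extract_digital_features(row: pd.Series | dict) -> FeatureVector:
    """The two-entry digital feature vector, in seconds."""
    values = {k: float(row[k]) for k in DIGITAL_FEATURES}
    for k, v in values.items():
        if v < 0:
            raise ValueError(f"{k} negative after cleaning: {v}")
    return FeatureVector(values)
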