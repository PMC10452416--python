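"""Ordered, named feature vectors shared by all modality extractors."""

from __future__ import annotations

from collections.abc import Iterator, Mapping

import pandas as pd


class FeatureVector(Mapping):
    """An ordered feature_id -> value map with per-feature quality flags.

    The extractors guarantee a fixed schema: every feature id is always
    present, and features that could not be measured carry a flag (and a
    placeholder value) instead of being dropped, so downstream tables keep
    a stable column set.
    """

    def __init__(self, values: dict[str, float], flags: dict[str, str] | None = None):
        self._values = dict(values)
        self.flags = dict(flags or {})
        unknown = set(self.flags) - set(self._values)
        if unknown:
            raise KeyError(f"flags for unknown features: {sorted(unknown)}")

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    @property
    def names(self) -> list[str]:
        return list(self._values)

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self._values, name=name, dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureVector({len(self)} features, {len(self.flags)} flagged)"


def feature_table(vectors: dict[str, FeatureVector]) -> pd.DataFrame:
    """Stack per-sample vectors into a DataFrame (rows = sample ids)."""
    return pd.DataFrame({k: v.to_series() for k, v in vectors.items()}).T
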