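"""Canonical registry of the 87 per-minute PSG features.

Every extractor module reports its values under the names listed here, so a
feature table always carries exactly 87 feature columns in a fixed order.
Feature names follow the field's conventional short labels (``NN50_RR``,
``RES4``, ``std_abs`` ...); because the same short label can occur on more
than one channel (e.g. ``med`` for SaO2, airflow and thoracic), table
columns are qualified as ``"<channel>:<name>"``.

The module also ships the published per-feature discrimination counts
(``lam`` = number of patients for whom the feature separated apnea from
normal minutes under both ANOVA and the rank-sum test) used by the
fixture-check command and the class-partition logic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

CHANNELS = ("ecg", "spo2", "airflow", "abdo", "thor")

#: expected number of features per channel
CHANNEL_COUNTS = {"ecg": 62, "spo2": 4, "airflow": 9, "abdo": 6, "thor": 6}

N_FEATURES = 87


@dataclass(frozen=True)
class FeatureDef:
    """One registry entry: ordinal number (1-based), source channel, name."""

    number: int
    channel: str
    name: str

    @property
    def column(self) -> str:
        """Unique column label used in feature tables."""
        return f"{self.channel}:{self.name}"


def _load_table() -> pd.DataFrame:
    ref = importlib.resources.files("apneapsg.data").joinpath("feature_lambda.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh)


_TABLE = _load_table()

#: the 87 feature definitions, in canonical order
FEATURES: tuple[FeatureDef, ...] = tuple(
    FeatureDef(int(r.number), str(r.channel), str(r.name))
    for r in _TABLE.itertuples(index=False)
)

#: canonical column order for feature tables
FEATURE_COLUMNS: tuple[str, ...] = tuple(f.column for f in FEATURES)

_BY_COLUMN = {f.column: f for f in FEATURES}
_BY_NUMBER = {f.number: f for f in FEATURES}


def by_column(column: str) -> FeatureDef:
    return _BY_COLUMN[column]


def by_number(number: int) -> FeatureDef:
    return _BY_NUMBER[number]


def channel_columns(channel: str) -> list[str]:
    """Feature columns contributed by one channel, in registry order."""
    return [f.column for f in FEATURES if f.channel == channel]


def published_lambda() -> pd.Series:
    """Published per-feature λ counts, indexed by feature number (1..87)."""
    return _TABLE.set_index("number")["lam"]
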