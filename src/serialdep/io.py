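"""Trial-table file formats, run manifests, and seeded substreams."""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .circular import PERIOD, wrap_ori

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trial_table",
    "write_trial_table",
    "RunManifest",
    "substream_rng",
]

#: columns every TrialTable CSV must carry (degrees; 0-based trial indices)
REQUIRED_COLUMNS = (
    "participant_id",
    "trial_index",
    "role",
    "condition",
    "stimulus_ori",
    "response_ori",
    "prev_inducer_ori",
    "excluded",
)

_ORI_COLUMNS = (
    "stimulus_ori",
    "response_ori",
    "prev_inducer_ori",
    "distractor_ori",
    "prev_distractor_ori",
)


class SchemaError(ValueError):
    """A trial-table file violates the documented schema."""


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a TrialTable to CSV (documented header, no index column)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table is missing required columns: {missing}")
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a TrialTable CSV.

    Orientation columns are wrapped into [0, 180) with a warning when any
    value needed wrapping; unparsable orientations raise a
    :class:`SchemaError` naming the offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table is missing required columns: {missing}")
    for col in _ORI_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"unparsable orientations in column {col!r} at rows "
                f"{list(df.index[bad][:10])}"
            )
        finite = vals.notna()
        needs_wrap = finite & ((vals < 0) | (vals >= PERIOD))
        if needs_wrap.any():
            warnings.warn(
                f"{int(needs_wrap.sum())} value(s) in {col!r} wrapped into [0, 180)"
            )
            vals = pd.Series(wrap_ori(vals.to_numpy()), index=vals.index).where(
                finite, np.nan
            )
        df[col] = vals
    df["excluded"] = df["excluded"].astype(bool)
    return df


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    config: dict = field(default_factory=dict)
    package_version: str = ""
    stage_counts: dict = field(default_factory=dict)  # stage -> row/exclusion counts
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def record(self, stage: str, **counts) -> None:
        self.stage_counts[stage] = {k: int(v) for k, v in counts.items()}

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one manifest seed.

    The same (seed, name) pair always yields the same generator, so stages
    can be rerun independently yet reproducibly.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
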