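"""CSV and JSON input/output for dose-response data.

The on-disk table format is one row per well:

    condition, fs, dose, replicate, geomean[, n_cells, seed]

``dose`` must be strictly positive and ``geomean`` positive.  Reading
validates the schema and reports the offending row and column; writing
uses full-precision float text so a round trip is lossless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import DoseResponse

__all__ = [
    "REQUIRED_COLUMNS",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "aggregate_replicates",
    "to_dose_responses",
]

REQUIRED_COLUMNS = ("condition", "fs", "dose", "replicate", "geomean")


class DoseResponseParseError(ValueError):
    """Raised when a dose-response CSV violates the schema."""


def write_dose_response_csv(data, path) -> None:
    """Write well-level dose-response data (or experiments) to CSV."""
    if isinstance(data, pd.DataFrame):
        df = data
    elif isinstance(data, (list, tuple)):
        df = pd.concat([x.to_frame() for x in data], ignore_index=True)
    else:
        df = data.to_frame()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DoseResponseParseError(f"missing required columns: {missing}")
    # 17 significant digits: float64 round-trips exactly through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_dose_response_csv(path) -> pd.DataFrame:
    """Read and validate a well-level dose-response CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DoseResponseParseError(f"missing required columns: {missing}")
    for col, pred, what in (
        ("dose", lambda v: v > 0, "positive"),
        ("geomean", lambda v: v > 0, "positive"),
        ("replicate", lambda v: v >= 1, ">= 1"),
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~vals.apply(lambda v: bool(np.isfinite(v) and pred(v)))]
        if len(bad):
            raise DoseResponseParseError(
                f"column '{col}' must be {what}: bad value at row {int(bad[0]) + 1}"
            )
    # integral-looking text must not demote float columns
    for col in ("fs", "dose", "geomean"):
        df[col] = df[col].astype(float)
    return df


def aggregate_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Per-dose geometric mean and sd of geomeans across replicates.

    Groups by (condition, fs, dose); the summary value is the
    geometric mean of the replicate geometric means.
    """
    def _agg(g: pd.Series) -> float:
        return float(np.exp(np.mean(np.log(g))))

    out = (
        df.groupby(["condition", "fs", "dose"], sort=True)["geomean"]
        .agg(geomean=_agg, sd=lambda g: float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
             n_replicates="count")
        .reset_index()
    )
    return out


def to_dose_responses(df: pd.DataFrame) -> dict[tuple[str, float], DoseResponse]:
    """Aggregate replicates and split into one curve per (condition, fs)."""
    agg = aggregate_replicates(df)
    curves = {}
    for (cond, fs), g in agg.groupby(["condition", "fs"]):
        g = g.sort_values("dose")
        curves[(str(cond), float(fs))] = DoseResponse(
            inputs=g["dose"].to_numpy(), outputs=g["geomean"].to_numpy(),
            input_label="dose", output_label="geomean",
        )
    return curves
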