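"""Reading/writing rectangular samples and result bundles.

Samples travel as UTF-8 CSV with a header row: required columns person_id,
household_id, Z, D, weight (plus optional applied/approved), covariates
prefixed ``cov_`` and outcomes prefixed ``out_``. Stata tables (.dta) are
converted to the same schema on load; a column-mapping dict lets versioned
public-use layouts be renamed without editing code.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import ObservationalSample, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["read_sample", "write_sample", "write_results", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("person_id", "household_id", "Z", "D", "weight")
_BINARY_COLUMNS = ("Z", "D", "applied", "approved")


def read_sample(path, column_map: dict[str, str] | None = None) -> ObservationalSample:
    """Load and validate a person-level sample from CSV or Stata.

    Rows with missing values in required columns are dropped (count logged);
    row order is preserved. Raises :class:`SchemaError` for a missing
    required column and ``ValueError`` (with the row index) for non-binary
    values in a binary column.
    """
    path = Path(path)
    if path.suffix.lower() == ".dta":
        df = pd.read_stata(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "applied" not in df.columns:
        df["applied"] = df["Z"].astype(np.int64) * df["D"].astype(np.int64)
    if "approved" not in df.columns:
        df["approved"] = df["applied"]
    covs = [c for c in df.columns if c.startswith(ObservationalSample.COV_PREFIX)]
    outs = [c for c in df.columns if c.startswith(ObservationalSample.OUT_PREFIX)]
    required = list(REQUIRED_COLUMNS) + ["applied", "approved"] + covs + outs
    before = len(df)
    df = df.dropna(subset=required).reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.info("read_sample: dropped %d rows with missing required fields", dropped)
    for col in _BINARY_COLUMNS:
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            raise ValueError(f"non-binary value in column {col!r} at row "
                             f"{int(np.flatnonzero(bad)[0])}")
    sample = ObservationalSample(
        df=df,
        covariate_names=[c[len(ObservationalSample.COV_PREFIX):] for c in covs],
        outcome_names=[c[len(ObservationalSample.OUT_PREFIX):] for c in outs],
    )
    sample.validate()
    return sample


def write_sample(sample: ObservationalSample, path) -> None:
    sample.df.to_csv(path, index=False)


def write_results(report, out_dir) -> list[Path]:
    """Write the tidy CSVs and the JSON run manifest; full numeric precision."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _dump(df: pd.DataFrame | None, name: str):
        if df is None:
            return
        p = out / name
        df.to_csv(p, index=False, float_format="%.17g")
        written.append(p)

    _dump(report.ate_gate, "ate_gate.csv")
    _dump(report.balance, "balance.csv")
    _dump(report.diagnostics, "diagnostics.csv")
    _dump(report.uptake_stages, "uptake_stages.csv")
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(report.manifest, fh, indent=2, default=str)
    written.append(manifest_path)
    return written
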