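"""Delimited-table I/O with a run-manifest reference line.

All artefacts the package emits are plain CSV. When a manifest digest is
supplied, the file starts with a ``# manifest: <digest>`` comment line;
:func:`read_table` skips comment lines and parses ISO-8601 date columns.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

DATE_COLUMNS = (
    "birth_date", "registration_start", "up_to_standard_date",
    "registration_end", "death_date", "event_date", "prescription_date",
    "sepsis_date", "linked_date", "start", "end", "seg_start",
)


def write_table(df: pd.DataFrame, path, manifest_digest: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if manifest_digest:
            fh.write(f"# manifest: {manifest_digest}\n")
        df.to_csv(fh, index=False, date_format="%Y-%m-%d")


def read_table(path, parse_dates: Optional[Iterable[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    cols = set(parse_dates) if parse_dates is not None else set(DATE_COLUMNS)
    for c in df.columns:
        if c in cols:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
    return df


def manifest_reference(path) -> Optional[str]:
    """Return the manifest digest recorded in a table file, if any."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# manifest:"):
        return first.split(":", 1)[1].strip()
    return None
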