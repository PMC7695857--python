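"""Readers/writers for break lists, summaries and provenance.

Two break interchange formats:

* plain CSV with columns segment_id, bp_index, strand, source;
* a minimal SDD-inspired text format — ``#``-prefixed ``key=value`` header
  lines (genome size, dose, config hash, package version) followed by one
  comma-separated damage record per line.  The full community SDD standard
  carries many optional fields this pipeline does not populate, so only
  this flavour is written and read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .scoring import BREAK_COLUMNS, empty_breaks

SDD_RECORD_FIELDS = BREAK_COLUMNS


class BreakFileError(ValueError):
    """Malformed break record; carries the offending line number."""


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable/dataclass config."""
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)

    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def provenance_block(config_obj, seed: Optional[int] = None) -> dict:
    block = {"package": "helixbreak", "version": __version__,
             "config_hash": config_hash(config_obj)}
    if seed is not None:
        block["seed"] = seed
    return block


# -- CSV ---------------------------------------------------------------------

def write_breaks_csv(breaks: pd.DataFrame, path) -> None:
    breaks[BREAK_COLUMNS].to_csv(path, index=False)


def read_breaks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BREAK_COLUMNS) - set(df.columns)
    if missing:
        raise BreakFileError(f"break CSV missing columns: {sorted(missing)}")
    return _validate_breaks(df[BREAK_COLUMNS].copy())


def _validate_breaks(df: pd.DataFrame) -> pd.DataFrame:
    bad = ~df["source"].isin(["direct", "indirect"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise BreakFileError(
            f"record {row + 1}: invalid source {df['source'].iloc[row]!r}")
    bad = ~df["strand"].isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise BreakFileError(
            f"record {row + 1}: invalid strand {df['strand'].iloc[row]!r}")
    return df


# -- SDD-flavoured text ------------------------------------------------------

def write_breaks_sdd(breaks: pd.DataFrame, path, genome_gbp: float,
                     dose_gy: float, config_obj=None,
                     seed: Optional[int] = None) -> None:
    header = {"format": "helixbreak-sdd-mini/1",
              "genome_gbp": genome_gbp, "dose_gy": dose_gy,
              "version": __version__}
    if config_obj is not None:
        header["config_hash"] = config_hash(config_obj)
    if seed is not None:
        header["seed"] = seed
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}={val}\n")
        fh.write("# fields=" + ",".join(SDD_RECORD_FIELDS) + "\n")
        for row in breaks[BREAK_COLUMNS].itertuples(index=False):
            fh.write(f"{row.segment_id},{row.bp_index},{row.strand},"
                     f"{row.source}\n")


def read_breaks_sdd(path):
    """Returns ``(breaks DataFrame, header dict)``."""
    header: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    header[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise BreakFileError(
                    f"line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append((int(parts[0]), int(parts[1]), int(parts[2]),
                             parts[3].strip()))
            except ValueError as exc:
                raise BreakFileError(f"line {lineno}: {exc}") from exc
    if rows:
        df = pd.DataFrame(rows, columns=BREAK_COLUMNS)
    else:
        df = empty_breaks()
    return _validate_breaks(df), header


def write_summary_json(summary, path, config_obj=None,
                       seed: Optional[int] = None,
                       extra: Optional[dict] = None) -> None:
    payload = {"summary": summary.to_dict(),
               "provenance": provenance_block(config_obj, seed)}
    if extra:
        payload.update(extra)

    def clean(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=clean)
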