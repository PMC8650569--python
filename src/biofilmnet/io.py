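"""Count-table I/O, result serialisation and run manifests.

The universal exchange object is the long-format count table (CSV) with
the exact header::

    context,species,replicate,time_h,cfu_per_cm2,censored,detection_limit

One row per (context, species, replicate, time); censored rows store the
detection limit as their count.  All validation errors are reported with
1-based data row numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "CountTableError",
    "validate_count_table",
    "read_count_table",
    "write_count_table",
    "fits_to_frame",
    "summaries_to_frame",
    "RunManifest",
]

REQUIRED_COLUMNS = [
    "context", "species", "replicate", "time_h", "cfu_per_cm2",
    "censored", "detection_limit",
]

KEY_COLUMNS = ["context", "species", "replicate", "time_h"]


class CountTableError(ValueError):
    """Invalid count table; the message lists every offending row."""


def validate_count_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; returns the (typed) table.

    Checks: exact column set, positive counts, replicate >= 1, censored
    rows storing the detection limit, and uniqueness of
    (context, species, replicate, time_h).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"missing column(s): {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        df = df[REQUIRED_COLUMNS].copy()
    else:
        df = df.copy()
    df["censored"] = df["censored"].astype(bool)
    for col in ("time_h", "cfu_per_cm2", "detection_limit"):
        df[col] = pd.to_numeric(df[col])
    df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")

    problems = []
    rows = np.arange(1, len(df) + 1)
    bad = df["cfu_per_cm2"].to_numpy() <= 0
    for r in rows[bad]:
        problems.append(f"row {r}: cfu_per_cm2 must be > 0")
    bad = df["replicate"].to_numpy() < 1
    for r in rows[bad]:
        problems.append(f"row {r}: replicate must be >= 1")
    cens = df["censored"].to_numpy()
    mismatch = cens & ~np.isclose(df["cfu_per_cm2"].to_numpy(),
                                  df["detection_limit"].to_numpy())
    for r in rows[mismatch]:
        problems.append(f"row {r}: censored rows must store the detection limit")
    dup = df.duplicated(subset=KEY_COLUMNS)
    for r in rows[dup.to_numpy()]:
        key = df.iloc[r - 1][KEY_COLUMNS].tolist()
        problems.append(f"row {r}: duplicate key {key}")
    if problems:
        raise CountTableError("; ".join(problems))
    return df


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a count-table CSV."""
    df = pd.read_csv(path)
    if list(df.columns) != REQUIRED_COLUMNS:
        raise CountTableError(
            f"expected header {','.join(REQUIRED_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}")
    return validate_count_table(df)


def write_count_table(df: pd.DataFrame, path) -> None:
    validate_count_table(df).to_csv(path, index=False)


def fits_to_frame(fits) -> pd.DataFrame:
    """Flatten ``{(context, species): FitResult}`` into one row per fit."""
    rows = []
    for (context, species), fr in sorted(fits.items()):
        p = fr.params
        rows.append({
            "species": species, "context": context,
            "x0": p.x0 if p else np.nan, "mu": p.mu if p else np.nan,
            "K": p.K if p else np.nan, "tau": p.tau if p else np.nan,
            "status": fr.status, "sse": fr.sse, "n_points": fr.n_points,
        })
    return pd.DataFrame(rows, columns=["species", "context", "x0", "mu", "K",
                                       "tau", "status", "sse", "n_points"])


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = [{
        "contrast": s.contrast, "statistic": s.statistic,
        "p_retained": s.p_retained, "n_repeats_used": s.n_repeats_used,
        "stars": s.stars,
    } for s in summaries]
    return pd.DataFrame(rows, columns=["contrast", "statistic", "p_retained",
                                       "n_repeats_used", "stars"])


@dataclass
class RunManifest:
    """Provenance record tying seeds and configuration to outputs."""

    command: str
    seed: int | None
    config_hash: str
    outputs: list = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, seed: int | None, config_text: str,
               outputs) -> "RunManifest":
        from . import __version__
        return cls(
            command=command, seed=seed,
            config_hash=hashlib.sha256(config_text.encode()).hexdigest(),
            outputs=[str(o) for o in outputs],
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
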