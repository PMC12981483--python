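"""Reading and writing λ-record files.

Constant-pH engines write per-frame titration coordinates in assorted
engine-specific layouts; this package uses one engine-agnostic dialect that
converters can trivially target: a header-bearing tab-separated file, one file
per simulated pH, with the pH recorded in a comment header line::

    # pH: 7.00
    frame\tresidue_id\tlambda\tchi
    0\tASP6\t0.931250\t0.052349
    0\tHIS26\t0.120000\tNA

``chi`` is ``NA`` for residues with a single titratable site.  Frames need not
be contiguous but must be non-decreasing per residue.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["read_lambda_records", "write_lambda_records", "read_lambda_directory"]

_COLUMNS = ["frame", "residue_id", "lambda", "chi"]


def write_lambda_records(path, ph: float, records: pd.DataFrame) -> None:
    """Write one pH's records in the λ-record TSV dialect (deterministic)."""
    df = records.loc[:, _COLUMNS].copy()
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# pH: {float(ph):.4f}\n")
        df.to_csv(
            fh,
            sep="\t",
            index=False,
            na_rep="NA",
            float_format="%.6f",
            lineterminator="\n",
        )


def read_lambda_records(path) -> tuple[float, pd.DataFrame]:
    """Read a λ-record TSV file; returns (pH, records DataFrame).

    Malformed records are rejected with file/line context rather than
    silently coerced.
    """
    path = Path(path)
    header_ph: float | None = None
    body_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.lower().startswith("ph"):
                    try:
                        header_ph = float(stripped.split(":", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise ValueError(
                            f"{path}:{lineno}: malformed pH header {line.strip()!r}"
                        ) from exc
                continue
            body_lines.append(line)
    if header_ph is None:
        raise ValueError(f"{path}: missing '# pH: <value>' header line")
    if not body_lines:
        raise ValueError(f"{path}: no records after header")
    try:
        df = pd.read_csv(
            io.StringIO("".join(body_lines)),
            sep="\t",
            na_values=["NA"],
            dtype={"frame": int, "residue_id": str, "lambda": float, "chi": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed record table: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lam = df["lambda"].to_numpy()
    bad = np.flatnonzero((lam < 0) | (lam > 1) | np.isnan(lam))
    if bad.size:
        row = int(bad[0])
        raise ValueError(
            f"{path}: lambda outside [0, 1] at data row {row} "
            f"(residue {df['residue_id'].iat[row]!r}, frame {df['frame'].iat[row]})"
        )
    chi = df["chi"].to_numpy()
    present = ~np.isnan(chi)
    if np.any((chi[present] < 0) | (chi[present] > 1)):
        raise ValueError(f"{path}: chi outside [0, 1]")
    for rid, sub in df.groupby("residue_id", sort=False):
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) < 0):
            raise ValueError(
                f"{path}: frame indices not non-decreasing for residue {rid!r}"
            )
    return header_ph, df.loc[:, _COLUMNS]


def read_lambda_directory(directory) -> Mapping[float, pd.DataFrame]:
    """Read every ``*.tsv`` λ-record file in a directory, keyed by pH."""
    directory = Path(directory)
    out: dict[float, pd.DataFrame] = {}
    for path in sorted(directory.glob("*.tsv")):
        ph, df = read_lambda_records(path)
        if ph in out:
            out[ph] = pd.concat([out[ph], df], ignore_index=True)
        else:
            out[ph] = df
    if not out:
        raise FileNotFoundError(f"no .tsv λ-record files found in {directory}")
    return out
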