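"""Format readers/writers shared by the CLI.

CSV tables use a two-line header: column names (with the unit encoded in the
name, e.g. ``time_s``) followed by a units row (e.g. ``s``).  The units row
is mandatory on read — silent unit drift is the failure mode this dialect is
designed against.  Images are plain grayscale TIFF/PNG.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class ParseError(ValueError):
    """Malformed input file."""


def write_table(df: pd.DataFrame, path: str | Path, units: list[str]) -> None:
    """Write CSV with a names row then a units row, then numeric data."""
    if len(units) != df.shape[1]:
        raise ValueError("one unit per column required")
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(",".join(map(str, df.columns)) + "\n")
        fh.write(",".join(units) + "\n")
        df.to_csv(fh, header=False, index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read the two-line-header CSV dialect; returns (frame, units).

    Raises :class:`ParseError` with the offending line number when the units
    row is missing (detected by the second line parsing entirely as numbers).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: need a header row and a units row (line 2 missing)")
    names = [c.strip() for c in lines[0].split(",")]
    units = [c.strip() for c in lines[1].split(",")]
    if len(units) != len(names):
        raise ParseError(f"{path}:2: units row has {len(units)} cells, expected {len(names)}")

    def _is_number(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    if all(_is_number(c) for c in units):
        raise ParseError(f"{path}:2: missing units row (line 2 is numeric data)")
    body = "\n".join(lines[2:])
    if not body.strip():
        df = pd.DataFrame(columns=names)
    else:
        df = pd.read_csv(_io.StringIO(body), header=None, names=names)
    return df, units


def write_image(array: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image; TIFF for .tif/.tiff, PNG otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(array))
    else:
        iio.imwrite(path, np.asarray(array))


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))
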