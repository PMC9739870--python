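"""Readers and writers for the file formats the pipeline touches.

Three formats are involved: tpsDig-style TPS landmark files (``LM=`` blocks),
binary (black/white) pattern images stored as PNG, and the biometric table as
a plain CSV.  TPS coordinates are kept in the TPS convention (y axis pointing
up, origin at the bottom-left of the source photograph); :func:`flip_y` is the
single place where they are converted to raster row coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "TpsRecord",
    "TpsParseError",
    "ValidationError",
    "POPULATIONS",
    "FEATURE_COLUMNS",
    "read_tps_file",
    "write_tps_file",
    "read_binary_image",
    "write_binary_image",
    "read_biometric_table",
    "validate_biometric_table",
    "flip_y",
]

#: population code -> (species, site typology); the five study sites.
POPULATIONS: dict[str, tuple[str, str]] = {
    "AC": ("perspicillata", "lentic"),   # Acqua della chiesa (trough)
    "CN": ("perspicillata", "lentic"),   # Ciccopano nuove (rocky spring ponds)
    "SA": ("perspicillata", "brook"),    # Sant'Angelo
    "TC": ("terdigitata", "brook"),      # Torrente Cerasuolo
    "TR": ("terdigitata", "brook"),      # Torrente Rosa
}

#: biometric feature columns, mm
FEATURE_COLUMNS = ["AG", "CL", "HL", "HW", "No", "RU", "SVL", "TF", "TL", "tL", "tW"]

LABEL_COLUMNS = ["id", "species", "site_typology", "population"]


class TpsParseError(ValueError):
    """Raised on a malformed TPS file; message names the offending line."""


class ValidationError(ValueError):
    """Raised when a biometric table violates the study-design constraints."""


@dataclass
class TpsRecord:
    """One specimen's landmark block from a TPS file.

    ``points`` are (x, y) pairs in TPS convention (origin bottom-left).
    ``scale``, when present, is the physical size of one pixel.
    """

    id: str
    points: np.ndarray
    image: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TpsRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.image == other.image
            and (self.scale is None) == (other.scale is None)
            and (self.scale is None or np.isclose(self.scale, other.scale))
            and self.points.shape == other.points.shape
            and np.allclose(self.points, other.points, atol=1e-6)
        )


def read_tps_file(path: str | Path) -> list[TpsRecord]:
    """Parse a tpsDig TPS file into a list of :class:`TpsRecord`.

    Each block starts with ``LM=<count>`` followed by that many ``x y``
    coordinate lines and optional ``IMAGE=``, ``ID=``, ``SCALE=`` lines.
    Coordinates are kept in file order and TPS y-convention.
    """
    path = Path(path)
    records: list[TpsRecord] = []
    n_expected = 0
    points: list[tuple[float, float]] = []
    meta: dict[str, str] = {}
    in_block = False
    header_line = 0

    def close_block(lineno: int) -> None:
        nonlocal in_block
        if not in_block:
            return
        if len(points) != n_expected:
            raise TpsParseError(
                f"{path}: block starting at line {header_line} declares "
                f"LM={n_expected} but lists {len(points)} points"
            )
        records.append(
            TpsRecord(
                id=meta.get("ID", str(len(records))),
                points=np.array(points, dtype=float),
                image=meta.get("IMAGE"),
                scale=float(meta["SCALE"]) if "SCALE" in meta else None,
            )
        )
        points.clear()
        meta.clear()
        in_block = False

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                close_block(lineno)
                try:
                    n_expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise TpsParseError(f"{path}: line {lineno}: bad LM header {line!r}") from exc
                if n_expected <= 0:
                    raise TpsParseError(f"{path}: line {lineno}: LM count must be positive")
                in_block = True
                header_line = lineno
            elif "=" in line and not _looks_numeric(line):
                key, _, value = line.partition("=")
                meta[key.strip().upper()] = value.strip()
            else:
                if not in_block:
                    raise TpsParseError(f"{path}: line {lineno}: coordinates outside an LM block")
                parts = line.split()
                if len(parts) != 2:
                    raise TpsParseError(f"{path}: line {lineno}: expected 'x y', got {line!r}")
                try:
                    points.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise TpsParseError(
                        f"{path}: line {lineno}: non-numeric coordinate {line!r}"
                    ) from exc
                if len(points) > n_expected:
                    raise TpsParseError(
                        f"{path}: line {lineno}: more points than declared LM={n_expected}"
                    )
    close_block(lineno if "lineno" in dir() else 0)
    return records


def _looks_numeric(line: str) -> bool:
    head = line.split()[0]
    try:
        float(head)
        return True
    except ValueError:
        return False


def write_tps_file(records: Sequence[TpsRecord], path: str | Path) -> None:
    """Write TPS records; round-trips with :func:`read_tps_file` at 6 decimals."""
    if len(records) == 0:
        raise ValueError("cannot write an empty TPS file")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"LM={len(rec.points)}\n")
            for x, y in rec.points:
                fh.write(f"{x:.6f} {y:.6f}\n")
            if rec.image is not None:
                fh.write(f"IMAGE={rec.image}\n")
            fh.write(f"ID={rec.id}\n")
            if rec.scale is not None:
                fh.write(f"SCALE={rec.scale:.6f}\n")


def flip_y(points: np.ndarray, height: int) -> np.ndarray:
    """Convert between TPS (origin bottom-left) and raster (origin top-left) y.

    The transform is its own inverse: ``y -> height - 1 - y`` with pixel
    centers at integer coordinates.
    """
    pts = np.array(points, dtype=float)
    pts[:, 1] = (height - 1) - pts[:, 1]
    return pts


def read_binary_image(path: str | Path) -> np.ndarray:
    """Load a black/white pattern image as a {0,1} uint8 matrix.

    Any pixel with luminance > 127 maps to 1 (the yellow patch, stored as
    white); everything else is 0.  The rule is idempotent on {0, 255} images.
    """
    with Image.open(path) as img:
        gray = np.asarray(img.convert("L"))
    return (gray > 127).astype(np.uint8)


def write_binary_image(values: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} matrix as an 8-bit grayscale PNG (1 -> 255)."""
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("binary image must contain only 0 and 1")
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)


def validate_biometric_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a biometric table against the study design.

    Checks: all feature and label columns present; population codes known;
    species and site typology consistent with the population; measurements
    non-negative; AG <= SVL <= TL whenever all three are present.
    Returns the validated frame (labels as plain strings).
    """
    missing = [c for c in LABEL_COLUMNS + FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    df = df.copy()
    for row_idx, row in df.iterrows():
        pop = row["population"]
        if pop not in POPULATIONS:
            raise ValidationError(f"row {row_idx}: unknown population code {pop!r}")
        species, site = POPULATIONS[pop]
        if row["species"] != species:
            raise ValidationError(
                f"row {row_idx}: population {pop} is S. {species}, got {row['species']!r}"
            )
        if row["site_typology"] != site:
            raise ValidationError(
                f"row {row_idx}: population {pop} is a {site} site, got {row['site_typology']!r}"
            )
        for col in FEATURE_COLUMNS:
            v = row[col]
            if pd.notna(v) and v < 0:
                raise ValidationError(f"row {row_idx}: negative {col} = {v}")
        ag, svl, tl = row["AG"], row["SVL"], row["TL"]
        if pd.notna(ag) and pd.notna(svl) and pd.notna(tl) and not (ag <= svl <= tl):
            raise ValidationError(f"row {row_idx}: expected AG <= SVL <= TL, got {ag}, {svl}, {tl}")
    return df


def read_biometric_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-individual biometric CSV.

    One row per individual: an ``id``, the three design labels (species,
    site_typology, population) and the 11 measurements in mm (missing
    values allowed).
    """
    df = pd.read_csv(path)
    return validate_biometric_table(df)
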