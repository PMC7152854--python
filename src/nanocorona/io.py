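"""Reading and writing localization tables and cluster reports.

All coordinates inside the package are nanometres.  The canonical on-disk
dialect is a comma-separated file with header

    frame,x_nm,y_nm,z_nm,photons,channel

where the ``z_nm`` column is absent for 2D data.  Unit suffixes in the header
make the nm/px ambiguity of vendor exports explicit.  Other dialects (renamed
columns, pixel units with a known pixel size) are ingested through
:class:`LocalizationDialect`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IngestError, InputError

__all__ = [
    "LocalizationTable",
    "LocalizationDialect",
    "CANONICAL_DIALECT",
    "read_localizations",
    "write_localizations",
    "write_report",
    "read_report",
]

#: Default photon count assigned when the source file carries no photon column.
DEFAULT_PHOTONS = 1000.0

#: Channel identifier assigned when the source file carries no channel column.
DEFAULT_CHANNEL = "ch1"

_REQUIRED = ("frame", "x", "y")
_OPTIONAL = ("z", "photons", "channel")

REPORT_COLUMNS = [
    "cluster",
    "channel",
    "n",
    "measure",
    "density",
    "equivalent_diameter",
    "centroid_x",
    "centroid_y",
    "centroid_z",
]


@dataclass(frozen=True)
class LocalizationDialect:
    """Column mapping and units of a localization file.

    Parameters
    ----------
    columns
        Map from canonical field name (``frame``, ``x``, ``y``, ``z``,
        ``photons``, ``channel``) to the column name in the source file.
        ``frame``, ``x`` and ``y`` are required; the rest are optional.
    unit
        Unit of the source coordinates, ``"nm"`` or ``"px"``.
    pixel_size_nm
        Pixel pitch used to scale ``px`` coordinates to nm; required when
        ``unit == "px"``.
    """

    columns: Mapping[str, str]
    unit: str = "nm"
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        for name in _REQUIRED:
            if name not in self.columns:
                raise IngestError(f"dialect does not map required column {name!r}")
        mapped = list(self.columns.values())
        if len(set(mapped)) != len(mapped):
            raise IngestError("dialect maps two fields to the same source column")
        if self.unit not in ("nm", "px"):
            raise IngestError(f"unknown coordinate unit {self.unit!r}")
        if self.unit == "px" and not (
            self.pixel_size_nm is not None and self.pixel_size_nm > 0
        ):
            raise IngestError("pixel-unit dialect requires a positive pixel_size_nm")


CANONICAL_DIALECT = LocalizationDialect(
    columns={
        "frame": "frame",
        "x": "x_nm",
        "y": "y_nm",
        "z": "z_nm",
        "photons": "photons",
        "channel": "channel",
    }
)


class LocalizationTable:
    """Channel-tagged point set in nm with frame and photon metadata.

    Thin wrapper over a :class:`pandas.DataFrame` with canonical columns
    ``frame, x, y[, z], photons, channel``.  Dimensionality is uniform:
    the ``z`` column is present iff the table is 3D.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        expected = ["frame", "x", "y"] + (["z"] if "z" in df.columns else [])
        expected += ["photons", "channel"]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise InputError(f"localization table missing columns {missing}")
        self.df = df.loc[:, expected].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        for col in ("x", "y") + (("z",) if self.is_3d else ()):
            bad = ~np.isfinite(df[col].to_numpy(dtype=float))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise IngestError(f"non-finite coordinate in column {col!r}, row {row}")
        if (df["frame"].to_numpy() < 1).any():
            row = int(np.flatnonzero(df["frame"].to_numpy() < 1)[0])
            raise IngestError(f"non-positive frame index in column 'frame', row {row}")
        if (df["photons"].to_numpy(dtype=float) < 0).any():
            row = int(np.flatnonzero(df["photons"].to_numpy(dtype=float) < 0)[0])
            raise IngestError(f"negative photon count in column 'photons', row {row}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_3d(self) -> bool:
        return "z" in self.df.columns

    @property
    def ndim(self) -> int:
        return 3 if self.is_3d else 2

    @property
    def channels(self) -> list[str]:
        """Channel identifiers present, in order of first appearance."""
        return list(dict.fromkeys(self.df["channel"].astype(str)))

    def coords(self) -> np.ndarray:
        """(n, d) float array of positions in nm."""
        cols = ["x", "y", "z"] if self.is_3d else ["x", "y"]
        return self.df[cols].to_numpy(dtype=float)

    def select_channel(self, channel: str) -> "LocalizationTable":
        sub = self.df[self.df["channel"].astype(str) == str(channel)]
        return LocalizationTable(sub.copy())

    def subset(self, mask_or_index) -> "LocalizationTable":
        """Row subset by boolean mask or integer index, order preserved."""
        sub = self.df.iloc[np.asarray(mask_or_index).nonzero()[0]] if (
            np.asarray(mask_or_index).dtype == bool
        ) else self.df.iloc[np.asarray(mask_or_index)]
        return LocalizationTable(sub.copy())

    @classmethod
    def empty(cls, three_d: bool = False) -> "LocalizationTable":
        cols = ["frame", "x", "y"] + (["z"] if three_d else []) + ["photons", "channel"]
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in cols}))

    @classmethod
    def from_arrays(
        cls,
        x: Iterable[float],
        y: Iterable[float],
        z: Iterable[float] | None = None,
        frame: Iterable[int] | None = None,
        photons: Iterable[float] | None = None,
        channel: Iterable[str] | str = DEFAULT_CHANNEL,
    ) -> "LocalizationTable":
        x = np.asarray(list(x), dtype=float)
        n = x.size
        data: dict = {
            "frame": np.asarray(list(frame), dtype=int) if frame is not None else np.ones(n, dtype=int),
            "x": x,
            "y": np.asarray(list(y), dtype=float),
        }
        if z is not None:
            data["z"] = np.asarray(list(z), dtype=float)
        data["photons"] = (
            np.asarray(list(photons), dtype=float) if photons is not None else np.full(n, DEFAULT_PHOTONS)
        )
        data["channel"] = (
            np.full(n, channel) if isinstance(channel, str) else np.asarray(list(channel))
        )
        return cls(pd.DataFrame(data))


def read_localizations(
    path: str | Path, dialect: LocalizationDialect = CANONICAL_DIALECT
) -> LocalizationTable:
    """Read a localization CSV into a validated table in nm.

    Pixel-unit coordinates are scaled by ``dialect.pixel_size_nm``.  A missing
    channel column yields the single channel ``"ch1"``; a missing photon
    column yields ``DEFAULT_PHOTONS``.

    Raises
    ------
    IngestError
        If a required column is unmapped or absent, a coordinate is
        non-numeric or non-finite, or a photon count is negative; the message
        names the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    out = pd.DataFrame()
    for name in _REQUIRED + _OPTIONAL:
        src = dialect.columns.get(name)
        if src is None or src not in raw.columns:
            if name in _REQUIRED:
                raise IngestError(
                    f"{path.name}: required column {name!r} "
                    f"({src or 'unmapped'}) not found"
                )
            continue
        col = raw[src]
        if name == "channel":
            out[name] = col.astype(str)
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna() if name != "z" else numeric.isna()
        if name in ("x", "y", "z", "frame", "photons"):
            bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IngestError(
                f"{path.name}: non-numeric value in column {src!r}, row {row}"
            )
        out[name] = numeric.to_numpy(dtype=float)
    scale = dialect.pixel_size_nm if dialect.unit == "px" else 1.0
    for axis in ("x", "y", "z"):
        if axis in out.columns:
            out[axis] = out[axis] * scale
    if "photons" not in out.columns:
        out["photons"] = DEFAULT_PHOTONS
    if "channel" not in out.columns:
        out["channel"] = DEFAULT_CHANNEL
    out["frame"] = out["frame"].astype(int)
    return LocalizationTable(out)


def write_localizations(table: LocalizationTable, path: str | Path) -> Path:
    """Write a table in the canonical dialect (full repr precision)."""
    path = Path(path)
    df = table.df.copy()
    rename = {"x": "x_nm", "y": "y_nm", "z": "z_nm"}
    df = df.rename(columns=rename)
    df.to_csv(path, index=False)
    return path


def write_report(stats: pd.DataFrame | Sequence[Mapping], path: str | Path) -> Path:
    """Write per-cluster statistics as a TSV.

    Rows carry (cluster id, channel, n, measure, density, equivalent
    diameter, centroid).  An empty input produces a header-only file.
    Round-tripping through :func:`read_report` reproduces values to better
    than 1e-9 relative (pandas writes full repr precision).
    """
    path = Path(path)
    df = pd.DataFrame(stats) if not isinstance(stats, pd.DataFrame) else stats.copy()
    if df.empty:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    cols = [c for c in REPORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
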