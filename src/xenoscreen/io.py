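"""Tabular and track I/O with strict validation.

Readers reject malformed input (naming the offending row) rather than
silently coercing; ``write . read`` and ``read . write`` round trips are
identities on valid files. Tables are UTF-8, tab-separated by default with
comma auto-detection, header row mandatory. Well coordinates are normalized
to zero-padded form (``A1`` -> ``A01``) for stable sort order.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthCurve

__all__ = [
    "PlateMap",
    "WellEntry",
    "ROLES",
    "normalize_well",
    "read_plate_timeseries",
    "write_plate_timeseries",
    "read_plate_map",
    "write_plate_map",
    "read_gene_table",
    "write_gene_table",
    "write_wig",
    "read_wig",
]

ROLES = frozenset(
    {"treatment", "vehicle_control", "dye_footprint", "empty", "media_control"}
)

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")


def normalize_well(well: str) -> str:
    """Normalize a well coordinate to zero-padded form, e.g. ``A1`` -> ``A01``."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"invalid well coordinate: {well!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


def well_row_col(well: str) -> tuple[str, int]:
    """Split a normalized well into (row letter, column number)."""
    w = normalize_well(well)
    return w[0], int(w[1:])


@dataclass(frozen=True)
class WellEntry:
    """Content of one well on a plate map."""

    content_id: str
    concentration: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role: {self.role!r}")
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError("concentration must be finite and >= 0")


@dataclass(frozen=True)
class PlateMap:
    """Well -> (compound, concentration in uM, role) layout for one plate.

    Every plate must declare at least one vehicle-control well (the DMSO
    wells interspersed within the plate that anchor normalization).
    """

    plate_id: str
    wells: dict[str, WellEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for well, entry in self.wells.items():
            w = normalize_well(well)
            if w in normalized:
                raise ValueError(f"duplicate well {w} on plate {self.plate_id}")
            normalized[w] = entry
        object.__setattr__(self, "wells", normalized)
        if not any(e.role == "vehicle_control" for e in normalized.values()):
            raise ValueError(
                f"plate {self.plate_id} declares no vehicle_control well"
            )

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, e in self.wells.items() if e.role == role)

    @property
    def control_wells(self) -> list[str]:
        return self.wells_with_role("vehicle_control")


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)


def _parse_float(value: str, what: str, row: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric {what} {value!r} at data row {row}") from None
    if not np.isfinite(out):
        raise ValueError(f"non-finite {what} {value!r} at data row {row}")
    return out


_TIME_UNIT = {"h": 1.0, "hours": 1.0, "min": 1 / 60.0, "minutes": 1 / 60.0, "s": 1 / 3600.0}


def read_plate_timeseries(path, dialect: str = "long") -> list[GrowthCurve]:
    """Read plate-reader OD600 time series into growth curves.

    ``long`` dialect: columns plate_id, well, strain_id, replicate, time, od
    (optional ``time_unit`` column converts to hours). ``wide`` dialect:
    metadata columns plate_id, well, strain_id, replicate followed by one
    numeric column per time point (hours).

    Duplicate (plate, well, time) rows, non-numeric OD and unsortable time
    axes are rejected with the offending row named.
    """
    df = _read_table(path)
    if dialect == "long":
        required = {"plate_id", "well", "strain_id", "replicate", "time", "od"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long time-series file missing columns: {sorted(missing)}")
        records: dict[tuple, list[tuple[float, float, int]]] = {}
        for i, row in enumerate(df.itertuples(index=False), start=1):
            t = _parse_float(row.time, "time", i)
            if "time_unit" in df.columns:
                unit = getattr(row, "time_unit")
                if unit not in _TIME_UNIT:
                    raise ValueError(f"unknown time unit {unit!r} at data row {i}")
                t *= _TIME_UNIT[unit]
            od = _parse_float(row.od, "OD", i)
            key = (row.plate_id, normalize_well(row.well), row.strain_id, int(row.replicate))
            records.setdefault(key, []).append((t, od, i))
        curves = []
        for (plate, well, strain, rep), pts in records.items():
            pts.sort(key=lambda x: x[0])
            times = np.array([p[0] for p in pts])
            if np.any(np.diff(times) == 0):
                j = int(np.argmax(np.diff(times) == 0))
                raise ValueError(
                    f"duplicate time point for plate {plate} well {well} "
                    f"(data row {pts[j + 1][2]})"
                )
            curves.append(
                GrowthCurve(plate, well, strain, rep, times, np.array([p[1] for p in pts]))
            )
        return sorted(curves, key=lambda c: (c.plate_id, c.strain_id, c.replicate, c.well))
    if dialect == "wide":
        meta = ["plate_id", "well", "strain_id", "replicate"]
        missing = set(meta) - set(df.columns)
        if missing:
            raise ValueError(f"wide time-series file missing columns: {sorted(missing)}")
        time_cols = [c for c in df.columns if c not in meta]
        times = np.array([_parse_float(c, "time header", 0) for c in time_cols])
        order = np.argsort(times)
        if np.any(np.diff(times[order]) == 0):
            raise ValueError("duplicate time columns in wide file")
        seen: set[tuple] = set()
        curves = []
        for i in range(len(df)):
            row = df.iloc[i]
            key = (row["plate_id"], normalize_well(row["well"]),
                   row["strain_id"], int(row["replicate"]))
            if key in seen:
                raise ValueError(f"duplicate well row at data row {i + 1}")
            seen.add(key)
            od = np.array([_parse_float(row[c], "OD", i + 1) for c in time_cols])
            curves.append(GrowthCurve(key[0], key[1], key[2], key[3], times[order], od[order]))
        return curves
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plate_timeseries(curves, path, dialect: str = "long", sep: str = "\t") -> None:
    """Write growth curves back to disk in the long or wide dialect."""
    path = Path(path)
    if dialect == "long":
        rows = []
        for c in curves:
            for t, od in zip(c.times, c.od):
                rows.append((c.plate_id, c.well, c.strain_id, c.replicate, t, od))
        pd.DataFrame(
            rows, columns=["plate_id", "well", "strain_id", "replicate", "time", "od"]
        ).to_csv(path, sep=sep, index=False)
    elif dialect == "wide":
        times = curves[0].times
        for c in curves:
            if not np.array_equal(c.times, times):
                raise ValueError("wide dialect requires a shared time axis")
        rows = [
            [c.plate_id, c.well, c.strain_id, c.replicate, *c.od] for c in curves
        ]
        cols = ["plate_id", "well", "strain_id", "replicate", *[repr(float(t)) for t in times]]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_plate_map(path) -> PlateMap:
    """Read a plate map table (columns: well, content, concentration, role)."""
    df = _read_table(path)
    required = {"well", "content", "concentration", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df.columns and len(df) else "plate"
    wells: dict[str, WellEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        w = normalize_well(row.well)
        if w in wells:
            raise ValueError(f"duplicate well {w} at data row {i}")
        conc = _parse_float(row.concentration, "concentration", i)
        wells[w] = WellEntry(content_id=row.content, concentration=conc, role=row.role)
    return PlateMap(plate_id=plate_id, wells=wells)


def write_plate_map(plate_map: PlateMap, path, sep: str = "\t") -> None:
    rows = [
        (plate_map.plate_id, w, e.content_id, e.concentration, e.role)
        for w, e in sorted(plate_map.wells.items())
    ]
    pd.DataFrame(
        rows, columns=["plate_id", "well", "content", "concentration", "role"]
    ).to_csv(path, sep=sep, index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene coordinate table (gene_id, start, end, strand[, annotations]).

    Coordinates are 1-based inclusive; ``annotations`` (optional) holds
    comma-separated term ids (e.g. KEGG). gene_ids must be unique and
    start <= end.
    """
    df = _read_table(path)
    required = {"gene_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "start": [int(_parse_float(v, "start", i + 1)) for i, v in enumerate(df["start"])],
            "end": [int(_parse_float(v, "end", i + 1)) for i, v in enumerate(df["end"])],
            "strand": df["strand"],
        }
    )
    if "annotations" in df.columns:
        out["annotations"] = df["annotations"]
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    bad = out["start"] > out["end"]
    if bad.any():
        raise ValueError(f"start > end for gene {out.loc[bad, 'gene_id'].iloc[0]!r}")
    if not out["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return out


def write_gene_table(genes: pd.DataFrame, path, sep: str = "\t") -> None:
    genes.to_csv(path, sep=sep, index=False)


def write_wig(site_counts: dict[int, float], chrom: str, path) -> None:
    """Write insertion counts as a 1-based variableStep wiggle track."""
    items = sorted(site_counts.items())
    for pos, count in items:
        if int(pos) < 1:
            raise ValueError(f"wiggle positions are 1-based; got {pos}")
        if count < 0:
            raise ValueError(f"negative count at position {pos}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"variableStep chrom={chrom}\n")
        for pos, count in items:
            fh.write(f"{int(pos)} {count:g}\n")


def read_wig(path) -> tuple[dict[int, float], str]:
    """Parse a variableStep wiggle file back to (position -> count, chrom)."""
    counts: dict[int, float] = {}
    chrom = ""
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("variableStep"):
                m = re.search(r"chrom=(\S+)", line)
                chrom = m.group(1) if m else ""
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed wiggle line {i}: {line!r}")
            counts[int(parts[0])] = float(parts[1])
    return counts, chrom
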