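"""Reading and writing kinetic CSV exports and report tables.

Instrument exports arrive as comma-separated files, one plate-run per
file.  The canonical dialect read and written here is:

.. code-block:: text

    project,PROJ1
    species,Bacillus sp.
    strain,WT
    plate,PM01
    replicate,1
    temperature,37
    Time(min),A01,A02,...,H12
    0,12.0,11.8,...,12.4
    15,12.5,12.1,...,12.9
    ...

A metadata header block (key,value rows) is followed by a table with one
time column — ``Time(min)`` in minutes, or ``Hour`` in hours (converted
to minutes on read) — and one column per well, ``A01`` through ``H12``.
Phenotype labels are not part of the instrument export; they come from a
sidecar *phenotype map* CSV with columns ``plate,well,phenotype`` and an
optional ``mode_of_action``.

Report tables ("spreadsheet-openable" outputs of the analysis modules)
are written as plain CSV with full numeric precision.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import WELL_IDS, WELL_RE, KineticCurve, RecordSet, WellRecord

__all__ = [
    "KineticParseError",
    "LabelingError",
    "parse_kinetic_csv",
    "write_kinetic_csv",
    "write_report_table",
    "read_phenotype_map",
    "write_phenotype_map",
    "load_directory",
]

log = logging.getLogger(__name__)

_META_KEYS = ("project", "species", "strain", "plate", "replicate", "temperature")
_TIME_COLS = ("Time(min)", "Hour")


class KineticParseError(ValueError):
    """A kinetic CSV does not conform to the expected dialect."""


class LabelingError(ValueError):
    """A well has no phenotype label and default labelling is disabled."""


def _fmt(x: float) -> str:
    """Full-precision, round-trip-exact float rendering."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def read_phenotype_map(path: Union[str, Path]) -> dict[tuple[str, str], str]:
    """Read a sidecar phenotype map: (plate, well) -> phenotype label."""
    df = pd.read_csv(path, dtype=str)
    required = {"plate", "well", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise KineticParseError(
            f"phenotype map {path} lacks columns: {sorted(missing)}"
        )
    return {
        (row.plate, row.well): row.phenotype
        for row in df.itertuples(index=False)
    }


def write_phenotype_map(
    mapping: Mapping[tuple[str, str], str], path: Union[str, Path]
) -> Path:
    """Write a phenotype map CSV (columns plate, well, phenotype)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plate", "well", "phenotype"])
        for (plate, well), phen in mapping.items():
            w.writerow([plate, well, phen])
    return path


def parse_kinetic_csv(
    path: Union[str, Path],
    phenotype_map: Optional[Mapping[tuple[str, str], str]] = None,
    metadata_overrides: Optional[Mapping[str, object]] = None,
    *,
    default_phenotype: bool = True,
    require_full_plate: bool = True,
) -> RecordSet:
    """Parse one plate-run kinetic CSV into a RecordSet.

    Returns one :class:`WellRecord` per well column, each carrying the
    full time series.  Metadata comes from the header block, then is
    overridden by ``metadata_overrides`` (the step where the user links a
    kinetic dataset to a strain entry).  Phenotype labels are looked up in
    ``phenotype_map``; an unmapped well gets the default label
    ``"<plate>_<well>"`` unless ``default_phenotype=False``, in which case
    it is a :class:`LabelingError`.

    With ``require_full_plate`` (the default) all 96 well columns must be
    present; relax it to re-read subsets written by filtering.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_rows = 0
    with path.open(newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                header_rows += 1
                continue
            if row[0] in _TIME_COLS:
                break
            if len(row) < 2:
                raise KineticParseError(
                    f"{path}: malformed metadata row {header_rows + 1}: {row}"
                )
            meta[row[0].strip()] = row[1].strip()
            header_rows += 1
        else:
            raise KineticParseError(
                f"{path}: no data header row starting with one of {_TIME_COLS}"
            )

    df = pd.read_csv(path, skiprows=header_rows, dtype=str)
    time_col = df.columns[0]
    well_cols = list(df.columns[1:])

    if len(set(well_cols)) != len(well_cols):
        dupes = sorted({c for c in well_cols if well_cols.count(c) > 1})
        raise KineticParseError(f"{path}: duplicate well columns: {dupes}")
    bad = [c for c in well_cols if not WELL_RE.match(c)]
    if bad:
        raise KineticParseError(f"{path}: unrecognised well columns: {bad}")
    if require_full_plate:
        missing = [w for w in WELL_IDS if w not in well_cols]
        if missing:
            raise KineticParseError(
                f"{path}: missing well column(s): {missing}"
            )

    def _numeric(col: str) -> np.ndarray:
        # numpy's parser is correctly rounded (pandas' fast path is not),
        # which the exact round-trip contract depends on
        raw = df[col]
        try:
            return raw.to_numpy(dtype=str).astype(float)
        except ValueError:
            for r, cell in enumerate(raw):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise KineticParseError(
                        f"{path}: non-numeric value {cell!r} at data row "
                        f"{r + 1}, column {col!r}"
                    ) from None
            raise

    times = _numeric(time_col)
    if time_col == "Hour":
        times = times * 60.0
    steps = np.diff(times)
    if np.any(steps <= 0):
        r = int(np.nonzero(steps <= 0)[0][0]) + 1
        raise KineticParseError(
            f"{path}: time column not strictly increasing at data row {r + 1}"
        )

    overrides = dict(metadata_overrides or {})
    merged = {**meta, **{k: v for k, v in overrides.items() if v is not None}}
    for key in _META_KEYS:
        if key not in merged:
            raise KineticParseError(f"{path}: missing metadata key {key!r}")

    plate = str(merged["plate"])
    records = []
    # preserve the canonical A01..H12 order regardless of column order
    ordered = [w for w in WELL_IDS if w in well_cols] + [
        w for w in well_cols if w not in WELL_IDS
    ]
    for well in ordered:
        if phenotype_map is not None and (plate, well) in phenotype_map:
            phenotype = phenotype_map[(plate, well)]
        elif default_phenotype:
            phenotype = f"{plate}_{well}"
        else:
            raise LabelingError(
                f"{path}: well {well} on plate {plate} has no phenotype label"
            )
        records.append(
            WellRecord(
                project=str(merged["project"]),
                species=str(merged["species"]),
                strain=str(merged["strain"]),
                phenotype=phenotype,
                plate=plate,
                well=well,
                replicate=int(merged["replicate"]),
                temperature=float(merged["temperature"]),
                curve=KineticCurve(times, _numeric(well)),
            )
        )
    return RecordSet(records)


def write_kinetic_csv(rs: RecordSet, path: Union[str, Path]) -> Path:
    """Write a RecordSet as one plate-run kinetic CSV.

    All records must share project/species/strain/plate/replicate/
    temperature (one plate-run per file, as the instrument exports) and an
    identical time grid.  Numbers are written at full precision so that
    :func:`parse_kinetic_csv` inverts the file exactly and a second write
    is byte-identical.
    """
    records = list(rs)
    if not records:
        raise ValueError("cannot write an empty RecordSet")
    conflicts = [
        key
        for key in _META_KEYS
        if len({getattr(r, key) for r in records}) > 1
    ]
    if conflicts:
        raise ValueError(
            f"records mix metadata for keys {conflicts}; "
            "write one plate-run per file"
        )
    times = records[0].curve.times
    for r in records[1:]:
        if not np.array_equal(r.curve.times, times):
            raise ValueError(
                "records in one plate-run file must share a time grid"
            )

    first = records[0]
    by_well = {r.well: r for r in records}
    wells = [w for w in WELL_IDS if w in by_well]
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["project", first.project])
        w.writerow(["species", first.species])
        w.writerow(["strain", first.strain])
        w.writerow(["plate", first.plate])
        w.writerow(["replicate", str(first.replicate)])
        w.writerow(["temperature", _fmt(first.temperature)])
        w.writerow(["Time(min)", *wells])
        for i, t in enumerate(times):
            w.writerow(
                [_fmt(t), *(_fmt(by_well[well].curve.values[i]) for well in wells)]
            )
    return path


def write_report_table(
    rows: Sequence[Sequence], columns: Sequence[str], path: Union[str, Path]
) -> Path:
    """Write a rectangular report table as CSV with a header row.

    Floats are rendered at full precision (round-trip exact); the file
    opens directly in spreadsheet software.
    """
    ncol = len(columns)
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise ValueError(
                f"ragged row {i}: {len(row)} cells, expected {ncol}"
            )
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(columns))
        for row in rows:
            w.writerow(
                [
                    _fmt(c) if isinstance(c, (float, np.floating)) else c
                    for c in row
                ]
            )
    return path


def load_directory(
    directory: Union[str, Path],
    *,
    require_full_plate: bool = True,
) -> RecordSet:
    """Parse every kinetic CSV in a directory into one RecordSet.

    Files are recognised by their metadata header (first cell
    ``project``); a ``phenotype_map.csv`` sidecar, if present, supplies
    phenotype labels.  Files are read in sorted-name order so the result
    is deterministic.
    """
    directory = Path(directory)
    map_path = directory / "phenotype_map.csv"
    phen_map = read_phenotype_map(map_path) if map_path.exists() else None
    combined = RecordSet()
    n_files = 0
    for path in sorted(directory.glob("*.csv")):
        with path.open() as fh:
            first = fh.readline()
        if not first.startswith("project,"):
            continue
        rs = parse_kinetic_csv(
            path, phenotype_map=phen_map, require_full_plate=require_full_plate
        )
        for rec in rs:
            combined.append(rec)
        n_files += 1
    if n_files == 0:
        raise KineticParseError(f"no kinetic CSV files found in {directory}")
    log.info("loaded %d records from %d files in %s", len(combined), n_files, directory)
    return combined
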