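"""Tabular I/O for melt curves, plate layouts, sample metadata and results.

All artifacts are plain CSV (comma-separated, UTF-8, header required,
``.`` decimal) so simulated and instrument-exported runs share one dialect:

* melt CSV      — long format, ``well,temperature,rfu[,amplified]``
* layout CSV    — ``well,sample_id,replicate``
* metadata CSV  — ``sample_id,rna_yield,dna_sex,known_female_anchor,cohort``
* calls CSV     — ``sample_id,call,n_wells_pass,n_modal,fraction_modal,cluster_label,flags``
* cluster CSV   — ``well,sample_id,cluster,outlier,primary_tm``

Parsers reject malformed numerics and ragged temperature grids rather than
silently coercing them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeltCurve",
    "PlateFormatError",
    "read_melt_csv",
    "write_melt_csv",
    "read_layout",
    "read_metadata",
    "read_layout_and_metadata",
    "write_outputs",
]

#: minimum number of temperature points a usable melt trace must have
MIN_CURVE_POINTS = 20

#: tolerance on grid-step uniformity, in °C
GRID_STEP_TOL = 1e-6


class PlateFormatError(ValueError):
    """A tabular input violates the documented plate/melt CSV contract."""


@dataclass(frozen=True)
class MeltCurve:
    """One well's raw fluorescence-vs-temperature melt trace.

    Parameters
    ----------
    well_id : str
        Instrument well identifier (unique within a run).
    temperatures : ndarray
        Strictly increasing, uniformly spaced temperature grid in °C.
    rfu : ndarray
        Relative fluorescence units, same length as ``temperatures``.
    amplified : bool or None
        Instrument/simulator amplification flag. ``None`` means unknown and
        is inferred later from the curve itself during QC.
    """

    well_id: str
    temperatures: np.ndarray
    rfu: np.ndarray
    amplified: bool | None = None

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        rfu = np.asarray(self.rfu, dtype=float)
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "rfu", rfu)
        if temps.ndim != 1 or rfu.ndim != 1 or temps.size != rfu.size:
            raise PlateFormatError(
                f"well {self.well_id!r}: temperatures and rfu must be "
                f"1-D arrays of equal length"
            )
        if temps.size < MIN_CURVE_POINTS:
            raise PlateFormatError(
                f"well {self.well_id!r}: melt trace has {temps.size} points; "
                f"at least {MIN_CURVE_POINTS} required"
            )
        diffs = np.diff(temps)
        if not np.all(diffs > 0):
            raise PlateFormatError(
                f"well {self.well_id!r}: temperatures not strictly increasing"
            )
        if np.ptp(diffs) > GRID_STEP_TOL:
            raise PlateFormatError(
                f"well {self.well_id!r}: temperature grid not uniform "
                f"(step varies by {np.ptp(diffs):.2e} °C)"
            )
        if not np.all(np.isfinite(rfu)):
            raise PlateFormatError(
                f"well {self.well_id!r}: non-finite RFU values"
            )

    @property
    def step(self) -> float:
        """Grid step in °C."""
        return float(self.temperatures[1] - self.temperatures[0])

    def __len__(self) -> int:
        return int(self.temperatures.size)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: object) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing required column(s) {missing}")


def _numeric(series: pd.Series, name: str, path: object) -> pd.Series:
    try:
        return pd.to_numeric(series, errors="raise")
    except (ValueError, TypeError) as exc:
        raise PlateFormatError(f"{path}: non-numeric value in column {name!r}: {exc}") from exc


_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if pd.isna(value):
            return False
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise PlateFormatError(f"cannot interpret {value!r} as a boolean flag")


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read a long-format melt CSV into one :class:`MeltCurve` per well.

    All wells must share an identical uniform temperature grid; a well with
    missing or extra temperature rows raises :class:`PlateFormatError`
    naming the offending well.
    """
    df = pd.read_csv(path, dtype={"well": str})
    _require_columns(df, ["well", "temperature", "rfu"], path)
    df = df.copy()
    df["temperature"] = _numeric(df["temperature"], "temperature", path)
    df["rfu"] = _numeric(df["rfu"], "rfu", path)
    has_amp = "amplified" in df.columns

    curves: list[MeltCurve] = []
    reference_grid: np.ndarray | None = None
    for well, group in df.groupby("well", sort=True):
        group = group.sort_values("temperature")
        temps = group["temperature"].to_numpy()
        amplified = None
        if has_amp:
            flags = {_parse_bool(v) for v in group["amplified"] if not pd.isna(v)}
            if len(flags) > 1:
                raise PlateFormatError(
                    f"{path}: well {well!r} has conflicting amplified flags"
                )
            amplified = flags.pop() if flags else None
        curve = MeltCurve(str(well), temps, group["rfu"].to_numpy(), amplified)
        if reference_grid is None:
            reference_grid = curve.temperatures
        elif curve.temperatures.size != reference_grid.size or not np.allclose(
            curve.temperatures, reference_grid, atol=GRID_STEP_TOL
        ):
            raise PlateFormatError(
                f"{path}: well {well!r} is on a different temperature grid "
                f"than the rest of the plate (ragged input)"
            )
        curves.append(curve)
    if not curves:
        raise PlateFormatError(f"{path}: no melt data rows")
    return curves


def write_melt_csv(curves: Iterable[MeltCurve], path: str | Path) -> None:
    """Write melt curves in the long CSV dialect read by :func:`read_melt_csv`.

    Temperatures carry 2 decimals (exact on the instrument's 0.5 °C grid);
    RFU carries 12 significant digits so write→read round-trips are lossless
    at the 1e−9 level.
    """
    rows = []
    for curve in curves:
        for t, f in zip(curve.temperatures, curve.rfu):
            row = {"well": curve.well_id, "temperature": f"{t:.2f}", "rfu": f"{f:.12g}"}
            if curve.amplified is not None:
                row["amplified"] = str(bool(curve.amplified)).lower()
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read the plate layout CSV (``well,sample_id,replicate``)."""
    df = pd.read_csv(path, dtype={"well": str, "sample_id": str})
    _require_columns(df, ["well", "sample_id", "replicate"], path)
    df["replicate"] = _numeric(df["replicate"], "replicate", path).astype(int)
    dup = df["well"][df["well"].duplicated()]
    if not dup.empty:
        raise PlateFormatError(f"{path}: duplicate well id(s) {sorted(dup.unique())}")
    return df.reset_index(drop=True)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata CSV.

    Columns: ``sample_id, rna_yield, dna_sex, known_female_anchor, cohort``.
    ``rna_yield`` may be blank (unknown) but must be positive when present.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "cohort": str})
    _require_columns(
        df, ["sample_id", "rna_yield", "dna_sex", "known_female_anchor", "cohort"], path
    )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise PlateFormatError(
            f"{path}: duplicate sample_id(s) {sorted(dup.unique())} in metadata"
        )
    df["rna_yield"] = _numeric(df["rna_yield"], "rna_yield", path)
    bad = df["rna_yield"].notna() & (df["rna_yield"] <= 0)
    if bad.any():
        raise PlateFormatError(
            f"{path}: non-positive rna_yield for sample(s) "
            f"{df.loc[bad, 'sample_id'].tolist()}"
        )
    df["known_female_anchor"] = df["known_female_anchor"].map(_parse_bool)
    df["dna_sex"] = df["dna_sex"].fillna("unknown").astype(str).str.lower()
    allowed = {"female", "male", "unknown"}
    bad_sex = set(df["dna_sex"]) - allowed
    if bad_sex:
        raise PlateFormatError(f"{path}: dna_sex value(s) {sorted(bad_sex)} not in {sorted(allowed)}")
    return df.reset_index(drop=True)


def read_layout_and_metadata(
    layout_path: str | Path, metadata_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the layout and metadata tables.

    Every sample referenced by the layout must have a metadata row; missing
    samples get a stub row (``dna_sex='unknown'``, no yield, no anchor flag)
    and a warning, so a run can proceed without truth labels.
    """
    layout = read_layout(layout_path)
    metadata = read_metadata(metadata_path)
    missing = sorted(set(layout["sample_id"]) - set(metadata["sample_id"]))
    if missing:
        warnings.warn(
            f"samples {missing} present in layout but absent from metadata; "
            f"adding stub rows with dna_sex='unknown'",
            stacklevel=2,
        )
        stubs = pd.DataFrame(
            {
                "sample_id": missing,
                "rna_yield": np.nan,
                "dna_sex": "unknown",
                "known_female_anchor": False,
                "cohort": "unknown",
            }
        )
        metadata = pd.concat([metadata, stubs], ignore_index=True)
    return layout, metadata


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_outputs(
    calls: pd.DataFrame,
    clusters: pd.DataFrame,
    report: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the run's calls CSV, per-well cluster CSV and JSON report.

    Deterministic and idempotent: rows are sorted and the report is written
    with sorted keys, so reruns on identical inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out / "calls.csv",
        "clusters": out / "clusters.csv",
        "report": out / "report.json",
    }
    calls.sort_values("sample_id").to_csv(paths["calls"], index=False)
    clusters.sort_values("well").to_csv(paths["clusters"], index=False)
    with open(paths["report"], "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
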