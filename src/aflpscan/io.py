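"""Data model and text-based I/O for AFLP intensity and presence/absence matrices.

The raw observable of a band-intensity AFLP assay is an individuals x markers
matrix of nonnegative fluorescence peak heights, accompanied by a sample map
giving each individual's population, sex and PCR plate.  Everything downstream
(presence calling, the F-model scan, triage) consumes these two objects.

All files are UTF-8 TSV with "." as decimal separator.  Missing intensities are
encoded as empty cells and carried as NaN; they are excluded, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("female", "male", "unknown")

#: canonical categories of low-F_ST outliers after triage
TRIAGE_CATEGORIES = (
    "bimodal_balancing",
    "bimodal_no_per_pop",
    "uni_multimodal",
    "low_frequency",
    "sex_linked",
    "batch_artifact",
)


class AflpDataError(ValueError):
    """Malformed matrix, sample map or fixture input."""


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual: identity plus the metadata the pipeline tests against."""

    sample_id: str
    population_id: str
    sex: str = "unknown"
    plate_id: str = ""

    def __post_init__(self) -> None:
        if not self.population_id:
            raise AflpDataError(f"sample {self.sample_id!r}: empty population_id")
        if self.sex not in SEXES:
            raise AflpDataError(f"sample {self.sample_id!r}: sex {self.sex!r} not in {SEXES}")


def _check_axes(values: pd.DataFrame, samples: pd.DataFrame) -> None:
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].tolist()
        raise AflpDataError(f"duplicate sample IDs: {dups}")
    if values.columns.duplicated().any():
        dups = values.columns[values.columns.duplicated()].tolist()
        raise AflpDataError(f"duplicate marker IDs: {dups}")
    if not values.index.equals(samples.index):
        raise AflpDataError("sample metadata does not match matrix rows")


@dataclass
class IntensityMatrix:
    """Individuals x markers band intensities with joined sample metadata.

    ``values``: DataFrame indexed by sample_id, columns marker IDs, float
    intensities >= 0, NaN for missing.  ``samples``: DataFrame indexed by
    sample_id with columns population_id, sex, plate_id, in matrix row order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_axes(self.values, self.samples)
        arr = self.values.to_numpy()
        finite = arr[~np.isnan(arr)]
        if np.any(~np.isfinite(finite)) or np.any(finite < 0):
            raise AflpDataError("intensities must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population IDs in order of first appearance."""
        return list(dict.fromkeys(self.samples["population_id"]))

    def records(self) -> list[SampleRecord]:
        return [
            SampleRecord(str(sid), str(r.population_id), str(r.sex), str(r.plate_id))
            for sid, r in self.samples.iterrows()
        ]

    def subset_markers(self, marker_ids: Sequence[str]) -> "IntensityMatrix":
        missing = [m for m in marker_ids if m not in self.values.columns]
        if missing:
            raise AflpDataError(f"unknown markers: {missing[:5]}")
        return IntensityMatrix(self.values.loc[:, list(marker_ids)].copy(), self.samples.copy())


@dataclass
class BinaryMatrix:
    """Presence/absence matrix on the same axes as an :class:`IntensityMatrix`.

    Values are 0.0 (absent), 1.0 (present) or NaN (missing).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_axes(self.values, self.samples)
        arr = self.values.to_numpy()
        ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
        if not ok.all():
            raise AflpDataError("binary matrix values must be 0, 1 or missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population_id"]))


def split_marker_id(marker_id: str) -> tuple[str, int]:
    """Split a marker ID of the form primer-combination + index ("CTaa125").

    The primer combination is everything before the first digit.
    """
    for k, ch in enumerate(marker_id):
        if ch.isdigit():
            if k == 0:
                break
            return marker_id[:k], int(marker_id[k:])
    raise AflpDataError(f"marker ID {marker_id!r} is not primer-combination + index")


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_map(path: str | Path) -> pd.DataFrame:
    sm = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "population_id", "sex", "plate_id"}
    if not required.issubset(sm.columns):
        raise AflpDataError(f"sample map must have columns {sorted(required)}")
    if sm["sample_id"].duplicated().any():
        raise AflpDataError("duplicate sample_id in sample map")
    bad = set(sm["sex"]) - set(SEXES)
    if bad:
        raise AflpDataError(f"unknown sex values {sorted(bad)}")
    return sm.set_index("sample_id")


def _read_matrix_values(path: str | Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    markers = header[1:]
    if not markers:
        raise AflpDataError("malformed header: no marker columns")
    if len(set(markers)) != len(markers):
        dups = sorted({m for m in markers if markers.count(m) > 1})
        raise AflpDataError(f"duplicate marker ID columns: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        raise AflpDataError("duplicate sample ID rows in matrix file")
    if df.columns.duplicated().any():
        raise AflpDataError("duplicate marker ID columns in matrix file")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise AflpDataError(f"non-numeric cell in column {col!r}")
    return df.astype(float)


def _join_sample_map(values: pd.DataFrame, sample_map_path: str | Path) -> pd.DataFrame:
    sm = read_sample_map(sample_map_path)
    unknown = set(sm.index) - set(values.index)
    if unknown:
        raise AflpDataError(f"sample map rows not in matrix: {sorted(unknown)[:5]}")
    missing = set(values.index) - set(sm.index)
    if missing:
        raise AflpDataError(f"matrix samples missing from map: {sorted(missing)[:5]}")
    return sm.loc[values.index]


def read_intensity_table(path: str | Path, sample_map_path: str | Path) -> IntensityMatrix:
    """Read a TSV intensity matrix (first row marker IDs, first column sample IDs)
    and join the sample map."""
    values = _read_matrix_values(path)
    return IntensityMatrix(values, _join_sample_map(values, sample_map_path))


def read_binary_table(path: str | Path, sample_map_path: str | Path) -> BinaryMatrix:
    values = _read_matrix_values(path)
    return BinaryMatrix(values, _join_sample_map(values, sample_map_path))


def write_matrix(matrix: IntensityMatrix | BinaryMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def write_sample_map(matrix: IntensityMatrix | BinaryMatrix, path: str | Path) -> None:
    matrix.samples.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# scan results

RESULT_COLUMNS = ["marker_id", "gamma", "po", "q_value", "fst_mean", "call"]


def write_scan_results(results: Iterable, path: str | Path) -> None:
    """Write per-locus scan output as TSV.

    One row per locus: marker ID, posterior selection probability gamma,
    posterior odds (infinity rendered ``inf``), q-value, posterior-mean F_ST
    and the call (neutral/positive/balancing).
    """
    rows = list(results)
    if not rows:
        raise AflpDataError("no scan results to write")
    df = pd.DataFrame(
        [
            {
                "marker_id": r.marker_id,
                "gamma": f"{r.gamma:.6f}",
                "po": "inf" if math.isinf(r.po) else f"{r.po:.6g}",
                "q_value": f"{r.q_value:.6f}",
                "fst_mean": f"{r.fst_mean:.6f}",
                "call": r.call,
            }
            for r in rows
        ],
        columns=RESULT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_scan_results(path: str | Path) -> pd.DataFrame:
    """Read a scan-results TSV back into a DataFrame ("inf" parses to infinity)."""
    df = pd.read_csv(path, sep="\t")
    df["po"] = df["po"].astype(float)
    return df
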