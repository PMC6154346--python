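"""Spectra and reference-table containers plus delimited-text readers/writers.

The canonical interchange format is plain delimited text (comma by default,
tab accepted): a spectra file has a header row of wavelengths in nm and a
first column of sample ids; a reference file has analyte columns written as
``name[unit]``.  The standard instrument grid is 400-2498 nm inclusive at
2 nm steps, i.e. 1050 data points of log(1/R) apparent absorbance.

Note on the grid: an inclusive 400-2500 nm grid at 2 nm would hold 1051
points; the convention adopted here honors the 1050-point count, so the
last channel sits at 2498 nm.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "WavelengthGrid",
    "STANDARD_GRID",
    "SpectraSet",
    "ReferenceTable",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "average_duplicates",
    "align_by_ids",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres."""

    start_nm: float
    step_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.n_points < 2:
            raise ValueError("a grid needs at least 2 points")

    @property
    def stop_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_points - 1)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)


#: 400-2498 nm inclusive, 2 nm steps, 1050 channels (visible + NIR).
STANDARD_GRID = WavelengthGrid(400.0, 2.0, 1050)


def _check_ids(ids: Sequence[str]) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate sample id: {i!r}")
        seen.add(i)
    return ids


@dataclass
class SpectraSet:
    """Sample ids, wavelength grid and a samples x wavelengths log(1/R) matrix.

    ``column_mask`` marks wavelength channels that remain valid after edge
    effects of derivative filters; masked-out (False) channels are excluded
    from model fitting but kept so the grid length never changes.
    """

    sample_ids: list[str]
    grid: WavelengthGrid
    absorbance: np.ndarray
    column_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x wavelengths)")
        n, p = self.absorbance.shape
        if n != len(self.sample_ids):
            raise ValueError("row count does not match number of sample ids")
        if p != self.grid.n_points:
            raise ValueError("column count does not match grid.n_points")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if self.column_mask is None:
            self.column_mask = np.ones(p, dtype=bool)
        else:
            self.column_mask = np.asarray(self.column_mask, dtype=bool)
            if self.column_mask.shape != (p,):
                raise ValueError("column_mask length must equal grid.n_points")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def copy_with(self, absorbance: np.ndarray, column_mask: np.ndarray | None = None) -> "SpectraSet":
        mask = self.column_mask if column_mask is None else column_mask
        return SpectraSet(list(self.sample_ids), self.grid, absorbance, mask.copy())

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        rows = [index[i] for i in ids]
        return SpectraSet(list(ids), self.grid, self.absorbance[rows], self.column_mask.copy())


@dataclass
class ReferenceTable:
    """Per-sample reference analyte concentrations.

    ``analytes`` is a list of (name, unit) pairs; units are carried verbatim
    (e.g. ``umol/g dw`` for glucosinolates, ``mg GAE/g dw`` for phenolics).
    """

    sample_ids: list[str]
    analytes: list[tuple[str, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.analytes)):
            raise ValueError("values shape must be (n_samples, n_analytes)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference values contain non-finite entries")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.analytes]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def unit(self, name: str) -> str:
        return self.analytes[self.names.index(name)][1]

    def subset(self, ids: Sequence[str]) -> "ReferenceTable":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        rows = [index[i] for i in ids]
        return ReferenceTable(list(ids), list(self.analytes), self.values[rows])

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{n}[{u}]" for n, u in self.analytes]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


def _read_table(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    return df


def _to_float(df: pd.DataFrame, path) -> np.ndarray:
    try:
        return df.to_numpy(dtype=float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise


def read_spectra(path, delimiter: str = ",") -> SpectraSet:
    """Read a spectra file: header = wavelengths (nm), first column = ids."""
    df = _read_table(path, delimiter)
    try:
        wl = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"{path}: header column {exc} is not a wavelength") from None
    if len(wl) < 2:
        raise FormatError(f"{path}: need at least two wavelength columns")
    steps = np.diff(wl)
    if steps[0] <= 0 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise FormatError(f"{path}: wavelengths are not uniformly increasing")
    grid = WavelengthGrid(float(wl[0]), float(steps[0]), len(wl))
    values = _to_float(df, path)
    return SpectraSet([str(i) for i in df.index], grid, values)


def write_spectra(s: SpectraSet, path, delimiter: str = ",") -> None:
    cols = [format(w, "g") for w in s.grid.wavelengths]
    df = pd.DataFrame(s.absorbance, index=s.sample_ids, columns=cols)
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter, float_format="%.10g")


def _parse_analyte(col: str) -> tuple[str, str]:
    col = col.strip()
    if col.endswith("]") and "[" in col:
        name, unit = col[:-1].split("[", 1)
        return name.strip(), unit.strip()
    return col, ""


def read_reference(path, delimiter: str = ",") -> ReferenceTable:
    """Read a reference table whose columns are ``name[unit]``."""
    df = _read_table(path, delimiter)
    analytes = [_parse_analyte(c) for c in df.columns]
    values = _to_float(df, path)
    return ReferenceTable([str(i) for i in df.index], analytes, values)


def write_reference(r: ReferenceTable, path, delimiter: str = ",") -> None:
    df = r.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter, float_format="%.10g")


def average_duplicates(s: SpectraSet, pairing: Mapping[str, str]) -> SpectraSet:
    """Average duplicate scans into one spectrum per sample.

    ``pairing`` maps each scan id (a row of ``s``) to its sample id; output
    rows are arithmetic means of all scans of a sample, ordered by first
    appearance of the sample id.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for k, scan in enumerate(s.sample_ids):
        if scan not in pairing:
            raise FormatError(f"scan id {scan!r} missing from pairing")
        sid = pairing[scan]
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(k)
    rows = np.vstack([s.absorbance[groups[sid]].mean(axis=0) for sid in order])
    return SpectraSet(order, s.grid, rows, s.column_mask.copy())


def align_by_ids(s: SpectraSet, r: ReferenceTable) -> tuple[SpectraSet, ReferenceTable, list[str]]:
    """Join spectra and reference strictly on sample id.

    Returns the two tables restricted to the common ids (spectra order) and
    the list of unmatched ids from either side; unmatched ids are reported,
    never dropped silently by the caller's hands.
    """
    ref_ids = set(r.sample_ids)
    spec_ids = set(s.sample_ids)
    common = [i for i in s.sample_ids if i in ref_ids]
    unmatched = [i for i in s.sample_ids if i not in ref_ids]
    unmatched += [i for i in r.sample_ids if i not in spec_ids]
    return s.subset(common), r.subset(common), unmatched
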