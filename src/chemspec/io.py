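"""Readers, writers and validated containers for every table the pipeline touches.

Spectra travel as tab- (or comma-) delimited ASCII matrices with a wavenumber
header row — the common instrument export. Peak tables, feature metadata and
sample design sheets are plain CSV. Samples are always bound to their design
row by ``sample_id`` string, never by position.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = ("sample", "QC")
DEFAULT_DOSES = (0.0, 0.003, 0.03, 0.2)

_DELIMS = {"tab": "\t", "comma": ","}


class ParseError(ValueError):
    """A malformed cell or row in an input file."""


def class_label(pH, dose) -> str:
    """Condition label derived from (pH, dose), e.g. ``'pH7:0.2'``.

    Pure function of its inputs: equal (pH, dose) always map to the same
    label, so the 8-condition design yields exactly 8 labels.
    """
    return f"pH{int(pH)}:{float(dose):g}"


@dataclass
class SpectraMatrix:
    """Absorbance spectra, one sample per row, on a shared wavenumber axis.

    The axis is kept strictly descending (4000 → 600 cm⁻¹ convention); an
    ascending file is re-sorted on load with a logged notice.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} spectra"
            )
        if len(self.wavenumbers) != p:
            raise ValueError(
                f"axis length {len(self.wavenumbers)} != {p} channels"
            )
        d = np.diff(self.wavenumbers)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("wavenumber axis must be strictly monotone")
        if np.all(d > 0):  # normalise to descending
            logger.info("ascending wavenumber axis re-sorted to descending")
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.intensities = self.intensities[:, ::-1].copy()
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def select_channels(self, mask: np.ndarray) -> "SpectraMatrix":
        return SpectraMatrix(
            self.wavenumbers[mask], self.intensities[:, mask], list(self.sample_ids)
        )

    def subset(self, sample_ids: Sequence[str]) -> "SpectraMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return SpectraMatrix(
            self.wavenumbers.copy(), self.intensities[rows], list(sample_ids)
        )


@dataclass
class PeakTable:
    """GC-MS peak areas (samples × features) plus per-feature annotations.

    ``features`` is indexed by feature name and carries ``msi_level``
    (Metabolomics Standards Initiative identification tier, 1–4) and
    ``retention_index``. Abundance columns are aligned to feature rows by
    name, so metadata row order never matters.
    """

    abundances: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self):
        if not self.features.index.is_unique:
            dupes = self.features.index[self.features.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        missing = [c for c in self.abundances.columns if c not in self.features.index]
        if missing:
            raise ValueError(f"features missing from metadata: {missing}")
        levels = self.features["msi_level"]
        bad = self.features.index[~levels.isin([1, 2, 3, 4])].tolist()
        if bad:
            raise ValueError(f"msi_level outside 1-4 for features: {bad}")
        if (self.abundances.values < 0).any():
            raise ValueError("peak areas must be non-negative")
        # keep metadata in abundance-column order
        self.features = self.features.loc[list(self.abundances.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.abundances.columns)

    def subset_features(self, names: Sequence[str]) -> "PeakTable":
        return PeakTable(self.abundances[list(names)].copy(), self.features.loc[list(names)].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakTable":
        return PeakTable(self.abundances.loc[list(sample_ids)].copy(), self.features.copy())


@dataclass
class SampleDesign:
    """Experimental design sheet: pH, dose, replicate structure, role.

    pH and dose are categorical levels (the condition grid), never free
    floats; the class label of a sample is ``class_label(pH, dose)``.
    """

    table: pd.DataFrame
    dose_set: tuple = DEFAULT_DOSES

    REQUIRED = ("sample_id", "pH", "dose", "bio_rep", "tech_rep", "role")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design sheet missing columns: {missing}")
        t = self.table
        bad_roles = sorted(set(t["role"]) - set(VALID_ROLES))
        if bad_roles:
            raise ValueError(f"unknown role values: {bad_roles}")
        if not t["sample_id"].is_unique:
            dupes = t["sample_id"][t["sample_id"].duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        s = t[t["role"] == "sample"]
        key = list(zip(s["pH"], s["dose"], s["bio_rep"], s["tech_rep"]))
        if len(key) != len(set(key)):
            seen, dupes = set(), []
            for k in key:
                if k in seen:
                    dupes.append(k)
                seen.add(k)
            raise ValueError(f"duplicate (pH,dose,bio_rep,tech_rep) rows: {dupes}")
        self.table = t.reset_index(drop=True)

    def validate_doses(self):
        """Strict mode: every sample dose must come from the declared set."""
        s = self.table[self.table["role"] == "sample"]
        bad = sorted(set(s["dose"]) - set(self.dose_set))
        if bad:
            raise ValueError(f"doses outside declared set {self.dose_set}: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def labels(self) -> pd.Series:
        """Class label per row (QC rows labelled 'QC'), indexed by sample_id."""
        t = self.table
        lab = [
            "QC" if r == "QC" else class_label(p, d)
            for r, p, d in zip(t["role"], t["pH"], t["dose"])
        ]
        return pd.Series(lab, index=t["sample_id"].values, name="class")

    def samples(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "sample"].copy()

    def qc(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "QC"].copy()

    def subset(self, sample_ids: Iterable[str]) -> "SampleDesign":
        ids = set(sample_ids)
        return SampleDesign(
            self.table[self.table["sample_id"].isin(ids)].copy(), self.dose_set
        )


# ---------------------------------------------------------------------------
# spectra I/O

def read_spectra(path, dialect: str = "tab") -> SpectraMatrix:
    """Read an ASCII spectra matrix: header row = wavenumbers, then
    ``sample_id`` + intensities per row.

    Raises :class:`ParseError` naming the offending row/column on ragged
    rows, non-numeric cells or missing values.
    """
    delim = _DELIMS[dialect]
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    rows = [r for r in rows if r]  # drop blank lines
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one spectrum")
    header = rows[0]
    axis_cells = header[1:] if header[0].strip() and not _is_number(header[0]) else header
    try:
        wavenumbers = np.array([float(c) for c in axis_cells])
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric wavenumber in header: {e}") from None
    p = len(wavenumbers)
    ids, data = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != p + 1:
            raise ParseError(
                f"{path}: row {i} has {len(row)} fields, expected {p + 1}"
            )
        ids.append(row[0])
        vals = np.empty(p)
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                raise ParseError(f"{path}: missing value at row {i}, column {j + 2}")
            try:
                vals[j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {i}, column {j + 2}"
                ) from None
        data.append(vals)
    return SpectraMatrix(wavenumbers, np.vstack(data), ids)


def write_spectra(s: SpectraMatrix, path, dialect: str = "tab") -> None:
    delim = _DELIMS[dialect]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["sample_id"] + [repr(float(v)) for v in s.wavenumbers])
        for sid, row in zip(s.sample_ids, s.intensities):
            w.writerow([sid] + [repr(float(v)) for v in row])


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# peak table / design I/O

def read_peak_table(path, meta_path) -> PeakTable:
    """Read a samples × features abundance CSV plus a feature metadata CSV.

    Metadata rows are joined to abundance columns by feature name; row order
    in the metadata file is irrelevant.
    """
    ab = pd.read_csv(path, index_col=0)
    meta = pd.read_csv(meta_path)
    if "name" not in meta.columns:
        raise ValueError("feature metadata needs a 'name' column")
    meta = meta.set_index("name")
    missing = [c for c in ab.columns if c not in meta.index]
    if missing:
        raise ValueError(f"features missing from metadata: {missing}")
    if ab.isna().any().any():
        raise ValueError("peak table contains missing values")
    return PeakTable(ab, meta)


def write_peak_table(pt: PeakTable, path, meta_path) -> None:
    pt.abundances.to_csv(path, index_label="sample_id")
    pt.features.to_csv(meta_path, index_label="name")


def read_design(path, strict: bool = False, dose_set=DEFAULT_DOSES) -> SampleDesign:
    t = pd.read_csv(path)
    design = SampleDesign(t, tuple(dose_set))
    if strict:
        design.validate_doses()
    return design


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, index=False)


def convert_metabolite_xlsx(
    xlsx_path,
    csv_path,
    sheet=0,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Convert a supplementary metabolite-list workbook to the feature
    metadata CSV this package reads.

    ``column_map`` maps workbook column names to the canonical
    ``name`` / ``msi_level`` / ``retention_index`` fields; identity by
    default.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=column_map)
    keep = [c for c in ("name", "msi_level", "retention_index") if c in df.columns]
    if "name" not in keep or "msi_level" not in keep:
        raise ValueError("workbook must provide 'name' and 'msi_level' columns (after mapping)")
    out = df[keep]
    out.to_csv(csv_path, index=False)
    return out
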