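"""Readers, writers and validated containers for every table the pipeline touches.

All on-disk formats are delimited text (tab-separated by default, comma via
``sep=","``): ROI time series as T rows x N columns, connectivity matrices as
N x N, phenotypes as a named-header table, rigid-body motion parameters as
T x 6 (three translations in mm, then three rotations in radians).

The 90-region AAL parcellation ships as a package fixture
(``data/aal90_nodes.tsv``).  Its indices, abbreviations and names follow the
standard AAL-90 convention; the MNI coordinates are approximate region
centroids kept for reports and plots only — no computation consumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

GROUP_LABELS = ("D-AD", "nD-AD", "NC")
SEX_LABELS = ("M", "F")

#: phenotype columns that must be present in every phenotype table
REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "group", "age", "sex")

#: optional numeric phenotype columns (absent cells are allowed)
OPTIONAL_PHENOTYPE_COLUMNS = (
    "education",
    "duration_months",
    "mmse",
    "hamd",
    "dnpi",
    "mean_rms",
    "mean_fd",
)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtlasNode:
    """One parcellation region: 1-based index, short label, name, MNI centroid."""

    index: int
    abbreviation: str
    name: str
    mni_xyz: tuple[float, float, float]


@dataclass
class RoiTimeSeries:
    """One subject's preprocessed regional signals, T time points x N nodes."""

    subject_id: str
    values: np.ndarray
    t_repeat: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"{self.subject_id}: time series must be 2-D, got {self.values.ndim}-D"
            )
        if self.values.shape[0] < 3:
            raise ValidationError(
                f"{self.subject_id}: need at least 3 time points, got {self.values.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            t, n = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"{self.subject_id}: non-finite value at time point {t + 1}, node {n + 1}"
            )
        variances = self.values.var(axis=0)
        dead = np.flatnonzero(variances <= 0.0)
        if dead.size:
            raise ValidationError(
                f"{self.subject_id}: node {dead[0] + 1} has zero variance; "
                "Pearson correlation is undefined for constant signals"
            )

    @property
    def n_timepoints(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[1])


@dataclass
class SubjectPhenotype:
    """Group membership, demographics and clinical scores for one subject.

    ``mean_rms``/``mean_fd`` (mm) may be filled later from motion traces.
    Absent optional scores are ``None``.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    education: Optional[float] = None
    duration_months: Optional[float] = None
    mmse: Optional[float] = None
    hamd: Optional[float] = None
    dnpi: Optional[float] = None
    mean_rms: Optional[float] = None
    mean_fd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValidationError(
                f"{self.subject_id}: unknown group {self.group!r}; "
                f"expected one of {GROUP_LABELS}"
            )
        if self.sex not in SEX_LABELS:
            raise ValidationError(
                f"{self.subject_id}: unknown sex {self.sex!r}; expected M or F"
            )
        for name in ("age", "education", "duration_months", "mmse", "hamd",
                     "dnpi", "mean_rms", "mean_fd"):
            value = getattr(self, name)
            if value is None:
                continue
            value = float(value)
            if not math.isfinite(value):
                raise ValidationError(f"{self.subject_id}: {name} is not finite")
            if value < 0:
                raise ValidationError(f"{self.subject_id}: {name} is negative ({value})")
            setattr(self, name, value)


@dataclass
class MotionParams:
    """Rigid-body realignment parameters, T x 6 (mm, mm, mm, rad, rad, rad)."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise FormatError(
                f"{self.subject_id}: motion parameters must be T x 6, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.subject_id}: non-finite motion parameter")

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


# ---------------------------------------------------------------------------
# low-level parsing
# ---------------------------------------------------------------------------

def _split_rows(path: Path, sep: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            rows.append(line.split(sep))
    if not rows:
        raise FormatError(f"{path}: file is empty")
    return rows


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _parse_numeric_rows(rows: Sequence[Sequence[str]], path: Path,
                        first_data_row: int) -> np.ndarray:
    data = np.empty((len(rows), len(rows[0])), dtype=float)
    for i, row in enumerate(rows):
        for j, token in enumerate(row):
            try:
                data[i, j] = float(token)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {token!r} at row "
                    f"{first_data_row + i}, column {j + 1}"
                ) from None
    return data


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def load_atlas(path: Optional[Path | str] = None) -> list[AtlasNode]:
    """Load a node table (defaults to the packaged AAL-90 fixture).

    Enforces unique, contiguous 1..N indices and unique abbreviations.
    """
    if path is None:
        ref = resources.files("costnet").joinpath("data/aal90_nodes.tsv")
        with resources.as_file(ref) as fixture:
            frame = pd.read_csv(fixture, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    required = {"index", "abbreviation", "name", "x", "y", "z"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"atlas table missing columns: {sorted(missing)}")
    nodes = [
        AtlasNode(
            index=int(row["index"]),
            abbreviation=str(row["abbreviation"]),
            name=str(row["name"]),
            mni_xyz=(float(row["x"]), float(row["y"]), float(row["z"])),
        )
        for row in frame.to_dict("records")
    ]
    indices = [node.index for node in nodes]
    if indices != list(range(1, len(nodes) + 1)):
        raise ValidationError("atlas indices must be unique and contiguous from 1")
    abbreviations = [node.abbreviation for node in nodes]
    if len(set(abbreviations)) != len(abbreviations):
        raise ValidationError("atlas abbreviations must be unique")
    return nodes


def atlas_abbreviations(atlas: Sequence[AtlasNode]) -> list[str]:
    return [node.abbreviation for node in atlas]


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def read_timeseries(path: Path | str, expected_nodes: int = 90, *,
                    sep: str = "\t", subject_id: Optional[str] = None,
                    atlas: Optional[Sequence[AtlasNode]] = None,
                    t_repeat: float = 2.0) -> RoiTimeSeries:
    """Read one subject's T x N regional time-series table.

    An optional first header row of node abbreviations is accepted; when an
    atlas is supplied the header must match its order exactly (headers are
    checked, never used to reorder columns).
    """
    path = Path(path)
    rows = _split_rows(path, sep)
    header: Optional[list[str]] = None
    if rows and not _looks_numeric(rows[0][0]):
        header = [token.strip() for token in rows[0]]
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: no data rows after header")
    widths = {len(row) for row in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    width = widths.pop()
    if width != expected_nodes:
        raise FormatError(
            f"{path}: expected {expected_nodes} node columns, found {width}"
        )
    if header is not None:
        if len(header) != width:
            raise FormatError(
                f"{path}: header has {len(header)} labels for {width} columns"
            )
        if atlas is not None:
            expected = atlas_abbreviations(atlas)
            if header != expected:
                bad = next(
                    (k for k, (h, e) in enumerate(zip(header, expected)) if h != e)
                )
                raise ValidationError(
                    f"{path}: header column {bad + 1} is {header[bad]!r}, "
                    f"atlas expects {expected[bad]!r}"
                )
    data = _parse_numeric_rows(rows, path, first_data_row=2 if header else 1)
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        values=data,
        t_repeat=t_repeat,
    )


def write_timeseries(series: RoiTimeSeries, path: Path | str, *,
                     sep: str = "\t") -> None:
    np.savetxt(path, series.values, delimiter=sep, fmt="%.17g")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, path: Path | str, *, sep: str = "\t") -> None:
    """Write a square matrix so that :func:`read_matrix` round-trips bit-exactly.

    ``%.17g`` preserves every IEEE double exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise FormatError(f"matrix must be square, got shape {matrix.shape}")
    np.savetxt(path, matrix, delimiter=sep, fmt="%.17g")


def read_matrix(path: Path | str, *, sep: str = "\t") -> np.ndarray:
    path = Path(path)
    rows = _split_rows(path, sep)
    data = _parse_numeric_rows(rows, path, first_data_row=1)
    if data.shape[0] != data.shape[1]:
        raise FormatError(f"{path}: matrix is {data.shape[0]} x {data.shape[1]}, not square")
    return data


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: Path | str, *, sep: str = "\t") -> list[SubjectPhenotype]:
    """Read the subject phenotype table (named header, one row per subject)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "group": str, "sex": str})
    missing = set(REQUIRED_PHENOTYPE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if frame["subject_id"].duplicated().any():
        dup = frame.loc[frame["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate subject_id {dup!r}")
    records: list[SubjectPhenotype] = []
    for row in frame.to_dict("records"):
        kwargs = {
            "subject_id": str(row["subject_id"]),
            "group": str(row["group"]),
            "age": float(row["age"]),
            "sex": str(row["sex"]).strip(),
        }
        for name in OPTIONAL_PHENOTYPE_COLUMNS:
            if name in frame.columns:
                value = row[name]
                kwargs[name] = None if pd.isna(value) else float(value)
        records.append(SubjectPhenotype(**kwargs))
    return records


def phenotypes_to_frame(phenotypes: Sequence[SubjectPhenotype]) -> pd.DataFrame:
    """Tabular view of phenotype records (absent scores become NaN)."""
    rows = []
    for p in phenotypes:
        rows.append({
            "subject_id": p.subject_id, "group": p.group, "age": p.age,
            "sex": p.sex, "education": p.education,
            "duration_months": p.duration_months, "mmse": p.mmse,
            "hamd": p.hamd, "dnpi": p.dnpi, "mean_rms": p.mean_rms,
            "mean_fd": p.mean_fd,
        })
    return pd.DataFrame(rows)


def write_phenotypes(phenotypes: Sequence[SubjectPhenotype], path: Path | str, *,
                     sep: str = "\t") -> None:
    phenotypes_to_frame(phenotypes).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# motion parameters
# ---------------------------------------------------------------------------

def read_motion(path: Path | str, *, sep: str = "\t", degrees: bool = False,
                subject_id: Optional[str] = None) -> MotionParams:
    """Read a T x 6 realignment-parameter table.

    Rotations are radians by default; pass ``degrees=True`` for tables written
    in degrees (silent unit guessing is deliberately not attempted).
    """
    path = Path(path)
    rows = _split_rows(path, sep)
    if not _looks_numeric(rows[0][0]):
        rows = rows[1:]
    widths = {len(row) for row in rows}
    if widths != {6}:
        raise FormatError(f"{path}: motion table must have 6 columns, found {sorted(widths)}")
    data = _parse_numeric_rows(rows, path, first_data_row=1)
    if degrees:
        data = data.copy()
        data[:, 3:] = np.deg2rad(data[:, 3:])
    return MotionParams(subject_id=subject_id or path.stem, values=data)


def write_motion(motion: MotionParams, path: Path | str, *, sep: str = "\t") -> None:
    np.savetxt(path, motion.values, delimiter=sep, fmt="%.17g")
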