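"""Readers and writers for the formats the pipeline touches.

Volumes are NIfTI-1 (via nibabel), motion traces are plain-text 6-column
files (3 translations in mm, 3 rotations in degrees), the cohort table is
TSV/CSV, and run configuration is YAML/JSON.

Conventions
-----------
* Voxel coordinates are 0-based array indices; world (MNI-style) coordinates
  in mm are produced only through the affine.
* Rotations are stored in degrees throughout.
* All volumes entering one analysis must share grid shape and affine; the
  cohort loader asserts this and fails loudly otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("rehoscope")

GROUPS = ("BD", "HC")
SEXES = ("M", "F")

COHORT_COLUMNS = (
    "subject_id",
    "group",
    "sex",
    "age",
    "education",
    "hamd",
    "illness_length",
    "n_episodes",
)


@dataclass
class Bold4D:
    """A subject's 4D BOLD time series.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensity in arbitrary units, float64 in memory.
    affine : ndarray, shape (4, 4)
        Voxel-to-world matrix in mm.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Binary brain mask on the analysis grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError("mask has no nonzero voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: t x 3 translations (mm), t x 3 rotations (deg)."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be t x 3")
        if self.translations.shape[0] < 1:
            raise ValueError("empty motion trace")

    @property
    def n_rows(self) -> int:
        return self.translations.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Return the t x 6 regressor block [translations | rotations]."""
        return np.hstack([self.translations, self.rotations])

    def tail(self, n: int) -> "MotionTrace":
        """Last ``n`` rows (used to align a full-length trace with post-drop data)."""
        if n > self.n_rows:
            raise ValueError(f"requested {n} rows from trace of length {self.n_rows}")
        return MotionTrace(self.translations[-n:], self.rotations[-n:])


@dataclass
class CohortTable:
    """Typed per-subject cohort table (group labels and clinical covariates)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("cohort table is empty")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad_group = set(df["group"].dropna()) - set(GROUPS)
        if bad_group or df["group"].isna().any():
            raise ValueError(f"unknown or missing group labels: {sorted(bad_group)}")
        bad_sex = set(df["sex"].dropna()) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def patients(self) -> pd.DataFrame:
        return self.table[self.table["group"] == "BD"].reset_index(drop=True)

    def controls(self) -> pd.DataFrame:
        return self.table[self.table["group"] == "HC"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_bold(path: str | Path, tr: float | None = None) -> Bold4D:
    """Load a 4D NIfTI-1 BOLD volume.

    The repetition time is taken from the header's 4th zoom unless ``tr``
    is given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such BOLD file: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D BOLD, got {img.ndim}D in {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite voxels in {path}")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
        if tr <= 0:
            raise ValueError(f"no repetition time in header of {path}; pass tr=")
    return Bold4D(data=data, affine=img.affine.copy(), tr=float(tr))


def write_bold(bold: Bold4D, path: str | Path) -> Path:
    """Write a Bold4D to NIfTI-1 at float32, recording TR in the header."""
    path = Path(path)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (bold.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI map; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such map file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D map, got {img.ndim}D in {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return data, img.affine.copy()


def write_map(data: np.ndarray, affine: np.ndarray, path: str | Path,
              description: str = "") -> Path:
    """Write a 3D map to NIfTI-1 at float32; the affine is preserved exactly."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3D map, got {data.ndim}D")
    if not np.isfinite(data).all():
        raise ValueError("map contains non-finite values")
    path = Path(path)
    img = nib.Nifti1Image(data.astype(np.float32), np.asarray(affine, dtype=np.float64))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BrainMask:
    data, affine = read_map(path)
    return BrainMask(data=data > 0.5, affine=affine)


def write_mask(mask: BrainMask, path: str | Path) -> Path:
    return write_map(mask.data.astype(np.uint8), mask.affine, path)


# ---------------------------------------------------------------------------
# Motion and cohort tables
# ---------------------------------------------------------------------------

def read_motion(path: str | Path) -> MotionTrace:
    """Read a whitespace-delimited 6-column motion file.

    Columns 1-3 are translations (mm), columns 4-6 rotations (degrees) —
    mirroring rigid-body realignment output.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such motion file: {path}")
    try:
        arr = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric motion file {path}: {exc}") from exc
    if arr.shape[1] != 6:
        raise ValueError(f"motion file {path} has {arr.shape[1]} columns, expected 6")
    return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:])


def write_motion(trace: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(str(path), trace.as_matrix(), fmt="%.6f")
    return path


def load_cohort(path: str | Path) -> CohortTable:
    """Load and validate the cohort table (TSV or CSV, inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort table: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty cohort table: {path}") from exc
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortTable(table=df)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.table.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


# ---------------------------------------------------------------------------
# Grid consistency
# ---------------------------------------------------------------------------

def assert_same_grid(shape: tuple[int, ...], affine: np.ndarray,
                     other_shape: tuple[int, ...], other_affine: np.ndarray,
                     what: str = "volume") -> None:
    """Raise if two volumes are not on the identical grid (shape + affine)."""
    if tuple(shape[:3]) != tuple(other_shape[:3]):
        raise ValueError(f"{what}: grid shape {other_shape[:3]} != expected {shape[:3]}")
    if not np.allclose(affine, other_affine, atol=1e-4):
        raise ValueError(f"{what}: affine differs from the reference grid")


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the affine)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def voxel_volume_mm3(affine: np.ndarray) -> float:
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def world_coords(affine: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (n x 3) to world mm coordinates (n x 3)."""
    voxels = np.atleast_2d(voxels)
    hom = np.hstack([voxels, np.ones((voxels.shape[0], 1))])
    return (np.asarray(affine) @ hom.T).T[:, :3]


def configure_logging(log_file: str | Path | None = None,
                      level: int = logging.INFO) -> logging.Logger:
    """Structured run logging to stderr and optionally a run log file."""
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(str(log_file))
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
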