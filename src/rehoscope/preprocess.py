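"""Per-subject temporal preprocessing.

Fixed stage order (logged): initial-volume discard -> motion QC -> nuisance
regression -> band-pass filtering. Regression precedes filtering. Nuisance
regressors (6 motion parameters, linear drift, global mean signal, intercept)
are taken from the retained post-drop time points only; the global signal is
the mean over the brain mask of the post-drop, unfiltered data.

The band-pass filter is an ideal (rectangular) frequency-domain filter:
DFT coefficients with frequency inside [f_lo, f_hi] are retained, all others
— including the zero-frequency term — are zeroed, so every output series has
exactly zero mean and exact spectral post-conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import Bold4D, BrainMask, MotionTrace, assert_same_grid

logger = logging.getLogger("rehoscope")

NUISANCE_COLUMNS = (
    "intercept",
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "linear_drift",
    "global_signal",
)


@dataclass
class QcReport:
    """Maximum excursion (max - min over retained time points) per plane."""

    subject_id: str
    trans_excursion_mm: np.ndarray   # (3,)
    rot_excursion_deg: np.ndarray    # (3,)
    passed: bool

    def as_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "passed": self.passed}
        for i, ax in enumerate("xyz"):
            d[f"trans_{ax}_mm"] = float(self.trans_excursion_mm[i])
        for i, ax in enumerate(("roll", "pitch", "yaw")):
            d[f"rot_{ax}_deg"] = float(self.rot_excursion_deg[i])
        return d


@dataclass
class NuisanceSet:
    """Design matrix for spurious-variance removal.

    Columns: intercept, 6 motion parameters, mean-centred linear drift, and
    the global (brain-mean) signal.
    """

    motion: np.ndarray          # t x 6
    linear_drift: np.ndarray    # t
    global_signal: np.ndarray   # t

    def __post_init__(self) -> None:
        t = self.motion.shape[0]
        if self.motion.shape != (t, 6):
            raise ValueError("motion block must be t x 6")
        if self.linear_drift.shape != (t,) or self.global_signal.shape != (t,):
            raise ValueError("all nuisance columns must have length t")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]

    def design_matrix(self) -> np.ndarray:
        t = self.n_timepoints
        return np.column_stack([
            np.ones(t),
            self.motion,
            self.linear_drift,
            self.global_signal,
        ])


def drop_initial_volumes(bold: Bold4D, n_drop: int) -> Bold4D:
    """Discard the first ``n_drop`` volumes (scanner calibration period)."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if n_drop >= bold.n_volumes:
        raise ValueError(
            f"cannot drop {n_drop} of {bold.n_volumes} volumes")
    if n_drop == 0:
        return bold
    return Bold4D(data=bold.data[..., n_drop:], affine=bold.affine, tr=bold.tr)


def motion_qc(trace: MotionTrace, subject_id: str = "",
              trans_mm: float = 2.0, rot_deg: float = 2.0) -> QcReport:
    """Maximum-excursion motion QC.

    Excursion per plane is max(value) - min(value) over the trace. A subject
    passes iff every translation excursion <= ``trans_mm`` and every rotation
    excursion <= ``rot_deg`` (defaults 2 mm, 2 degrees).
    """
    te = trace.translations.max(axis=0) - trace.translations.min(axis=0)
    re = trace.rotations.max(axis=0) - trace.rotations.min(axis=0)
    passed = bool((te <= trans_mm).all() and (re <= rot_deg).all())
    if not passed:
        logger.warning("motion QC failed for %s: trans %s mm, rot %s deg",
                       subject_id or "<subject>", np.round(te, 3), np.round(re, 3))
    return QcReport(subject_id=subject_id, trans_excursion_mm=te,
                    rot_excursion_deg=re, passed=passed)


def build_nuisance(bold: Bold4D, motion: MotionTrace,
                   mask: BrainMask) -> NuisanceSet:
    """Assemble the nuisance set for the retained time points.

    A motion trace longer than the retained series (e.g. recorded before the
    initial-volume discard) is truncated to its last t rows; a shorter trace
    is an error.
    """
    t = bold.n_volumes
    assert_same_grid(bold.shape3d, bold.affine, mask.data.shape, mask.affine, "mask")
    if motion.n_rows < t:
        raise ValueError(
            f"motion trace has {motion.n_rows} rows < {t} retained volumes")
    if motion.n_rows > t:
        motion = motion.tail(t)
    drift = np.arange(t, dtype=float)
    drift -= drift.mean()
    global_signal = bold.data[mask.data].mean(axis=0)
    return NuisanceSet(motion=motion.as_matrix(), linear_drift=drift,
                       global_signal=global_signal)


def regress_nuisance(bold: Bold4D, nuisance: NuisanceSet) -> Bold4D:
    """Replace every voxel series by its least-squares residual.

    The residual is orthogonal to all regressors; because the intercept is in
    the design, output voxel means are ~0. Idempotent to numerical tolerance.
    """
    if nuisance.n_timepoints != bold.n_volumes:
        raise ValueError(
            f"nuisance length {nuisance.n_timepoints} != {bold.n_volumes} volumes")
    X = nuisance.design_matrix()
    # Collinearity check on centred columns (intercept absorbs means).
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient nuisance design; offending columns: {bad}")
    shape3d = bold.shape3d
    Y = bold.data.reshape(-1, bold.n_volumes).T          # t x v
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return Bold4D(data=resid.T.reshape(shape3d + (-1,)), affine=bold.affine,
                  tr=bold.tr)


def _collinear_columns(Xc: np.ndarray) -> list[str]:
    """Name the columns involved in a rank deficiency (diagnostic only)."""
    bad = []
    for j in range(1, Xc.shape[1]):          # skip intercept
        others = np.delete(Xc, j, axis=1)
        col = Xc[:, j]
        if np.linalg.norm(col) < 1e-12:
            bad.append(NUISANCE_COLUMNS[j])
            continue
        proj, *_ = np.linalg.lstsq(others, col, rcond=None)
        if np.linalg.norm(col - others @ proj) < 1e-8 * np.linalg.norm(col):
            bad.append(NUISANCE_COLUMNS[j])
    return bad or ["<unidentified>"]


def bandpass(bold: Bold4D, f_lo: float, f_hi: float) -> Bold4D:
    """Ideal frequency-domain band-pass along the time axis.

    Keeps DFT bins with f_lo <= f <= f_hi (f > 0); zeros everything else
    including DC, so output voxel means are exactly 0. Linear in its input.
    """
    nyq = 1.0 / (2.0 * bold.tr)
    if not (0 <= f_lo < f_hi <= nyq + 1e-12):
        raise ValueError(f"band ({f_lo}, {f_hi}) invalid; Nyquist is {nyq} Hz")
    t = bold.n_volumes
    freqs = np.fft.rfftfreq(t, d=bold.tr)
    keep = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    coef = np.fft.rfft(bold.data, axis=-1)
    coef[..., ~keep] = 0.0
    out = np.fft.irfft(coef, n=t, axis=-1)
    return Bold4D(data=out, affine=bold.affine, tr=bold.tr)


def preprocess_subject(bold: Bold4D, motion: MotionTrace, mask: BrainMask,
                       subject_id: str = "", n_drop: int = 10,
                       band: tuple[float, float] = (0.01, 0.08),
                       qc_trans_mm: float = 2.0, qc_rot_deg: float = 2.0,
                       ) -> tuple[Bold4D, QcReport]:
    """Run the full per-subject preprocessing chain.

    Order: drop -> QC -> nuisance regression -> band-pass. QC failure is
    reported, not fatal (the caller decides whether to exclude the subject).
    """
    bold = drop_initial_volumes(bold, n_drop)
    if motion.n_rows > bold.n_volumes:
        motion = motion.tail(bold.n_volumes)
    qc = motion_qc(motion, subject_id, qc_trans_mm, qc_rot_deg)
    nuis = build_nuisance(bold, motion, mask)
    bold = regress_nuisance(bold, nuis)
    bold = bandpass(bold, *band)
    logger.info("preprocess: %s drop=%d band=%s qc_pass=%s",
                subject_id or "<subject>", n_drop, band, qc.passed)
    return bold, qc
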