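"""Synthetic two-group resting-state BOLD cohort generator.

The generator plants group differences in *local temporal synchrony*: inside
designated effect regions every voxel's series is

    sqrt(1 - rho) * independent band-limited noise
  + sqrt(rho)     * region-shared band-limited signal,

so the shared-variance fraction ``rho`` equals the expected pairwise
correlation between in-region voxels after band-pass filtering, and is the
quantity the regional-homogeneity statistic responds to. Outside the effect
regions the background is spatially smooth broadband noise (1-voxel Gaussian
smoothed), so background homogeneity is realistic (> 0) rather than at the
independent-noise floor. Linear drift, a global signal component, and
plausible rigid-body motion traces are added per subject.

Synchrony is parameterized as the shared-variance fraction rho rather than a
target Kendall's W because W depends on the neighbourhood size K and series
length n; the W(rho) mapping is characterized empirically in the test suite.

Grids of any size share a fixed field of view (FOV_MM, centred near the
anterior commissure), so the canonical DMN loci in MNI-style mm coordinates
fall inside every grid; voxel size scales inversely with grid shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core_io import (
    Bold4D,
    BrainMask,
    CohortTable,
    MotionTrace,
    write_bold,
    write_cohort,
    write_mask,
    write_motion,
)

logger = logging.getLogger("rehoscope")

# Field of view (mm) shared by all synthetic grids, and its world-space centre.
FOV_MM = np.array([192.0, 216.0, 156.0])
FOV_CENTER_MM = np.array([0.0, 0.0, 8.0])

# Brain: ellipsoid in world space (centre, semi-axes, mm).
BRAIN_CENTER_MM = np.array([0.0, -8.0, 8.0])
BRAIN_SEMIAXES_MM = np.array([85.0, 100.0, 70.0])

#: Canonical default-mode-network loci (MNI-style mm): medial prefrontal,
#: posterior cingulate/precuneus, bilateral inferior parietal, bilateral
#: lateral temporal, bilateral hippocampal formation.
DMN_LOCI_MM: dict[str, tuple[float, float, float]] = {
    "mPFC": (0.0, 52.0, -2.0),
    "PCC": (0.0, -54.0, 28.0),
    "L_IPL": (-46.0, -62.0, 32.0),
    "R_IPL": (48.0, -60.0, 32.0),
    "L_LatTemp": (-58.0, -24.0, -12.0),
    "R_LatTemp": (58.0, -24.0, -12.0),
    "L_Hipp": (-24.0, -22.0, -18.0),
    "R_Hipp": (24.0, -22.0, -18.0),
}

# Cohort composition emulated (group sizes, sex ratios, clinical summaries):
# BD 9M:17F, age 32.35+-11.31; HC 10M:16F, age 31.92+-12.19; education
# 12.32+-2.0 vs 13.15+-2.13 years; HAMD 19.65+-2.48 (floor 17); illness
# 4.20+-1.70 years; 3.44+-1.45 depressive episodes.
_DEMOG = {
    "BD": {"male_frac": 9 / 26, "age": (32.35, 11.31), "edu": (12.32, 2.0)},
    "HC": {"male_frac": 10 / 26, "age": (31.92, 12.19), "edu": (13.15, 2.13)},
}
_CLINICAL = {"hamd": (19.65, 2.48, 17.0, 30.0), "illness": (4.20, 1.70),
             "episodes": (3.44, 1.45)}


@dataclass
class EffectRegion:
    """A sphere (world mm) whose voxels share a band-limited signal."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    rho_hc: float
    rho_bd: float

    def __post_init__(self) -> None:
        for rho in (self.rho_hc, self.rho_bd):
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"rho must be in [0, 1], got {rho}")

    def rho(self, group: str) -> float:
        return self.rho_bd if group == "BD" else self.rho_hc


def default_effect_regions(radius_mm: float = 15.0, rho_hc: float = 0.3,
                           rho_bd: float = 0.6) -> list[EffectRegion]:
    """One effect sphere at each canonical DMN locus."""
    return [EffectRegion(c, radius_mm, rho_hc, rho_bd) for c in DMN_LOCI_MM.values()]


@dataclass
class SynthDesign:
    """Full specification of a synthetic cohort.

    Defaults are the paper-scale acquisition: 64x64x33 grid, TR 2 s, 240
    volumes, 26 subjects per group, signal band 0.01-0.08 Hz.
    """

    shape: tuple[int, int, int] = (64, 64, 33)
    tr: float = 2.0
    n_volumes: int = 240
    n_per_group: int = 26
    effect_regions: list[EffectRegion] = field(default_factory=default_effect_regions)
    noise_sd: float = 1.0
    drift_slope_sd: float = 0.005   # a.u. per volume
    global_amp: float = 0.3         # a.u., amplitude of shared whole-brain series
    motion_trans_mm: tuple[float, float] = (0.2, 1.2)   # excursion range, passing
    motion_rot_deg: tuple[float, float] = (0.2, 1.0)
    band: tuple[float, float] = (0.01, 0.08)
    share_network_signal: bool = True
    template_radius_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 20:
            raise ValueError("need n_volumes >= 20")
        f_lo, f_hi = self.band
        if not 0 < f_lo < f_hi < self.nyquist + 1e-12:
            raise ValueError(
                f"band {self.band} invalid for tr={self.tr} (Nyquist {self.nyquist} Hz)")

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world affine: FOV_MM spread over the grid, centred."""
        shape = np.asarray(self.shape, dtype=float)
        spacing = FOV_MM / shape
        offset = FOV_CENTER_MM - spacing * (shape - 1) / 2.0
        aff = np.eye(4)
        aff[:3, :3] = np.diag(spacing)
        aff[:3, 3] = offset
        return aff

    def brain_mask(self) -> BrainMask:
        """Ellipsoidal brain mask in world coordinates."""
        w = _voxel_world_grid(self.shape, self.affine)
        d = (w - BRAIN_CENTER_MM) / BRAIN_SEMIAXES_MM
        return BrainMask(data=(d ** 2).sum(-1) <= 1.0, affine=self.affine)

    # -- profiles ----------------------------------------------------------
    @classmethod
    def paper_scale(cls, **kw) -> "SynthDesign":
        return cls(**kw)

    @classmethod
    def scaled(cls, **kw) -> "SynthDesign":
        """Reduced-size profile: 32x32x16 grid, 120 volumes, 15 per group."""
        kw.setdefault("shape", (32, 32, 16))
        kw.setdefault("n_volumes", 120)
        kw.setdefault("n_per_group", 15)
        return cls(**kw)

    @classmethod
    def smoke(cls, **kw) -> "SynthDesign":
        """Minimal profile for quick end-to-end runs: 16x16x8 grid, 40 volumes."""
        kw.setdefault("shape", (16, 16, 8))
        kw.setdefault("n_volumes", 40)
        kw.setdefault("n_per_group", 3)
        kw.setdefault("effect_regions", default_effect_regions(rho_hc=0.8, rho_bd=0.8))
        return cls(**kw)

    def null(self) -> "SynthDesign":
        """Copy with no planted group difference (rho_bd set to rho_hc)."""
        regions = [replace(r, rho_bd=r.rho_hc) for r in self.effect_regions]
        return replace(self, effect_regions=regions)


def _voxel_world_grid(shape, affine) -> np.ndarray:
    """(x, y, z, 3) array of world mm coordinates of every voxel centre."""
    idx = np.indices(shape, dtype=float)
    ijk = np.stack([idx[0], idx[1], idx[2], np.ones(shape)], axis=-1)
    return np.einsum("rc,...c->...r", np.asarray(affine), ijk)[..., :3]


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def band_limited_signal(n: int, tr: float, band: tuple[float, float],
                        rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Zero-mean, unit-variance series with all spectral power inside ``band``.

    Constructed in the frequency domain: complex-normal coefficients at the
    DFT bins whose frequency lies in [f_lo, f_hi], zeros elsewhere (including
    DC), inverse-transformed and standardized. By construction the power
    fraction outside the band is 0.

    Returns shape (n,) or (size, n).
    """
    f_lo, f_hi = band
    nyq = 1.0 / (2.0 * tr)
    if not (0 <= f_lo < f_hi <= nyq + 1e-12):
        raise ValueError(f"band ({f_lo}, {f_hi}) outside (0, Nyquist={nyq}) for tr={tr}")
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    nkeep = int(keep.sum())
    if nkeep == 0:
        raise ValueError(f"band ({f_lo}, {f_hi}) contains no DFT bin at n={n}, tr={tr}")
    m = 1 if size is None else size
    coef = np.zeros((m, freqs.size), dtype=complex)
    coef[:, keep] = rng.standard_normal((m, nkeep)) + 1j * rng.standard_normal((m, nkeep))
    x = np.fft.irfft(coef, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x[0] if size is None else x


def region_voxel_mask(shape, affine, center_mm, radius_mm) -> np.ndarray:
    """Boolean mask of voxels within ``radius_mm`` of a world-space centre.

    radius 0 selects exactly the voxel nearest the centre.
    """
    w = _voxel_world_grid(shape, affine)
    d2 = ((w - np.asarray(center_mm, dtype=float)) ** 2).sum(-1)
    if radius_mm <= 0:
        out = np.zeros(shape, dtype=bool)
        out[np.unravel_index(np.argmin(d2), shape)] = True
        return out
    return d2 <= radius_mm ** 2


def make_dmn_template(shape, affine, loci_mm=None, radius_mm: float = 15.0,
                      brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Binary DMN template: union of spheres at the canonical loci.

    Intersected with the brain mask when one is given. Raises if the result
    is empty.
    """
    if loci_mm is None:
        loci_mm = list(DMN_LOCI_MM.values())
    out = np.zeros(shape, dtype=bool)
    for c in loci_mm:
        out |= region_voxel_mask(shape, affine, c, radius_mm)
    if brain_mask is not None:
        out &= np.asarray(brain_mask, dtype=bool)
    if not out.any():
        raise ValueError("DMN template is empty on this grid")
    return out


# ---------------------------------------------------------------------------
# Subject-level generation
# ---------------------------------------------------------------------------

def generate_motion(n: int, design: SynthDesign, rng: np.random.Generator,
                    qc_fail: bool = False) -> MotionTrace:
    """Bounded random-walk motion trace.

    Each axis is a cumulative random walk rescaled to a target excursion
    drawn inside the passing range (below the 2 mm / 2 deg QC thresholds);
    a QC-failure subject gets a 3 mm x-translation excursion.
    """
    def walk(targets):
        steps = rng.standard_normal((n, 3))
        w = np.cumsum(steps, axis=0)
        w -= w[0]
        ptp = w.max(axis=0) - w.min(axis=0)
        ptp[ptp < 1e-12] = 1.0
        return w * (targets / ptp)

    t_lo, t_hi = design.motion_trans_mm
    r_lo, r_hi = design.motion_rot_deg
    trans_targets = rng.uniform(t_lo, t_hi, 3)
    rot_targets = rng.uniform(r_lo, r_hi, 3)
    if qc_fail:
        trans_targets[0] = 3.0
    return MotionTrace(walk(trans_targets), walk(rot_targets))


def generate_subject(design: SynthDesign, group: str,
                     seed: int | np.random.SeedSequence,
                     qc_fail: bool = False) -> tuple[Bold4D, MotionTrace]:
    """Simulate one subject's 4D BOLD volume and motion trace.

    See the module docstring for the signal model. The in-region independent
    noise term is band-limited to the analysis band so that the planted
    shared-variance fraction rho survives band-pass filtering unchanged.
    """
    if group not in ("BD", "HC"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    shape, T = design.shape, design.n_volumes
    affine = design.affine
    brain = design.brain_mask().data

    # Spatially smooth broadband background, unit variance after smoothing.
    data = rng.standard_normal(shape + (T,))
    data = gaussian_filter(data, sigma=(1.0, 1.0, 1.0, 0.0), mode="nearest")
    data /= data.std()
    data *= design.noise_sd

    # Shared whole-brain ("global") slow component.
    g = gaussian_filter1d(rng.standard_normal(T), sigma=3.0)
    g = (g - g.mean()) / g.std()
    data[brain] += design.global_amp * design.noise_sd * g

    # Effect regions: shared + independent band-limited signal.
    shared_net = None
    if design.share_network_signal:
        shared_net = band_limited_signal(T, design.tr, design.band, rng)
    for region in design.effect_regions:
        rmask = region_voxel_mask(shape, affine, region.center_mm, region.radius_mm)
        rmask &= brain
        if not rmask.any():
            raise ValueError(
                f"effect region at {region.center_mm} lies outside grid/brain")
        v = int(rmask.sum())
        rho = region.rho(group)
        shared = shared_net if shared_net is not None else band_limited_signal(
            T, design.tr, design.band, rng)
        indep = band_limited_signal(T, design.tr, design.band, rng, size=v)
        series = np.sqrt(1.0 - rho) * indep + np.sqrt(rho) * shared
        data[rmask] = design.noise_sd * series
        data[rmask] += design.global_amp * design.noise_sd * g

    # Linear drift, slope drawn per voxel.
    tt = np.arange(T, dtype=float)
    tt -= tt.mean()
    slopes = rng.normal(0.0, design.drift_slope_sd, shape)
    data += slopes[..., None] * tt

    motion = generate_motion(T, design, rng, qc_fail=qc_fail)
    return Bold4D(data=data, affine=affine, tr=design.tr), motion


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort_table(design: SynthDesign, rng: np.random.Generator) -> CohortTable:
    """Simulated demographics and clinical covariates for both groups."""
    import pandas as pd

    rows = []
    for group in ("BD", "HC"):
        n = design.n_per_group
        dg = _DEMOG[group]
        n_male = int(round(dg["male_frac"] * n))
        sexes = ["M"] * n_male + ["F"] * (n - n_male)
        ages = _truncated_normal(rng, *dg["age"], 18.0, 60.0, n)
        edus = _truncated_normal(rng, *dg["edu"], 6.0, 22.0, n)
        if group == "BD":
            hamd = _truncated_normal(rng, *_CLINICAL["hamd"], n)
            illness = np.maximum(rng.normal(*_CLINICAL["illness"], n), 0.5)
            episodes = np.maximum(np.round(rng.normal(*_CLINICAL["episodes"], n)), 1)
        else:
            hamd = illness = episodes = [np.nan] * n
        for i in range(n):
            rows.append({
                "subject_id": f"{group.lower()}{i + 1:03d}",
                "group": group, "sex": sexes[i],
                "age": round(float(ages[i]), 1),
                "education": round(float(edus[i]), 1),
                "hamd": round(float(hamd[i]), 1) if group == "BD" else np.nan,
                "illness_length": round(float(illness[i]), 1) if group == "BD" else np.nan,
                "n_episodes": float(episodes[i]) if group == "BD" else np.nan,
            })
    return CohortTable(table=pd.DataFrame(rows))


def cohort_seed_sequences(design: SynthDesign) -> tuple[np.random.SeedSequence, list]:
    """Deterministic seed split: one child for the table, one per subject."""
    root = np.random.SeedSequence(design.seed)
    children = root.spawn(1 + 2 * design.n_per_group)
    return children[0], children[1:]


def iter_cohort(design: SynthDesign):
    """Yield (row, Bold4D, MotionTrace) for every subject, in table order.

    In-memory counterpart of :func:`generate_cohort`; same seeds, same data.
    """
    table_ss, subject_ss = cohort_seed_sequences(design)
    cohort = generate_cohort_table(design, np.random.default_rng(table_ss))
    for i, row in cohort.table.iterrows():
        bold, motion = generate_subject(design, row["group"], subject_ss[i])
        yield row, bold, motion


def generate_cohort(design: SynthDesign, out_dir: str | Path,
                    force: bool = False) -> dict:
    """Write a full synthetic cohort to ``out_dir``.

    Produces one BOLD NIfTI and one motion file per subject, the brain mask,
    and ``cohort.tsv``. Deterministic given ``design.seed``. Refuses to write
    into a non-empty directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    table_ss, subject_ss = cohort_seed_sequences(design)
    cohort = generate_cohort_table(design, np.random.default_rng(table_ss))
    mask = design.brain_mask()
    write_mask(mask, out_dir / "brain_mask.nii.gz")
    paths = {"bold": {}, "motion": {}}
    for i, row in cohort.table.iterrows():
        sid = row["subject_id"]
        bold, motion = generate_subject(design, row["group"], subject_ss[i])
        paths["bold"][sid] = str(write_bold(bold, out_dir / f"{sid}_bold.nii.gz"))
        paths["motion"][sid] = str(write_motion(motion, out_dir / f"{sid}_motion.txt"))
        logger.info("synth: wrote subject %s (%s)", sid, row["group"])
    write_cohort(cohort, out_dir / "cohort.tsv")
    return {"out_dir": str(out_dir), "n_subjects": len(cohort),
            "mask": str(out_dir / "brain_mask.nii.gz"),
            "cohort": str(out_dir / "cohort.tsv"), **paths}
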