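"""Second-level group statistics within the DMN mask.

Voxelwise two-sample comparison of normalized ReHo maps via a per-voxel
linear model (intercept + group + age + sex), cluster-extent thresholding
(uncorrected voxel p plus a strict ">" extent rule), ROI mean extraction,
clinical correlations in the patient group, and the demographic tests
(Pearson chi-square without continuity correction for sex; pooled-variance
two-sample t from summary statistics for age/education).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import CohortTable, voxel_volume_mm3, world_coords

logger = logging.getLogger("rehoscope")

CLINICAL_VARIABLES = ("sex", "age", "education", "hamd", "n_episodes",
                      "illness_length")


@dataclass
class GlmResult:
    """Voxelwise group-contrast t statistics inside the analysis mask."""

    t_map: np.ndarray          # 3D; 0 outside mask
    df: int
    contrast: str              # "BD>HC" for positive t
    covariates: tuple[str, ...]
    mask: np.ndarray           # 3D bool analysis mask
    affine: np.ndarray


def _design_matrix(cohort: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(cohort)), (cohort["group"] == "BD").astype(float).to_numpy()]
    names = ["intercept", "group_BD"]
    for cov in covariates:
        if cov == "age":
            age = cohort["age"].to_numpy(dtype=float)
            if np.isnan(age).any():
                raise ValueError("missing age covariate values")
            cols.append(age - age.mean())
            names.append("age_centered")
        elif cov == "sex":
            sex = cohort["sex"].map({"M": 0.0, "F": 1.0}).to_numpy(dtype=float)
            if np.isnan(sex).any():
                raise ValueError("missing sex covariate values")
            cols.append(sex)
            names.append("sex_F")
        else:
            vals = cohort[cov].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing values in covariate {cov!r}")
            cols.append(vals - vals.mean())
            names.append(cov)
    return np.column_stack(cols), names


def glm_two_sample(maps: list[np.ndarray] | np.ndarray, cohort: CohortTable,
                   mask: np.ndarray, affine: np.ndarray,
                   covariates: tuple[str, ...] = ("age", "sex")) -> GlmResult:
    """Per-voxel least squares of map value ~ intercept + group [+ covariates].

    ``maps`` are the per-subject normalized ReHo maps (list of 3D arrays or
    an (N, v) matrix already restricted to the mask), ordered as the cohort
    table. Positive t means BD > HC. With no covariates this reduces exactly
    to the pooled two-sample t-test.
    """
    df_cohort = cohort.table
    mask = np.asarray(mask, dtype=bool)
    if isinstance(maps, np.ndarray) and maps.ndim == 2:
        Y = maps
    else:
        Y = np.stack([m[mask] for m in maps])
    if Y.shape[0] != len(df_cohort):
        raise ValueError(f"{Y.shape[0]} maps for {len(df_cohort)} cohort rows")
    X, names = _design_matrix(df_cohort, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix (columns {names})")
    n = X.shape[0]
    df = n - rank
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                      # p x v
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    c = np.zeros(X.shape[1])
    c[names.index("group_BD")] = 1.0
    var_c = float(c @ XtX_inv @ c)
    denom = np.sqrt(sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (c @ beta) / denom, 0.0)
    t_map = np.zeros(mask.shape)
    t_map[mask] = t
    logger.info("glm_two_sample: n=%d df=%d covariates=%s", n, df, list(covariates))
    return GlmResult(t_map=t_map, df=df, contrast="BD>HC",
                     covariates=tuple(covariates), mask=mask, affine=affine)


CLUSTER_COLUMNS = ("contrast", "label", "size_voxels", "size_mm3",
                   "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm",
                   "peak_z_mm", "peak_t")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


def cluster_threshold(glm: GlmResult, voxel_p: float = 0.01,
                      extent_voxels: int = 12,
                      connectivity: int = 26) -> pd.DataFrame:
    """Cluster-extent thresholding of the group t-map.

    Voxels with two-sided p < ``voxel_p`` are kept, connected components are
    formed under the given connectivity, and clusters with size strictly
    greater than ``extent_voxels`` are reported — separately for each
    contrast direction. An empty table is a valid result.
    """
    t_crit = stats.t.isf(voxel_p / 2.0, glm.df)
    structure = _connectivity_structure(connectivity)
    vol = voxel_volume_mm3(glm.affine)
    rows = []
    for contrast, sign in (("BD>HC", 1.0), ("HC>BD", -1.0)):
        supra = (sign * glm.t_map > t_crit) & glm.mask
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            idx = np.argwhere(labels == lab)
            size = idx.shape[0]
            if size <= extent_voxels:
                continue
            tvals = sign * glm.t_map[tuple(idx.T)]
            peak = idx[np.argmax(tvals)]
            wx, wy, wz = world_coords(glm.affine, peak[None, :])[0]
            rows.append({
                "contrast": contrast, "label": lab, "size_voxels": int(size),
                "size_mm3": float(size * vol),
                "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
                "peak_x_mm": float(wx), "peak_y_mm": float(wy), "peak_z_mm": float(wz),
                "peak_t": float(glm.t_map[tuple(peak)]),
            })
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    logger.info("cluster_threshold: t_crit=%.3f (p<%g, df=%d), %d clusters > %d voxels",
                t_crit, voxel_p, glm.df, len(table), extent_voxels)
    return table


def cluster_mask(glm: GlmResult, table: pd.DataFrame, contrast: str = "BD>HC",
                 voxel_p: float = 0.01, connectivity: int = 26) -> np.ndarray:
    """Binary union of the reported clusters for one contrast direction."""
    t_crit = stats.t.isf(voxel_p / 2.0, glm.df)
    sign = 1.0 if contrast == "BD>HC" else -1.0
    supra = (sign * glm.t_map > t_crit) & glm.mask
    labels, _ = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    keep = table.loc[table["contrast"] == contrast, "label"].to_numpy()
    return np.isin(labels, keep)


def extract_roi_means(maps: list[np.ndarray], cluster: np.ndarray) -> np.ndarray:
    """Per-subject mean map value over a cluster mask."""
    cluster = np.asarray(cluster, dtype=bool)
    if not cluster.any():
        raise ValueError("empty cluster mask")
    return np.array([float(m[cluster].mean()) for m in maps])


def clinical_correlations(roi_means: np.ndarray, patients: pd.DataFrame,
                          variables: tuple[str, ...] = CLINICAL_VARIABLES,
                          region: str = "") -> pd.DataFrame:
    """Pearson correlations of ROI means with clinical variables (BD group).

    Sex is coded M=0, F=1 (point-biserial). p in (0.05, 0.10) is flagged as
    marginally significant. No multiple-testing correction is applied across
    the region x variable grid (flagged in the output).
    """
    roi_means = np.asarray(roi_means, dtype=float)
    if len(roi_means) != len(patients):
        raise ValueError("roi_means and patient table length mismatch")
    rows = []
    for var in variables:
        if var == "sex":
            x = patients["sex"].map({"M": 0.0, "F": 1.0}).to_numpy(dtype=float)
        else:
            x = patients[var].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(roi_means)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete observations for {var!r}")
        if np.std(x[ok]) < 1e-12:
            raise ValueError(f"zero-variance clinical variable {var!r}")
        r, p = stats.pearsonr(roi_means[ok], x[ok])
        rows.append({"region": region, "variable": var, "r": float(r),
                     "p": float(p), "n": int(ok.sum()),
                     "marginal": bool(0.05 < p < 0.10),
                     "multiple_testing_correction": "none"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demographic tests (computable from printed summary data)
# ---------------------------------------------------------------------------

def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def two_sample_t_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int
                         ) -> tuple[float, int, float]:
    """Pooled-variance two-sample |t| from summary statistics.

    Returns (|t|, df = n1 + n2 - 2, two-sided p).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = abs(mean1 - mean2) / se
    p = 2.0 * stats.t.sf(t, df)
    return float(t), int(df), float(p)


def demographics_table(cohort: CohortTable) -> pd.DataFrame:
    """Group comparison of the cohort's demographics.

    Chi-square (uncorrected) for the sex ratio; pooled two-sample t for age
    and education, computed from the sample summaries.
    """
    bd, hc = cohort.patients(), cohort.controls()
    rows = []
    a = int((bd["sex"] == "M").sum())
    b = int((bd["sex"] == "F").sum())
    c = int((hc["sex"] == "M").sum())
    d = int((hc["sex"] == "F").sum())
    chi2, p = chi_square_2x2(a, b, c, d)
    rows.append({"variable": "sex", "bd_summary": f"{a}:{b}",
                 "hc_summary": f"{c}:{d}", "statistic": chi2,
                 "test": "chi2", "df": 1, "p": p})
    for var in ("age", "education"):
        x1, x2 = bd[var].to_numpy(float), hc[var].to_numpy(float)
        t, df, p = two_sample_t_summary(x1.mean(), x1.std(ddof=1), len(x1),
                                        x2.mean(), x2.std(ddof=1), len(x2))
        rows.append({"variable": var,
                     "bd_summary": f"{x1.mean():.2f}±{x1.std(ddof=1):.2f}",
                     "hc_summary": f"{x2.mean():.2f}±{x2.std(ddof=1):.2f}",
                     "statistic": t, "test": "t", "df": df, "p": p})
    return pd.DataFrame(rows)
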