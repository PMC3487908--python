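"""Regional homogeneity: voxelwise Kendall's coefficient of concordance.

For each in-mask voxel, Kendall's W is computed over the time series of the
voxel and its nearest neighbours (cluster size K in {7, 19, 27}: the centre
plus face / face+edge / face+edge+corner neighbours). With rank sums
R_i = sum over the K series of the within-series rank at time point i, and
Rbar = K (n + 1) / 2,

    W = 12 * sum_i (R_i - Rbar)^2 / (K^2 (n^3 - n) - K * sum_j T_j),

where T_j = sum over tie groups of (t^3 - t) for series j is the standard
tie correction (0 for tie-free data; midranks are used for ties). W lies in
[0, 1]: 1 means the K series are perfectly concordant.

Mask-edge policy: a voxel's neighbourhood is restricted to its in-mask
members (effective K' >= 2); voxels with fewer than 2 in-mask members get 0.
Per-map counts of reduced-neighbourhood voxels are logged.

Maps are brain-mean normalized (mReHo: divide by the in-mask mean) and then
smoothed with a Gaussian kernel of given FWHM — computation, normalization,
smoothing, in that order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

from .core_io import Bold4D, BrainMask, assert_same_grid, voxel_sizes

logger = logging.getLogger("rehoscope")

#: FWHM of a Gaussian = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def neighborhood_offsets(K: int) -> np.ndarray:
    """Integer voxel offsets of the K-neighbourhood (includes (0,0,0)).

    K=7: centre + 6 face neighbours; K=19: + 12 edge neighbours;
    K=27: + 8 corner neighbours.
    """
    if K not in (7, 19, 27):
        raise ValueError(f"K must be one of 7, 19, 27; got {K}")
    max_norm = {7: 1, 19: 2, 27: 3}[K]
    offsets = [off for off in itertools.product((-1, 0, 1), repeat=3)
               if sum(o * o for o in off) <= max_norm]
    return np.array(sorted(offsets))


def rank_series(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n of a time series; ties get midranks."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("rank_series expects a 1D series with n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in series")
    return rankdata(x, method="average")


def _tie_term(ranks_sorted: np.ndarray) -> float:
    """sum (t^3 - t) over tie groups, from a sorted 1D rank/value array."""
    _, counts = np.unique(ranks_sorted, return_counts=True)
    c = counts[counts > 1].astype(float)
    return float((c ** 3 - c).sum())


def kendall_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series of length n.

    ``series_set`` is a (K, n) array. Ties are handled with midranks and the
    standard tie correction. If the corrected denominator is <= 0 (all series
    constant), returns 0. The result is clipped to [0, 1] against round-off.
    """
    arr = np.asarray(series_set, dtype=float)
    if arr.ndim != 2:
        raise ValueError("series_set must be a (K, n) array")
    K, n = arr.shape
    if K < 2 or n < 2:
        raise ValueError(f"need K >= 2 and n >= 2, got K={K}, n={n}")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in series_set")
    ranks = rankdata(arr, method="average", axis=1)
    R = ranks.sum(axis=0)
    Rbar = K * (n + 1) / 2.0
    S = float(((R - Rbar) ** 2).sum())
    T = sum(_tie_term(np.sort(arr[j])) for j in range(K))
    denom = (K * K * (n ** 3 - n) - K * T) / 12.0
    if denom <= 0:
        logger.warning("kendall_w: degenerate denominator (all-tied series); returning 0")
        return 0.0
    return float(np.clip(S / denom, 0.0, 1.0))


@dataclass
class ReHoMap:
    """3D map of Kendall's W values.

    Attributes: ``w`` (0 outside the mask), the mask, the neighbourhood size
    K, the number of time points n, and whether the map has been divided by
    its in-mask mean.
    """

    w: np.ndarray
    mask: BrainMask
    K: int
    n: int
    normalized: bool = False

    @property
    def affine(self) -> np.ndarray:
        return self.mask.affine

    def in_mask_values(self) -> np.ndarray:
        return self.w[self.mask.data]


def _shift_add(acc: np.ndarray, src: np.ndarray, off) -> None:
    """acc[x] += src[x + off] with zero fill outside the array bounds."""
    dst_sl, src_sl = [], []
    for o, size in zip(off, acc.shape[:3]):
        if o >= 0:
            dst_sl.append(slice(0, size - o))
            src_sl.append(slice(o, size))
        else:
            dst_sl.append(slice(-o, size))
            src_sl.append(slice(0, size + o))
    acc[tuple(dst_sl)] += src[tuple(src_sl)]


def reho_map(bold: Bold4D, mask: BrainMask, K: int = 27) -> ReHoMap:
    """Voxelwise Kendall's W over the K-neighbourhood of every in-mask voxel.

    Fully vectorized: per-voxel temporal ranks are computed once, then rank
    sums, effective neighbourhood sizes, and tie terms are accumulated by
    shifted addition over the K offsets. Out-of-mask voxels (and in-mask
    voxels with fewer than 2 in-mask neighbourhood members) get 0.
    """
    assert_same_grid(bold.shape3d, bold.affine, mask.data.shape, mask.affine, "mask")
    offsets = neighborhood_offsets(K)
    n = bold.n_volumes
    m = mask.data
    shape = bold.shape3d

    # Ranks are needed only for in-mask voxels; out-of-mask entries stay 0.
    in_mask_series = bold.data[m]                       # v x n
    ranks = np.zeros(shape + (n,))
    ranks[m] = rankdata(in_mask_series, method="average", axis=-1)

    # Tie terms per voxel (continuous BOLD data is effectively tie-free, so
    # take a fast path when no series has a tie anywhere).
    srt = np.sort(in_mask_series, axis=-1)
    tied_rows = (np.diff(srt, axis=-1) == 0).any(axis=-1)
    tie = np.zeros(shape)
    has_tie = bool(tied_rows.any())
    if has_tie:
        tie_in_mask = np.zeros(in_mask_series.shape[0])
        for j in np.flatnonzero(tied_rows):
            tie_in_mask[j] = _tie_term(srt[j])
        tie[m] = tie_in_mask
    del srt, in_mask_series

    R = np.zeros(shape + (n,))
    Kp = np.zeros(shape)
    Tsum = np.zeros(shape)
    mf = m.astype(float)
    for off in offsets:
        _shift_add(R, ranks, off)
        _shift_add(Kp, mf, off)
        if has_tie:
            _shift_add(Tsum, tie, off)

    Rbar = Kp[..., None] * (n + 1) / 2.0
    S = ((R - Rbar) ** 2).sum(axis=-1)
    denom = (Kp ** 2 * (n ** 3 - n) - Kp * Tsum) / 12.0

    valid = m & (Kp >= 2) & (denom > 0)
    w = np.zeros(shape)
    w[valid] = np.clip(S[valid] / denom[valid], 0.0, 1.0)

    n_reduced = int((m & (Kp < K)).sum())
    n_degenerate = int((m & ~valid).sum())
    if n_degenerate:
        logger.warning("reho_map: %d in-mask voxels without a valid neighbourhood "
                       "(set to 0)", n_degenerate)
    logger.info("reho_map: K=%d n=%d in-mask=%d reduced-neighbourhood=%d",
                K, n, int(m.sum()), n_reduced)
    return ReHoMap(w=w, mask=mask, K=K, n=n, normalized=False)


def normalize_map(m: ReHoMap) -> ReHoMap:
    """Divide in-mask values by the in-mask mean (mReHo; output mean = 1)."""
    mean = m.in_mask_values().mean()
    if mean <= 0:
        raise ValueError(f"cannot normalize: in-mask mean is {mean}")
    w = np.zeros_like(m.w)
    w[m.mask.data] = m.w[m.mask.data] / mean
    return ReHoMap(w=w, mask=m.mask, K=m.K, n=m.n, normalized=True)


def gaussian_smooth(data: np.ndarray, fwhm_mm: float,
                    affine: np.ndarray) -> np.ndarray:
    """Separable Gaussian smoothing with per-axis sigma honouring voxel size.

    sigma_axis (voxels) = fwhm_mm * FWHM_TO_SIGMA / voxel_size_axis.
    Zero-padded boundary; fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    data = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    sigmas = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes(affine)
    return gaussian_filter(data, sigma=sigmas, mode="constant", cval=0.0)


def reho_pipeline(bold: Bold4D, mask: BrainMask, K: int = 27,
                  fwhm_mm: float = 4.0) -> tuple[np.ndarray, ReHoMap]:
    """KCC map -> brain-mean normalization -> Gaussian smoothing.

    Returns (smoothed normalized map as a 3D array, the unsmoothed
    normalized ReHoMap).
    """
    raw = reho_map(bold, mask, K=K)
    norm = normalize_map(raw)
    smoothed = gaussian_smooth(norm.w, fwhm_mm, mask.affine)
    smoothed[~mask.data] = 0.0
    return smoothed, norm
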