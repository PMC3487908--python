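"""Temporal-concatenation group ICA and default-mode-network mask construction.

Stages (the classic group-ICA pipeline):

1. *Data reduction*: per-subject temporal PCA (whitened), temporal
   concatenation across subjects, then a group-level PCA to the model order.
2. *Independent component separation*: spatial ICA on the group-reduced data
   — Infomax (natural-gradient, logistic score) by default, with a seeded
   FastICA fallback. Components are spatial maps; mixing columns are the
   associated time courses.
3. *Back reconstruction*: subject-specific component maps and time courses
   are recovered through each subject's PCA operators (GICA-style
   back-projection) and z-scored over in-mask voxels.

The model order is estimated from the eigenspectrum of the concatenated,
voxel-variance-normalized data with the minimum-description-length (MDL)
criterion, bounded to [5, min(t-1, 40)].

The DMN component is selected by spatial correlation with a binary template;
the group DMN mask is the set of voxels whose subject z-maps pass a
voxelwise one-sample t-test at Bonferroni (FWE) alpha, split into anterior
(world y > 0) and posterior parts.

Outputs are canonicalized — components ordered by explained variance, signs
fixed so each map's skewness is >= 0 — so results are deterministic given
(data, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import Bold4D, BrainMask, assert_same_grid, world_coords

logger = logging.getLogger("rehoscope")

ORDER_BOUNDS = (5, 40)


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GroupReduction:
    """PCA-reduced, temporally concatenated multi-subject data.

    ``reduced`` is the whitened (n_components x voxels) group matrix;
    ``subject_reducers`` holds each subject's (d x t) whitening projector and
    ``group_blocks`` the (g x d) block of the group projector acting on that
    subject, so back-reconstruction can undo the reduction per subject.
    """

    reduced: np.ndarray                       # g x v
    subject_reducers: list[np.ndarray]        # each d x t
    subject_data: list[np.ndarray]            # each d x v  (whitened per-subject)
    group_blocks: list[np.ndarray]            # each g x d
    group_unblocks: list[np.ndarray]          # each d x g  (rows of pinv(G))
    retained_variance: list[float]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_data)

    @property
    def n_components(self) -> int:
        return self.reduced.shape[0]


@dataclass
class IcaDecomposition:
    """Group spatial components, mixing, and per-subject back-reconstructions."""

    n_components: int
    group_maps: np.ndarray                    # g x v, z-scored over voxels
    mixing: np.ndarray                        # g x g (in reduced space)
    time_courses: list[np.ndarray]            # each t x g
    subject_maps: list[np.ndarray]            # each g x v, z-scored
    seed: int
    algorithm: str = "infomax"


@dataclass
class DmnMask:
    """Binary DMN mask with its source component and anterior/posterior split."""

    data: np.ndarray                          # 3D bool
    affine: np.ndarray
    component_index: int
    anterior: np.ndarray = field(repr=False, default=None)
    posterior: np.ndarray = field(repr=False, default=None)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# Order estimation
# ---------------------------------------------------------------------------

def mdl_criterion(eigenvalues: np.ndarray, n_samples: int, k: int) -> float:
    """Wax-Kailath MDL score for ``k`` sources given a descending eigenspectrum."""
    lam = np.asarray(eigenvalues, dtype=float)
    p = lam.size
    rest = lam[k:]
    log_geo = np.mean(np.log(rest))
    log_arith = np.log(np.mean(rest))
    loglik = n_samples * (p - k) * (log_arith - log_geo)
    penalty = 0.5 * k * (2 * p - k + 1) * np.log(n_samples)
    return loglik + penalty


def estimate_order_mdl(data: list[np.ndarray] | np.ndarray,
                       bounds: tuple[int, int] = ORDER_BOUNDS) -> int:
    """MDL model-order estimate from temporally concatenated data.

    ``data`` is a list of per-subject (t x v) matrices (or one already
    concatenated matrix). Voxel series are variance-normalized before the
    eigenspectrum of the temporal covariance is taken. The MDL argmin is
    clamped to [bounds[0], min(t - 1, bounds[1])] where t is the per-subject
    time dimension.
    """
    if isinstance(data, np.ndarray):
        mats, t_subject = [data], data.shape[0]
    else:
        if len(data) < 2:
            raise ValueError("need >= 2 subjects for group order estimation")
        mats, t_subject = list(data), data[0].shape[0]
    X = np.vstack(mats).astype(float)                     # T_total x v
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    X = X / sd
    v = X.shape[1]
    sv = np.linalg.svd(X, compute_uv=False)
    lam = (sv ** 2) / v
    lam = lam[lam > max(1e-12 * lam[0], 1e-300)]
    lo, hi = bounds[0], min(t_subject - 1, bounds[1])
    if lam.size <= lo:
        raise ValueError(
            f"degenerate eigenspectrum: {lam.size} positive eigenvalues <= "
            f"lower bound {lo}")
    kmax = min(hi, lam.size - 1)
    scores = [mdl_criterion(lam, v, k) for k in range(0, kmax + 1)]
    k_hat = int(np.argmin(scores))
    k_clamped = int(np.clip(k_hat, lo, hi))
    logger.info("MDL order estimate: argmin=%d, clamped to %d (bounds [%d, %d])",
                k_hat, k_clamped, lo, hi)
    return k_clamped


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------

def _numerical_rank(Y: np.ndarray, rtol: float = 1e-10) -> int:
    """Rank of the time-centred data matrix (count of significant SVs)."""
    Yc = Y - Y.mean(axis=0)
    s = np.linalg.svd(Yc, compute_uv=False)
    return int((s > rtol * s[0]).sum())


def stack_to_matrix(bold: Bold4D, mask: BrainMask) -> np.ndarray:
    """Extract the (t x v) in-mask data matrix of one subject."""
    assert_same_grid(bold.shape3d, bold.affine, mask.data.shape, mask.affine, "mask")
    return bold.data[mask.data].T.copy()


def reduce_and_concatenate(subject_matrices: list[np.ndarray],
                           subject_dim: int, group_dim: int) -> GroupReduction:
    """Per-subject PCA whitening, temporal concatenation, group PCA whitening."""
    if not subject_matrices:
        raise ValueError("no subjects given")
    reducers, reduced_list, retained = [], [], []
    for i, Y in enumerate(subject_matrices):
        Y = np.asarray(Y, dtype=float)
        t, v = Y.shape
        if subject_dim > min(t, v) - 1:
            raise ValueError(
                f"subject_dim {subject_dim} exceeds available rank for subject {i} "
                f"(t={t}, v={v})")
        Yc = Y - Y.mean(axis=0)
        U, s, _ = np.linalg.svd(Yc, full_matrices=False)
        if s[subject_dim - 1] < 1e-12 * s[0]:
            raise ValueError(f"subject {i}: rank below requested subject_dim")
        R = U[:, :subject_dim].T                       # d x t projector
        Xi = R @ Yc                                    # d x v principal series
        rownorm = Xi.std(axis=1, keepdims=True)
        Xi = Xi / rownorm
        R = R / rownorm                                # keep Xi == R @ Yc
        reducers.append(R)
        reduced_list.append(Xi)
        retained.append(float((s[:subject_dim] ** 2).sum() / (s ** 2).sum()))
        logger.info("reduction: subject %d retains %.1f%% variance at d=%d",
                    i, 100 * retained[-1], subject_dim)
    Xc = np.vstack(reduced_list)                       # (N d) x v
    if group_dim > min(Xc.shape) - 1:
        raise ValueError(f"group_dim {group_dim} exceeds concatenated rank")
    Ug, sg, _ = np.linalg.svd(Xc, full_matrices=False)
    if sg[group_dim - 1] < 1e-12 * sg[0]:
        raise ValueError("group_dim exceeds available group rank")
    G = Ug[:, :group_dim].T                            # g x (N d)
    Z = G @ Xc
    zn = Z.std(axis=1, keepdims=True)
    Z = Z / zn
    G = G / zn
    Gp = np.linalg.pinv(G)                             # (N d) x g
    d = subject_dim
    blocks = [G[:, i * d:(i + 1) * d] for i in range(len(subject_matrices))]
    unblocks = [Gp[i * d:(i + 1) * d, :] for i in range(len(subject_matrices))]
    return GroupReduction(reduced=Z, subject_reducers=reducers,
                          subject_data=reduced_list, group_blocks=blocks,
                          group_unblocks=unblocks, retained_variance=retained)


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def infomax(Z: np.ndarray, seed: int = 0, lr: float = 0.1,
            max_iter: int = 20000, tol: float = 1e-6,
            anneal_deg: float = 60.0, anneal: float = 0.98) -> np.ndarray:
    """Batch natural-gradient Infomax unmixing of whitened data.

    Maximizes the entropy of logistic-transformed outputs — the classic
    super-Gaussian Infomax rule:  dW ~ (I + (1 - 2 g(U)) U^T / v) W  with
    g the logistic function and U = W Z. The learning rate is halved on
    divergence and annealed when successive updates turn by more than
    ``anneal_deg`` degrees (oscillation). Converges when the relative
    natural-gradient norm falls below ``tol`` (or the weight change becomes
    negligible); raises ConvergenceError with iteration diagnostics
    otherwise.
    """
    g, v = Z.shape
    rng = np.random.default_rng(seed)
    W = np.eye(g) + 0.005 * rng.standard_normal((g, g))
    cos_anneal = np.cos(np.radians(anneal_deg))
    prev_step = None
    gnorm = np.inf
    for it in range(max_iter):
        U = W @ Z
        Y = 1.0 / (1.0 + np.exp(-np.clip(U, -30, 30)))
        grad = (np.eye(g) + (1.0 - 2.0 * Y) @ U.T / v) @ W
        gnorm = np.linalg.norm(grad) / np.linalg.norm(W)
        if gnorm < tol:
            logger.info("infomax converged in %d iterations (|grad|=%.2e)", it, gnorm)
            return W
        step = lr * grad
        delta = np.linalg.norm(step) / np.linalg.norm(W)
        if not np.isfinite(delta) or delta > 1.0:
            lr *= 0.5
            prev_step = None
            if lr < 1e-10:
                raise ConvergenceError(
                    f"infomax diverged at iteration {it} (lr underflow)")
            continue
        W = W + step
        if delta < 1e-9:
            logger.info("infomax converged in %d iterations "
                        "(weight change %.2e, |grad|=%.2e)", it + 1, delta, gnorm)
            return W
        if prev_step is not None:
            cos_ang = float((step * prev_step).sum()
                            / (np.linalg.norm(step) * np.linalg.norm(prev_step)))
            if cos_ang < cos_anneal:
                lr *= anneal
        prev_step = step
    raise ConvergenceError(
        f"infomax did not converge in {max_iter} iterations "
        f"(relative gradient norm {gnorm:.2e}, lr {lr:.2e})")


def _canonicalize(S: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order components by explained variance; fix signs so skewness >= 0."""
    contrib = (A ** 2).sum(axis=0) * S.var(axis=1)
    order = np.argsort(contrib)[::-1]
    S, A = S[order], A[:, order]
    sk = stats.skew(S, axis=1)
    flip = np.where(sk < 0, -1.0, 1.0)
    return S * flip[:, None], A * flip[None, :]


def ica_unmix(reduction: GroupReduction, seed: int = 0,
              algorithm: str = "infomax") -> tuple[np.ndarray, np.ndarray]:
    """Unmix the group-reduced data into spatial components.

    Returns (group_maps g x v, mixing g x g). Deterministic for a fixed seed;
    components are ordered by explained variance with skewness >= 0.
    """
    Z = reduction.reduced
    if algorithm == "infomax":
        W = infomax(Z, seed=seed)
    elif algorithm == "fastica":
        from sklearn.decomposition import FastICA
        ica = FastICA(whiten=False, random_state=seed, max_iter=2000, tol=1e-6)
        ica.fit(Z.T)
        W = ica.components_
    else:
        raise ValueError(f"unknown ICA algorithm {algorithm!r}")
    S = W @ Z
    A = np.linalg.inv(W)
    return _canonicalize(S, A)


def back_reconstruct(reduction: GroupReduction, group_maps: np.ndarray,
                     mixing: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """GICA back-projection: per-subject component maps and time courses.

    Subject maps:  S_i = W G_i X_i  (through the group projector block and
    the subject's whitened data); z-scored per component over in-mask voxels.
    Time courses:  TC_i = R_i^+ G_i^+ A  (t x g).
    """
    W = np.linalg.inv(mixing)
    # group_maps were canonicalized after S = W Z; rebuild the matching W for
    # subject projection: S = A^-1 Z  with canonical A, so use inv(mixing).
    maps, tcs = [], []
    for Xi, Gi, Gui, Ri in zip(reduction.subject_data, reduction.group_blocks,
                               reduction.group_unblocks, reduction.subject_reducers):
        Si = W @ (Gi @ Xi)                              # g x v
        mu = Si.mean(axis=1, keepdims=True)
        sd = Si.std(axis=1, keepdims=True)
        sd[sd < 1e-12] = 1.0
        maps.append((Si - mu) / sd)
        tcs.append(np.linalg.pinv(Ri) @ (Gui @ mixing))  # t x g
    return maps, tcs


# ---------------------------------------------------------------------------
# DMN selection and mask
# ---------------------------------------------------------------------------

def select_dmn_component(group_maps: np.ndarray, template_in_mask: np.ndarray,
                         score_floor: float = 0.2) -> tuple[int, float]:
    """Pick the component whose |z| map best matches the binary template.

    Returns (component index, Pearson correlation). Exact ties break to the
    lower index (logged). Raises if no component reaches ``score_floor``.
    """
    tpl = np.asarray(template_in_mask, dtype=float).ravel()
    if tpl.size != group_maps.shape[1]:
        raise ValueError("template length does not match in-mask voxel count")
    if tpl.sum() == 0:
        raise ValueError("empty DMN template")
    scores = np.array([stats.pearsonr(np.abs(m), tpl)[0] for m in group_maps])
    best = int(np.argmax(scores))
    if (scores == scores[best]).sum() > 1:
        logger.warning("select_dmn_component: tie at score %.3f; taking lower index",
                       scores[best])
    if scores[best] < score_floor:
        raise ValueError(
            f"no DMN component found: best template match {scores[best]:.3f} "
            f"< floor {score_floor}")
    logger.info("DMN component %d selected (template match r=%.3f)",
                best, scores[best])
    return best, float(scores[best])


def dmn_mask_from_group(subject_maps: list[np.ndarray], component: int,
                        mask: BrainMask, alpha: float = 0.05) -> DmnMask:
    """Group DMN mask by voxelwise one-sample t-test with Bonferroni FWE.

    The selected component's subject z-maps are tested voxel-by-voxel against
    0 (df = N - 1); voxels with two-sided p * m < alpha and positive t form
    the mask. Voxels with zero across-subject variance are excluded (logged).
    The mask is split into anterior (world y > 0) and posterior parts.
    """
    if len(subject_maps) < 3:
        raise ValueError("need >= 3 subjects for the one-sample t-test")
    M = np.stack([sm[component] for sm in subject_maps])   # N x v
    N, v = M.shape
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    zero_var = sd < 1e-12
    if zero_var.any():
        logger.warning("dmn_mask: %d zero-variance voxels excluded", int(zero_var.sum()))
    sd[zero_var] = np.inf
    t = mu / (sd / np.sqrt(N))
    p = 2.0 * stats.t.sf(np.abs(t), df=N - 1)
    sig = (p * v < alpha) & (t > 0) & ~zero_var
    if not sig.any():
        raise ValueError(
            "DMN mask is empty at FWE alpha={:g}; use a larger cohort or alpha"
            .format(alpha))
    data = np.zeros(mask.data.shape, dtype=bool)
    data[mask.data] = sig
    vox = np.argwhere(data)
    wy = world_coords(mask.affine, vox)[:, 1]
    anterior = np.zeros_like(data)
    posterior = np.zeros_like(data)
    anterior[tuple(vox[wy > 0].T)] = True
    posterior[tuple(vox[wy <= 0].T)] = True
    logger.info("DMN mask: %d voxels (%d anterior, %d posterior)",
                int(data.sum()), int(anterior.sum()), int(posterior.sum()))
    return DmnMask(data=data, affine=mask.affine, component_index=component,
                   anterior=anterior, posterior=posterior)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def group_ica_dmn(subject_matrices: list[np.ndarray], mask: BrainMask,
                  template: np.ndarray, n_components: int | str = "auto",
                  subject_dim: int | None = None, algorithm: str = "infomax",
                  seed: int = 0, fwe_alpha: float = 0.05,
                  ) -> tuple[DmnMask, IcaDecomposition, dict]:
    """Full group-ICA DMN pipeline on pooled (both-group) data.

    ``template`` is a 3D binary array on the analysis grid. Returns the DMN
    mask, the decomposition, and a report dict (order, match score, retained
    variance).
    """
    t = subject_matrices[0].shape[0]
    # Band-passed data has temporal rank ~ the number of retained frequency
    # bins; cap the reduction dimensions by the weakest subject's rank.
    min_rank = min(_numerical_rank(Y) for Y in subject_matrices)
    if n_components == "auto":
        order = estimate_order_mdl(subject_matrices)
    else:
        order = int(n_components)
    order = min(order, min_rank - 1)
    if order < 2:
        raise ValueError("data rank too low for ICA (need >= 3)")
    if subject_dim is None:
        subject_dim = min(max(order + 5, 2 * order), t - 2, min_rank - 1)
    subject_dim = max(subject_dim, order)
    reduction = reduce_and_concatenate(subject_matrices, subject_dim, order)
    group_maps, mixing = ica_unmix(reduction, seed=seed, algorithm=algorithm)
    subject_maps, time_courses = back_reconstruct(reduction, group_maps, mixing)
    gz = (group_maps - group_maps.mean(axis=1, keepdims=True)) \
        / group_maps.std(axis=1, keepdims=True)
    comp, score = select_dmn_component(gz, template[mask.data])
    dmn = dmn_mask_from_group(subject_maps, comp, mask, alpha=fwe_alpha)
    decomp = IcaDecomposition(n_components=order, group_maps=gz, mixing=mixing,
                              time_courses=time_courses, subject_maps=subject_maps,
                              seed=seed, algorithm=algorithm)
    report = {"n_components": order, "subject_dim": subject_dim,
              "dmn_component": comp, "template_match": score,
              "retained_variance": reduction.retained_variance,
              "mask_voxels": dmn.n_voxels}
    return dmn, decomp, report
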