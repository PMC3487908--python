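"""End-to-end validation experiments on synthetic cohorts.

These routines exercise the full analysis chain (simulate -> preprocess ->
ReHo -> voxelwise GLM -> cluster-extent thresholding, and the group-ICA DMN
recovery) under known planted effects, and compute the quantities the study
design implies: detection rate of a planted synchrony difference, Dice
overlap with the planted mask, null false-positive cluster rates, and
ICA template-recovery scores.

The printed demographic summaries of the study cohort (sex counts, age and
education means/SDs) are inputs here: the demographic statistics are
recomputed from them at run time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import group_ica, group_stats, preprocess, reho, synth
from .core_io import CohortTable

logger = logging.getLogger("rehoscope")

# Printed cohort summaries (inputs to the demographic reproduction):
# sex M:F 9:17 (BD) vs 10:16 (HC); age 32.35+-11.31 vs 31.92+-12.19 years;
# education 12.32+-2.0 vs 13.15+-2.13 years; n = 26 per group.
STUDY_SEX_COUNTS = (9, 17, 10, 16)
STUDY_AGE = (32.35, 11.31, 26, 31.92, 12.19, 26)
STUDY_EDUCATION = (12.32, 2.0, 26, 13.15, 2.13, 26)
STUDY_N_VOLUMES = 240
STUDY_N_DROP = 10


def demographic_statistics() -> dict:
    """Recompute the study's demographic tests from the printed summaries."""
    chi2, p_sex = group_stats.chi_square_2x2(*STUDY_SEX_COUNTS)
    t_age, df_age, p_age = group_stats.two_sample_t_summary(*STUDY_AGE)
    t_edu, df_edu, p_edu = group_stats.two_sample_t_summary(*STUDY_EDUCATION)
    return {"sex_chi2": chi2, "sex_p": p_sex,
            "age_t": t_age, "age_df": df_age, "age_p": p_age,
            "education_t": t_edu, "education_df": df_edu, "education_p": p_edu}


def retained_volume_count(n_volumes: int = STUDY_N_VOLUMES,
                          n_drop: int = STUDY_N_DROP) -> int:
    """Volumes retained after the initial discard, computed on actual data."""
    design = synth.SynthDesign.smoke(n_volumes=n_volumes, seed=7)
    bold, _ = synth.generate_subject(design, "HC", 7)
    return preprocess.drop_initial_volumes(bold, n_drop).n_volumes


# ---------------------------------------------------------------------------
# Planted-effect recovery
# ---------------------------------------------------------------------------

def _subject_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_and_reho(design: synth.SynthDesign, group: str,
                      seed, n_drop: int = 10, fwhm_mm: float = 4.0,
                      K: int = 27) -> np.ndarray:
    """One subject: simulate, preprocess, smoothed normalized ReHo map."""
    bold, motion = synth.generate_subject(design, group, seed)
    mask = design.brain_mask()
    pre, _ = preprocess.preprocess_subject(bold, motion, mask, n_drop=n_drop,
                                           band=design.band)
    smoothed, _ = reho.reho_pipeline(pre, mask, K=K, fwhm_mm=fwhm_mm)
    return smoothed


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 0.0


@dataclass
class ReplicateResult:
    detected: bool
    dice: float
    n_clusters: int


def planted_mask(design: synth.SynthDesign) -> np.ndarray:
    """Union of the design's effect-region spheres, inside the brain."""
    brain = design.brain_mask().data
    out = np.zeros(design.shape, dtype=bool)
    for r in design.effect_regions:
        out |= synth.region_voxel_mask(design.shape, design.affine,
                                       r.center_mm, r.radius_mm)
    return out & brain


def _synthetic_cohort_covariates(design, rng) -> CohortTable:
    return synth.generate_cohort_table(design, rng)


def planted_effect_replicate(design: synth.SynthDesign, seed: int,
                             voxel_p: float = 0.01, extent_voxels: int = 12,
                             connectivity: int = 26) -> ReplicateResult:
    """One full second-level replicate on a fresh synthetic cohort.

    The analysis mask is the DMN template on the design grid (the region the
    second-level comparison is restricted to); the planted mask is the union
    of effect spheres. Detection means at least one supra-threshold BD>HC
    cluster intersects the planted mask; Dice is computed between the union
    of BD>HC clusters and the planted mask.
    """
    d = synth.SynthDesign(**{**design.__dict__, "seed": seed})
    mask = d.brain_mask()
    template = synth.make_dmn_template(d.shape, d.affine,
                                       radius_mm=d.template_radius_mm,
                                       brain_mask=mask.data)
    plant = planted_mask(d)
    rows, maps = [], []
    for row, bold, motion in synth.iter_cohort(d):
        pre, _ = preprocess.preprocess_subject(bold, motion, mask,
                                               band=d.band)
        smoothed, _ = reho.reho_pipeline(pre, mask)
        rows.append(row)
        maps.append(smoothed)
    import pandas as pd
    cohort = CohortTable(table=pd.DataFrame(rows).reset_index(drop=True))
    glm = group_stats.glm_two_sample(maps, cohort, template, d.affine,
                                     covariates=("age", "sex"))
    table = group_stats.cluster_threshold(glm, voxel_p=voxel_p,
                                          extent_voxels=extent_voxels,
                                          connectivity=connectivity)
    bd_rows = table[table["contrast"] == "BD>HC"]
    if len(bd_rows) == 0:
        return ReplicateResult(detected=False, dice=0.0, n_clusters=0)
    cmask = group_stats.cluster_mask(glm, table, "BD>HC", voxel_p, connectivity)
    detected = bool((cmask & plant).any())
    return ReplicateResult(detected=detected, dice=dice(cmask, plant),
                           n_clusters=len(bd_rows))


def recovery_experiment(base_seed: int, n_replicates: int = 20,
                        design: synth.SynthDesign | None = None) -> dict:
    """Planted-effect recovery over seeded replicates of the scaled design."""
    if design is None:
        design = synth.SynthDesign.scaled()
    seeds = [_subject_seed(s)
             for s in np.random.SeedSequence(base_seed).spawn(n_replicates)]
    results = [planted_effect_replicate(design, s) for s in seeds]
    rate = float(np.mean([r.detected and r.dice > 0.3 for r in results]))
    return {"detection_rate": rate,
            "mean_dice": float(np.mean([r.dice for r in results])),
            "n_replicates": n_replicates,
            "dices": [r.dice for r in results]}


def null_cluster_rate(base_seed: int, n_replicates: int = 8,
                      design: synth.SynthDesign | None = None) -> float:
    """Fraction of null replicates with any supra-threshold cluster."""
    if design is None:
        design = synth.SynthDesign.scaled().null()
    seeds = [_subject_seed(s)
             for s in np.random.SeedSequence(base_seed).spawn(n_replicates)]
    hits = 0
    for s in seeds:
        r = planted_effect_replicate(design, s)
        hits += int(r.n_clusters > 0)
    return hits / n_replicates


# ---------------------------------------------------------------------------
# ICA recovery
# ---------------------------------------------------------------------------

def ica_recovery(seed: int, n_per_group: int = 10,
                 design: synth.SynthDesign | None = None,
                 n_components: int = 15,
                 algorithm: str = "infomax") -> dict:
    """Group-ICA recovery of a planted template-shaped network source.

    Simulates a cohort whose DMN-template voxels share one band-limited
    network signal in every subject, runs the group ICA DMN pipeline, and
    reports the template-match score of the selected component and the Dice
    of the FWE-thresholded group mask against the template.
    """
    if design is None:
        design = synth.SynthDesign.scaled(
            n_per_group=n_per_group,
            effect_regions=synth.default_effect_regions(rho_hc=0.6, rho_bd=0.6),
            seed=seed)
    mask = design.brain_mask()
    template = synth.make_dmn_template(design.shape, design.affine,
                                       radius_mm=design.template_radius_mm,
                                       brain_mask=mask.data)
    mats = []
    for _, bold, motion in synth.iter_cohort(design):
        pre, _ = preprocess.preprocess_subject(bold, motion, mask,
                                               band=design.band)
        mats.append(group_ica.stack_to_matrix(pre, mask))
    dmn, _, report = group_ica.group_ica_dmn(
        mats, mask, template, n_components=n_components,
        algorithm=algorithm, seed=seed)
    return {"template_match": report["template_match"],
            "mask_dice": dice(dmn.data, template),
            "n_components": report["n_components"],
            "mask_voxels": dmn.n_voxels,
            "n_subjects": 2 * design.n_per_group}
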