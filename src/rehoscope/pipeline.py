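"""One-command end-to-end run: simulate -> preprocess -> ReHo -> DMN -> group.

A single :class:`RunConfig` holds every analysis parameter (the defaults are
the study settings: drop 10 volumes, band 0.01-0.08 Hz, K=27, FWHM 4 mm,
QC 2 mm / 2 deg, voxel p 0.01, extent 12 voxels, 26-connectivity, ICA FWE
alpha 0.05). One global seed derives per-stage and per-subject seeds through
``numpy.random.SeedSequence`` spawning, so reruns reproduce all numeric
outputs. A machine-readable manifest (stages, parameters, output checksums,
versions, seed) is written alongside the results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, group_ica, group_stats, preprocess, reho, synth
from .core_io import (
    assert_same_grid,
    load_cohort,
    read_bold,
    read_mask,
    read_motion,
    write_map,
)

logger = logging.getLogger("rehoscope")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Every knob of the pipeline in one place (no literals in stage code)."""

    out_dir: str = "rehoscope_run"
    # input cohort: either an existing folder (cohort.tsv + NIfTI + motion
    # files as written by the simulator) or simulate=True with a profile.
    data_dir: str | None = None
    simulate: bool = True
    profile: str = "smoke"            # smoke | scaled | paper
    n_drop: int = 10
    band: tuple[float, float] = (0.01, 0.08)
    K: int = 27
    fwhm_mm: float = 4.0
    qc_trans_mm: float = 2.0
    qc_rot_deg: float = 2.0
    ica_algorithm: str = "infomax"
    ica_order: int | str = "auto"
    fwe_alpha: float = 0.05
    voxel_p: float = 0.01
    extent_voxels: int = 12
    connectivity: int = 26
    seed: int = 0
    design_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K not in (7, 19, 27):
            raise ConfigError(f"K must be 7, 19 or 27 (got {self.K})")
        if not 0 < self.voxel_p < 1 or not 0 < self.fwe_alpha < 1:
            raise ConfigError("voxel_p and fwe_alpha must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if self.band[0] >= self.band[1]:
            raise ConfigError(f"invalid band {self.band}")
        if self.fwhm_mm < 0 or self.n_drop < 0 or self.extent_voxels < 0:
            raise ConfigError("negative parameter in config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def design(self) -> synth.SynthDesign:
        maker = {"smoke": synth.SynthDesign.smoke,
                 "scaled": synth.SynthDesign.scaled,
                 "paper": synth.SynthDesign.paper_scale}.get(self.profile)
        if maker is None:
            raise ConfigError(f"unknown profile {self.profile!r}")
        kw = dict(self.design_overrides)
        kw.setdefault("seed", self.seed)
        kw.setdefault("band", tuple(self.band))
        return maker(**kw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Execute all stages; returns the report folder.

    Any stage error aborts with the stage name (and subject id where
    applicable) in the exception message.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "stages": []}

    # -- stage: data ---------------------------------------------------------
    if config.simulate:
        data_dir = out / "data"
        design = config.design()
        if not (data_dir.exists() and any(data_dir.iterdir()) and not force):
            synth.generate_cohort(design, data_dir, force=force)
        manifest["stages"].append({"stage": "simulate",
                                   "profile": config.profile,
                                   "out": str(data_dir)})
    elif config.data_dir:
        data_dir = Path(config.data_dir)
    else:
        raise ConfigError("either simulate=true or data_dir must be given")

    cohort = load_cohort(data_dir / "cohort.tsv")
    mask = read_mask(data_dir / "brain_mask.nii.gz")

    # -- stage: preprocess + reho -------------------------------------------
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    qc_rows, maps, pre_mats = [], [], []
    for sid in cohort.subject_ids:
        try:
            bold = read_bold(data_dir / f"{sid}_bold.nii.gz")
            motion = read_motion(data_dir / f"{sid}_motion.txt")
            assert_same_grid(mask.data.shape, mask.affine, bold.shape3d,
                             bold.affine, f"subject {sid}")
            pre, qc = preprocess.preprocess_subject(
                bold, motion, mask, subject_id=sid, n_drop=config.n_drop,
                band=config.band, qc_trans_mm=config.qc_trans_mm,
                qc_rot_deg=config.qc_rot_deg)
            smoothed, _ = reho.reho_pipeline(pre, mask, K=config.K,
                                             fwhm_mm=config.fwhm_mm)
        except Exception as exc:
            raise RuntimeError(f"stage preprocess/reho failed for subject "
                               f"{sid}: {exc}") from exc
        qc_rows.append(qc.as_dict())
        maps.append(smoothed)
        pre_mats.append(group_ica.stack_to_matrix(pre, mask))
        write_map(smoothed, mask.affine, maps_dir / f"{sid}_mreho.nii.gz",
                  description=f"mReHo K={config.K} fwhm={config.fwhm_mm}mm")
    pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    manifest["stages"].append({"stage": "preprocess+reho",
                               "n_subjects": len(cohort),
                               "order": "drop,qc,regress,bandpass,kcc,normalize,smooth"})

    # -- stage: group ICA / DMN mask ----------------------------------------
    template = synth.make_dmn_template(mask.data.shape, mask.affine,
                                       brain_mask=mask.data)
    ica_seed = int(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
                   % (2 ** 31))
    try:
        dmn, decomp, ica_report = group_ica.group_ica_dmn(
            pre_mats, mask, template, n_components=config.ica_order,
            algorithm=config.ica_algorithm, seed=ica_seed,
            fwe_alpha=config.fwe_alpha)
    except Exception as exc:
        raise RuntimeError(f"stage group_ica failed: {exc}") from exc
    write_map(dmn.data.astype(np.uint8), mask.affine, out / "dmn_mask.nii.gz")
    with open(out / "ica_report.json", "w") as fh:
        json.dump(ica_report, fh, indent=2, default=_json_default)
    manifest["stages"].append({"stage": "group_ica", **{
        k: v for k, v in ica_report.items() if k != "retained_variance"}})

    # -- stage: group statistics --------------------------------------------
    try:
        glm = group_stats.glm_two_sample(maps, cohort, dmn.data, mask.affine,
                                         covariates=("age", "sex"))
        table = group_stats.cluster_threshold(
            glm, voxel_p=config.voxel_p, extent_voxels=config.extent_voxels,
            connectivity=config.connectivity)
        write_map(glm.t_map, mask.affine, out / "group_t_map.nii.gz",
                  description=f"two-sample t (BD>HC), df={glm.df}")
        table.to_csv(out / "cluster_table.tsv", sep="\t", index=False)

        corr_tables, roi_rows = [], []
        patients = cohort.patients()
        patient_idx = cohort.table.index[cohort.table["group"] == "BD"].to_numpy()
        for _, row in table.iterrows():
            cmask = group_stats.cluster_mask(glm, table.loc[[row.name]],
                                             row["contrast"], config.voxel_p,
                                             config.connectivity)
            means = group_stats.extract_roi_means(maps, cmask)
            label = f"{row['contrast']}_cluster{int(row['label'])}"
            for sid, m in zip(cohort.subject_ids, means):
                roi_rows.append({"subject_id": sid, "roi": label, "mean_mreho": m})
            corr_tables.append(group_stats.clinical_correlations(
                means[patient_idx], patients, region=label))
        pd.DataFrame(roi_rows).to_csv(out / "roi_means.tsv", sep="\t", index=False)
        corr = (pd.concat(corr_tables, ignore_index=True) if corr_tables
                else pd.DataFrame(columns=["region", "variable", "r", "p", "n",
                                           "marginal",
                                           "multiple_testing_correction"]))
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        group_stats.demographics_table(cohort).to_csv(
            out / "demographics.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage group_stats failed: {exc}") from exc
    manifest["stages"].append({"stage": "group_stats", "df": glm.df,
                               "n_clusters": int(len(table))})

    # -- manifest ------------------------------------------------------------
    manifest["outputs"] = {p.name: _md5(p) for p in sorted(out.glob("*"))
                           if p.is_file()}
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    logger.info("pipeline complete in %.1f s -> %s", manifest["elapsed_s"], out)
    return out


def render_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (three tables)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}: incomplete run")
    required = ["cluster_table.tsv", "demographics.tsv", "correlations.tsv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing: {missing}")
    lines = [f"rehoscope run report — {run_dir}", ""]
    clusters = pd.read_csv(run_dir / "cluster_table.tsv", sep="\t")
    lines.append("== Supra-threshold clusters ==")
    if len(clusters) == 0:
        lines.append("no significant clusters")
    else:
        lines.append(clusters.to_string(index=False))
    lines.append("")
    corr = pd.read_csv(run_dir / "correlations.tsv", sep="\t")
    lines.append("== Clinical correlations (BD group) ==")
    lines.append(corr.to_string(index=False) if len(corr) else
                 "no regions to correlate")
    lines.append("")
    demo = pd.read_csv(run_dir / "demographics.tsv", sep="\t")
    lines.append("== Demographics ==")
    lines.append(demo.to_string(index=False))
    return "\n".join(lines)
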