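"""End-to-end orchestration: simulate -> dbm -> select -> biotype ->
validate -> progress, with reproducible seeding and a hashed run manifest.

A single master seed deterministically spawns one seed per stage, so one
integer reproduces an entire run.  Every artifact is written under the
run's output directory; the manifest records per-stage parameters,
SHA-256 hashes of inputs and outputs, package version and wall time, and
can be re-verified against the files on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biotyping import discover_biotypes
from .feature_selection import ConfoundModel, select_features
from .morphometry import DBMImage, smooth_fwhm, write_dbm_image
from .progression import progression_summary
from .synthetic import OUTCOMES, SimulationConfig, simulate_cohort, simulate_longitudinal
from .validation import baseline_comparison, crossval_svm, voxelwise_group_ttest

__all__ = ["RunConfig", "run_pipeline", "report_biotype_shares", "verify_manifest", "STAGES"]

STAGES = ("simulate", "dbm", "select", "biotype", "validate", "progress")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults give a desk-scale cohort."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig | None = None
    fwhm_mm: float = 8.0
    alpha: float = 0.01
    var_target: float = 0.90
    k_min: int = 2
    k_max: int = 10
    folds: int = 10
    q_contrast: float = 0.005
    q_table: float = 0.05
    q_progression: float = 0.05
    write_maps: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("q_contrast", "q_table", "q_progression"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0 < self.var_target <= 1:
            raise ValueError(f"var_target must lie in (0, 1], got {self.var_target}")
        if not self.fwhm_mm > 0:
            raise ValueError("fwhm_mm must be positive")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_outputs(paths: list[Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(paths)}


def report_biotype_shares(labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster count and percentage of total, rendered to 2 decimals."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    vals, counts = np.unique(labels, return_counts=True)
    pct = 100.0 * counts / counts.sum()
    return pd.DataFrame(
        {"biotype": vals, "n": counts, "percent": [float(f"{x:.2f}") for x in pct]}
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }
    manifest: dict = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": _config_echo(config),
        "stages": {},
    }

    ctx: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            written = _STAGE_FUNCS[stage](config, stage_seeds[stage], out, ctx)
        except KeyError as exc:
            raise RuntimeError(f"stage {stage!r} is missing an upstream artifact: run {exc} first") from exc
        manifest["stages"][stage] = {
            "seed": stage_seeds[stage],
            "wall_seconds": round(time.perf_counter() - t0, 3),
            "outputs": _hash_outputs(written),
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"] = dataclasses.asdict(config.simulation)
    return d


def verify_manifest(out_dir: str | Path) -> list[str]:
    """Re-hash every recorded artifact; returns the names that changed."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for stage, rec in manifest["stages"].items():
        for name, digest in rec["outputs"].items():
            path = out / name
            if not path.exists() or _sha256(path) != digest:
                bad.append(name)
    return bad


# ---------------------------------------------------------------------------
# stages; each returns the list of files it wrote
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    sim = config.simulation or SimulationConfig(seed=seed)
    if config.simulation is None:
        sim = dataclasses.replace(sim, seed=seed)
    maps, cohort, truth = simulate_cohort(sim)
    longit = simulate_longitudinal(sim, truth, cohort)
    ctx.update(sim=sim, maps=maps, cohort=cohort, truth=truth, longitudinal=longit)
    written = []
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    long_path = out / "longitudinal.csv"
    longit.to_csv(long_path, index=False)
    truth_path = out / "ground_truth.csv"
    pd.DataFrame(
        {
            "subject_id": cohort.loc[cohort["group"] == "PD", "subject_id"].to_numpy(),
            "planted_biotype": truth.biotype,
        }
    ).to_csv(truth_path, index=False)
    written += [cohort_path, long_path, truth_path]
    if config.write_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for sid, img in zip(cohort["subject_id"], maps):
            write_dbm_image(img, maps_dir / f"{sid}_dbm.nii.gz")
    return written


def _stage_dbm(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    maps = ctx["maps"]
    ctx["smoothed"] = [smooth_fwhm(m, config.fwhm_mm) for m in maps]
    ctx["X"] = np.stack([m.values.ravel() for m in ctx["smoothed"]])
    return []


def _stage_select(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    cohort, X = ctx["cohort"], ctx["X"]
    is_pd = (cohort["group"] == "PD").to_numpy()
    model = ConfoundModel.fit(X[is_pd], cohort[is_pd])
    resid_pd = model.residuals(X[is_pd], cohort[is_pd])
    resid_hc = model.residuals(X[~is_pd], cohort[~is_pd])
    fmask = select_features(resid_pd, cohort[is_pd], alpha=config.alpha)
    ctx.update(fmask=fmask, resid_pd=resid_pd, resid_hc=resid_hc, is_pd=is_pd)
    counts_path = out / "selection_counts.csv"
    counts = pd.DataFrame(
        [{"score": k, "n_selected": v, "n_cases": fmask.n_cases[k]} for k, v in fmask.counts.items()]
        + [{"score": "union", "n_selected": fmask.union_count, "n_cases": int(is_pd.sum())}]
    )
    counts.to_csv(counts_path, index=False)
    grid = ctx["sim"].grid_shape
    mask_img = DBMImage(values=fmask.union.reshape(grid).astype(float), spacing_mm=ctx["sim"].voxel_spacing_mm)
    mask_path = out / "union_mask.nii.gz"
    write_dbm_image(mask_img, mask_path)
    return [counts_path, mask_path]


def _stage_biotype(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    fmask, resid_pd = ctx["fmask"], ctx["resid_pd"]
    if fmask.union_count < 2:
        raise RuntimeError("fewer than 2 selected voxels; cannot cluster")
    comps, assignment = discover_biotypes(
        resid_pd[:, fmask.union],
        var_target=config.var_target,
        k_range=range(config.k_min, config.k_max + 1),
        seed=seed,
    )
    ctx.update(components=comps, assignment=assignment)
    cohort = ctx["cohort"].copy()
    cohort.loc[cohort["group"] == "PD", "biotype_assigned"] = assignment.labels.astype(float)
    ctx["cohort_labeled"] = cohort
    labeled_path = out / "cohort_biotyped.csv"
    cohort.to_csv(labeled_path, index=False)
    shares_path = out / "biotype_shares.csv"
    report_biotype_shares(assignment.labels).to_csv(shares_path, index=False)
    linkage_path = out / "linkage.csv"
    pd.DataFrame(assignment.linkage, columns=["node_a", "node_b", "height", "n_members"]).to_csv(
        linkage_path, index=False
    )
    diag_path = out / "biotype_diagnostics.csv"
    pd.DataFrame(
        {
            "k": list(assignment.ch_by_k),
            "calinski_harabasz": list(assignment.ch_by_k.values()),
            "chosen": [k == assignment.k for k in assignment.ch_by_k],
            "kappa_vs_kmeans": assignment.kappa_kmeans,
            "n_components": comps.n_components,
        }
    ).to_csv(diag_path, index=False)
    return [labeled_path, shares_path, linkage_path, diag_path]


def _stage_validate(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    fmask, assignment = ctx["fmask"], ctx["assignment"]
    resid_pd, resid_hc = ctx["resid_pd"], ctx["resid_hc"]
    cohort, is_pd = ctx["cohort"], ctx["is_pd"]
    grid = ctx["sim"].grid_shape
    written = []
    for b in np.unique(assignment.labels):
        sel = assignment.labels == b
        contrast = voxelwise_group_ttest(resid_pd[sel], resid_hc, q=config.q_contrast)
        t_img = DBMImage(values=np.nan_to_num(contrast.t).reshape(grid), spacing_mm=ctx["sim"].voxel_spacing_mm)
        path = out / f"contrast_biotype{b}_vs_hc_t.nii.gz"
        write_dbm_image(t_img, path)
        written.append(path)
    table = baseline_comparison(
        cohort[is_pd].reset_index(drop=True),
        assignment.labels,
        continuous=("age", "education") + OUTCOMES,
        categorical=("sex", "race"),
        q=config.q_table,
    )
    table_path = out / "baseline_comparison.csv"
    table.to_csv(table_path, index=False)
    written.append(table_path)
    metrics = crossval_svm(
        resid_pd[:, fmask.union], assignment.labels, folds=config.folds, seed=seed
    )
    metrics_path = out / "classifier_metrics.csv"
    pd.DataFrame(
        [
            {
                "accuracy": metrics.accuracy,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "auc": metrics.auc,
                "positive_class": metrics.positive_class,
                "folds": metrics.folds,
                "seed": metrics.seed,
            }
        ]
    ).to_csv(metrics_path, index=False)
    ctx["classifier_metrics"] = metrics
    written.append(metrics_path)
    return written


def _stage_progress(config: RunConfig, seed: int, out: Path, ctx: dict) -> list[Path]:
    longit, assignment, cohort = ctx["longitudinal"], ctx["assignment"], ctx["cohort"]
    # progression contrasts use the *assigned* biotypes, as in practice
    pd_ids = cohort.loc[cohort["group"] == "PD", "subject_id"].to_numpy()
    assigned = dict(zip(pd_ids, assignment.labels))
    table = longit.copy()
    table["biotype"] = table["subject_id"].map(assigned)
    summary = progression_summary(table, OUTCOMES, q=config.q_progression)
    ctx["progression"] = summary
    path = out / "progression_summary.csv"
    summary.to_csv(path, index=False)
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "dbm": _stage_dbm,
    "select": _stage_select,
    "biotype": _stage_biotype,
    "validate": _stage_validate,
    "progress": _stage_progress,
}
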