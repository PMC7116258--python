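"""Synthetic multi-site cohorts with planted neuroanatomic biotypes.

The generator emulates the structure of a de novo Parkinson disease (PD)
imaging cohort followed longitudinally: voxelwise deformation-based
morphometry (DBM) maps for PD patients and healthy controls acquired at
several sites, six baseline clinical scores (MDS-UPDRS parts I-III, total,
tremor and PIGD), and a visit schedule with outcome trajectories that
differ by biotype.

Two biotypes are planted inside a "subcortical" block of the voxel grid:
biotype 1 subjects carry a negative mean shift of the DBM signal there
(locally smaller volumes than controls), biotype 2 a positive shift
(locally larger volumes); controls carry no shift.  On top of the planted
signal every map receives additive site, age and sex effects and
unit-variance voxel noise.  Baseline clinical scores are a linear function
of each subject's mean planted-mask signal plus noise, so voxel-score
correlations exist by construction.  Longitudinal outcomes follow a
random-intercept / random-slope linear model with biotype-specific mean
slopes.

Everything is driven by a single integer seed; identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .morphometry import DBMImage, DisplacementField, jacobian_determinant_map

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "OUTCOMES",
    "simulate_cohort",
    "simulate_displacement_field",
    "simulate_longitudinal",
]

#: The six baseline clinical scores, in canonical order.
OUTCOMES = ("updrs1", "updrs2", "updrs3", "updrs_total", "tremor", "pigd")

#: Population mean and SD of each score among de novo PD patients; UPDRS
#: parts I-III use the published cohort values, tremor/PIGD are the usual
#: mean-item-score scale.
SCORE_MEAN = {
    "updrs1": 5.6,
    "updrs2": 5.9,
    "updrs3": 20.7,
    "updrs_total": 32.2,
    "tremor": 0.45,
    "pigd": 0.22,
}
SCORE_SD = {
    "updrs1": 4.0,
    "updrs2": 4.2,
    "updrs3": 8.7,
    "updrs_total": 13.0,
    "tremor": 0.30,
    "pigd": 0.22,
}

#: Monthly mean slope per outcome for (biotype 1, biotype 2).  Biotype 1
#: declines faster on every scale except tremor, whose progression is the
#: same in both groups.
DEFAULT_SLOPES = {
    "updrs1": (0.06, 0.03),
    "updrs2": (0.10, 0.05),
    "updrs3": (0.25, 0.12),
    "updrs_total": (0.40, 0.20),
    "tremor": (0.004, 0.004),
    "pigd": (0.010, 0.004),
}

#: Strength of the link between mean planted-mask DBM signal and each
#: score, in units of the score's SD per unit of DBM signal.  Negative:
#: smaller subcortical volume = worse (higher) symptom scores.
DEFAULT_SCORE_LINK = {
    "updrs1": -0.5,
    "updrs2": -0.5,
    "updrs3": -0.5,
    "updrs_total": -0.5,
    "tremor": -0.2,
    "pigd": -0.4,
}

#: Visit schedule (months): quarterly during the first year, then every
#: six months out to five years.
DEFAULT_VISITS = (0.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0, 54.0, 60.0)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the reference study design: 314 PD patients and 143
    controls from multiple sites, a 36.3%/63.7% biotype split, a planted
    subcortical effect of 0.8 SD, and thirteen visits over five years.
    """

    n_pd: int = 314
    n_hc: int = 143
    biotype_fractions: tuple[float, ...] = (114 / 314, 200 / 314)
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    n_sites: int = 4
    effect_size: float = 0.8
    score_noise_sd: float = 1.0
    visit_months: tuple[float, ...] = DEFAULT_VISITS
    slope_by_biotype: dict = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    seed: int = 0
    # secondary knobs -----------------------------------------------------
    #: per-subject severity spread along the planted direction (SD units)
    severity_sd: float = 0.25
    #: SD of the per-site additive offset on voxel values
    site_effect_sd: float = 0.10
    #: voxel effect per SD of age / for male sex
    age_effect: float = 0.05
    sex_effect: float = 0.05
    score_link: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_LINK))
    #: longitudinal variance components
    random_intercept_sd: float = 2.0
    random_slope_sd: float = 0.1
    residual_sd: float = 1.0
    #: probability that a post-baseline visit record is missing
    dropout_rate: float = 0.0
    #: baseline age effect on longitudinal outcomes (score SD per age SD)
    longitudinal_age_effect: float = 0.05

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_hc < 1:
            raise ValueError("subject counts must be >= 1")
        fr = np.asarray(self.biotype_fractions, dtype=float)
        if fr.size < 2 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError(f"biotype_fractions must be >= 0 and sum to 1, got {self.biotype_fractions}")
        if len(self.grid_shape) != 3 or any(int(g) < 3 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 ints >= 3, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        vm = np.asarray(self.visit_months, dtype=float)
        if vm.size == 0 or vm[0] != 0 or np.any(np.diff(vm) <= 0):
            raise ValueError("visit_months must be strictly increasing and start at 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        object.__setattr__(self, "biotype_fractions", tuple(float(f) for f in fr))
        object.__setattr__(self, "grid_shape", tuple(int(g) for g in self.grid_shape))
        object.__setattr__(self, "voxel_spacing_mm", tuple(float(s) for s in self.voxel_spacing_mm))
        object.__setattr__(self, "visit_months", tuple(float(v) for v in vm))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of one simulated cohort."""

    biotype: np.ndarray  # label in {1, 2} per PD subject
    mask: np.ndarray  # boolean planted "subcortical" block
    slopes: dict  # outcome -> (slope biotype 1, slope biotype 2), per month
    site_effects: np.ndarray  # additive voxel offset per site
    age_effect: float
    sex_effect: float
    severity: np.ndarray  # per-PD-subject severity along the planted axis
    random_intercept_sd: float
    random_slope_sd: float
    residual_sd: float

    def __post_init__(self) -> None:
        if not set(np.unique(self.biotype)) <= {1, 2}:
            raise ValueError("biotype labels must be in {1, 2}")
        if not self.mask.any():
            raise ValueError("planted mask is empty")
        # strictly inside the grid: no mask voxel touches a face
        for ax in range(3):
            edge = [slice(None)] * 3
            for idx in (0, -1):
                edge[ax] = idx
                if self.mask[tuple(edge)].any():
                    raise ValueError("planted mask touches the grid boundary")


def _largest_remainder_counts(fractions: tuple[float, ...], n: int) -> np.ndarray:
    """Apportion n subjects to the fractions, exactly, deterministically."""
    quota = np.asarray(fractions) * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def planted_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Central block occupying the middle third of each axis."""
    mask = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(max(g // 3, 1), max(2 * g // 3, max(g // 3, 1) + 1)) for g in grid_shape)
    mask[sl] = True
    return mask


def simulate_cohort(config: SimulationConfig) -> tuple[list[DBMImage], pd.DataFrame, GroundTruth]:
    """Generate DBM maps, the baseline cohort table and the ground truth.

    Returns
    -------
    maps : list of DBMImage, one per subject, PD subjects first then
        controls, in the row order of the cohort table.
    cohort : DataFrame with subject_id, group, biotype (NaN for controls),
        site, age, sex, education, race and the six baseline scores
        (controls carry NaN scores).
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    n_pd, n_hc = config.n_pd, config.n_hc
    n = n_pd + n_hc

    # biotype allocation: exact largest-remainder counts, seeded permutation
    counts = _largest_remainder_counts(config.biotype_fractions, n_pd)
    biotype = np.repeat(np.arange(1, counts.size + 1), counts)
    biotype = biotype[rng.permutation(n_pd)]

    # sites: round-robin over a seeded permutation of all subjects
    site = np.empty(n, dtype=int)
    site[rng.permutation(n)] = np.arange(n) % config.n_sites
    site_effects = rng.normal(0.0, config.site_effect_sd, size=config.n_sites)

    age = rng.normal(61.0, 9.5, size=n).clip(31.0, 90.0)
    sex = rng.random(n) < 0.659  # True = male, matching the cohort's 65.9%
    education = rng.normal(15.0, 3.0, size=n).clip(5.0, 26.0).round(1)
    race_white = rng.random(n) < 0.9

    mask = planted_mask(config.grid_shape)
    severity = rng.normal(0.0, config.severity_sd, size=n_pd)
    sign = np.where(biotype == 1, -1.0, 1.0)
    shift = np.concatenate([sign * config.effect_size + severity, np.zeros(n_hc)])

    age_z = (age - 61.0) / 9.5
    maps: list[DBMImage] = []
    mean_mask_signal = np.empty(n)
    for i in range(n):
        values = 1.0 + rng.standard_normal(config.grid_shape)
        values += site_effects[site[i]]
        values += config.age_effect * age_z[i] + config.sex_effect * float(sex[i])
        values[mask] += shift[i]
        maps.append(DBMImage(values=values, spacing_mm=config.voxel_spacing_mm))
        mean_mask_signal[i] = values[mask].mean()

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": ["PD"] * n_pd + ["HC"] * n_hc,
            "biotype": np.concatenate([biotype.astype(float), np.full(n_hc, np.nan)]),
            "site": site,
            "age": age.round(1),
            "sex": np.where(sex, "M", "F"),
            "education": education,
            "race": np.where(race_white, "white", "other"),
        }
    )
    # scores: linear in the subject's realized mean planted-mask signal
    signal = mean_mask_signal - 1.0
    for k in OUTCOMES:
        link = config.score_link.get(k, 0.0) * SCORE_SD[k]
        score = SCORE_MEAN[k] + link * signal + rng.normal(0.0, config.score_noise_sd * SCORE_SD[k], size=n)
        score = np.maximum(score, 0.0).round(2)
        score[n_pd:] = np.nan  # motor scales administered to patients only
        cohort[k] = score

    truth = GroundTruth(
        biotype=biotype,
        mask=mask,
        slopes=dict(config.slope_by_biotype),
        site_effects=site_effects,
        age_effect=config.age_effect,
        sex_effect=config.sex_effect,
        severity=severity,
        random_intercept_sd=config.random_intercept_sd,
        random_slope_sd=config.random_slope_sd,
        residual_sd=config.residual_sd,
    )
    return maps, cohort, truth


def simulate_displacement_field(
    grid_shape: tuple[int, int, int],
    mode: str = "zero",
    *,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    s: float | None = None,
    amplitude: float = 0.2,
    seed: int | None = None,
) -> DisplacementField:
    """Test fixtures for the DBM stage.

    mode="zero"
        The zero field (identity warp).
    mode="affine"
        u(x) = (s - 1) x, a uniform scaling whose exact Jacobian
        determinant is s**3 everywhere; requires ``s > 0``.
    mode="smooth_random"
        A seeded band-limited random field with maximum displacement of
        ``amplitude`` voxels; the result is checked to be diffeomorphic
        (det J > 0 at every voxel) and rejected otherwise.
    """
    shape = tuple(int(g) for g in grid_shape)
    if mode == "zero":
        return DisplacementField(u=np.zeros(shape + (3,)), spacing_mm=spacing_mm)
    if mode == "affine":
        if s is None or s <= 0:
            raise ValueError(f"affine mode requires a positive scale s, got {s}")
        coords = np.stack(
            np.meshgrid(*(np.arange(g) * sp for g, sp in zip(shape, spacing_mm)), indexing="ij"),
            axis=-1,
        )
        return DisplacementField(u=(s - 1.0) * coords, spacing_mm=spacing_mm)
    if mode == "smooth_random":
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(shape + (3,))
        for c in range(3):
            u[..., c] = gaussian_filter(u[..., c], sigma=2.0, mode="nearest")
        peak = np.abs(u).max()
        u *= amplitude / peak  # amplitude in voxel units
        u *= np.asarray(spacing_mm)  # convert to mm
        fld = DisplacementField(u=u, spacing_mm=spacing_mm)
        det = jacobian_determinant_map(fld).values
        if det.min() <= 0:
            bad = np.unravel_index(int(np.argmin(det)), det.shape)
            raise ValueError(
                f"amplitude {amplitude} folds the grid: det J = {det.min():.4g} at voxel {bad}"
            )
        return fld
    raise ValueError(f"unknown mode {mode!r}")


def simulate_longitudinal(config: SimulationConfig, truth: GroundTruth, cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-format outcome table for the PD subjects.

    outcome(i, t) = baseline mean + covariate terms + b0_i
                    + (biotype slope + b1_i) * t + eps_it

    with b0 ~ N(0, random_intercept_sd^2), b1 ~ N(0, random_slope_sd^2)
    and eps ~ N(0, residual_sd^2), drawn per outcome.  When
    ``config.dropout_rate`` > 0 each post-baseline record is independently
    dropped with that probability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x10]))
    pd_rows = cohort[cohort["group"] == "PD"].reset_index(drop=True)
    if len(pd_rows) != len(truth.biotype):
        raise KeyError("ground truth does not match the cohort's PD subjects")
    months = np.asarray(config.visit_months)
    n_pd, n_t = len(pd_rows), months.size
    age_z = (pd_rows["age"].to_numpy() - 61.0) / 9.5

    frames = []
    for k in OUTCOMES:
        s1, s2 = truth.slopes.get(k, (0.0, 0.0))
        slope = np.where(truth.biotype == 1, s1, s2)
        b0 = rng.normal(0.0, truth.random_intercept_sd, size=n_pd)
        b1 = rng.normal(0.0, truth.random_slope_sd, size=n_pd)
        eps = rng.normal(0.0, truth.residual_sd, size=(n_pd, n_t))
        base = SCORE_MEAN[k] + config.longitudinal_age_effect * SCORE_SD[k] * age_z
        y = base[:, None] + b0[:, None] + (slope + b1)[:, None] * months[None, :] + eps
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(pd_rows["subject_id"].to_numpy(), n_t),
                    "visit_month": np.tile(months, n_pd),
                    "outcome": k,
                    "value": y.ravel(),
                    "biotype": np.repeat(truth.biotype, n_t),
                    "age": np.repeat(pd_rows["age"].to_numpy(), n_t),
                    "sex": np.repeat(pd_rows["sex"].to_numpy(), n_t),
                    "race": np.repeat(pd_rows["race"].to_numpy(), n_t),
                    "site": np.repeat(pd_rows["site"].to_numpy(), n_t),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if config.dropout_rate > 0:
        keep = (table["visit_month"] == 0) | (rng.random(len(table)) >= config.dropout_rate)
        table = table[keep].reset_index(drop=True)
    return table
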