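"""Seeded synthetic rs-fMRI cohorts with planted connectivity effects.

The generator emulates the structure of a population pediatric neuroimaging
cohort: children aged 6-10 years with roughly balanced sex, 160 BOLD volumes
at TR = 2 s on a coarse EPI-like grid, block-shaped mirrored ROIs, motion
traces with occasional >0.5 mm spikes, global white-matter/CSF nuisance
signals mixed into every voxel, and a right-skewed behavioral covariate (the
square root of a summed symptom-item score).

Signal model
------------
Every region r owns a unit-variance Gaussian latent series ``u_r``. A
planted edge (A, B) introduces a shared latent ``s``; the participating
voxels receive ``w*s + sqrt(1-w^2)*u_r`` so region signals stay unit
variance. The mixing weight ``w`` is solved in closed form so that the
*expected sample statistic the edge is scored with* — the region-mean
(MeanTS) correlation in homogeneous mode, the peak voxel-pair (ALPACA)
correlation in focal mode — equals the target correlation, accounting for
voxel noise dilution and the shared nuisance component.

Planted covariate effects act on the Fisher-z scale: the target correlation
for a subject of age a and sex g is

    r(a, g) = tanh( arctanh(baseline_r) + beta_age*(a - mean age) + beta_sex*g )

clamped to (0, 0.99). Because the downstream edgewise regression models
Fisher-z connectivity linearly in age and sex, z-scale planting makes those
models exactly correctly specified, so a planted ``beta_age`` is directly
the slope the regression should recover (in z units per year).

In focal mode only a contiguous block of ``hotspot_fraction`` of each
region's voxels (anchored at the region's scan-order corner, so the peak
location is reproducible) carries the shared latent. The hotspot behaves as
a single coherent locus: its voxels share one noise draw, which keeps the
peak-correlation statistic an unbiased estimate of the calibrated target
(a max over independently noisy pairs would be biased upward by selection).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, build_phantom_atlas
from .preprocess import LabeledVolume, MotionTrace, save_labeled_volume, save_motion


class CohortParameterError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedEffect:
    """A connectivity effect planted on one region pair.

    ``edge`` uses hemisphere-qualified region keys, e.g. ``("Acc_L", "Tha_L")``.
    ``beta_age`` and ``beta_sex`` are Fisher-z units per year and per
    male-vs-female contrast respectively.
    """

    edge: tuple[str, str]
    beta_age: float = 0.0
    beta_sex: float = 0.0
    mode: str = "homogeneous"  # or "focal"
    hotspot_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "focal"):
            raise CohortParameterError(f"unknown planted-effect mode {self.mode!r}")
        if not 0 < self.hotspot_fraction <= 1:
            raise CohortParameterError("hotspot_fraction must be in (0, 1]")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort (one seed = one cohort)."""

    n_subjects: int
    age_range: tuple[float, float] = (6.0, 10.0)
    sex_ratio: float = 0.5          # fraction male
    n_volumes: int = 160
    tr: float = 2.0
    voxel_dims: tuple[float, float, float] = (3.4, 3.4, 4.0)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    baseline_r: float = 0.5
    noise_sd: float = 0.5           # per-voxel noise, units of latent SD
    motion_spike_prob: float = 0.02  # per-volume probability of a >0.5 mm spike
    seed: int = 0
    # atlas geometry
    grid_shape: tuple[int, int, int] = (20, 20, 10)
    regions_per_group: dict[str, int] | str = field(
        default_factory=lambda: {"Fro": 1, "Occ": 1, "Par": 1, "Sub": 1, "Temp": 1}
    )
    block_shape: tuple[int, int, int] = (4, 4, 4)
    # nuisance model
    nuisance_weight: float = 0.2    # WM and CSF mixing weight into every voxel
    spike_offset: float = 3.0       # global intensity offset on spike volumes

    def __post_init__(self) -> None:
        if not 0 < self.baseline_r < 1:
            raise CohortParameterError("baseline_r must lie in (0, 1)")
        if self.n_subjects < 2:
            raise CohortParameterError("need at least 2 subjects")
        if self.n_volumes < 1:
            raise CohortParameterError("need at least 1 volume")
        if not 0 <= self.sex_ratio <= 1:
            raise CohortParameterError("sex_ratio must lie in [0, 1]")
        if self.noise_sd < 0:
            raise CohortParameterError("noise_sd must be nonnegative")

    @property
    def mean_age(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: int  # 0 female, 1 male
    cbcl_sqrt_total: float
    data: LabeledVolume | None = None
    motion: MotionTrace | None = None

    def __post_init__(self) -> None:
        if self.cbcl_sqrt_total < 0:
            raise CohortParameterError("cbcl_sqrt_total must be nonnegative")


# ---------------------------------------------------------------------------
# calibration


def target_correlation(
    spec: CohortSpec, effect: PlantedEffect, age: float, sex: int
) -> float:
    """Planted target correlation for one subject, clamped to (0, 0.99)."""
    z = (
        np.arctanh(spec.baseline_r)
        + effect.beta_age * (age - spec.mean_age)
        + effect.beta_sex * sex
    )
    return float(np.clip(np.tanh(z), 1e-3, 0.99))


def _nuisance_var(spec: CohortSpec) -> float:
    # WM and CSF are independent unit-variance series, both mixed with the
    # same weight into every voxel.
    return 2.0 * spec.nuisance_weight**2


def homogeneous_weight(
    spec: CohortSpec, r_target: float, n_vox_a: int, n_vox_b: int
) -> float:
    """Shared-latent weight so the expected MeanTS correlation is ``r_target``.

    The region mean over V voxels has variance 1 + nu + sigma^2/V (signal +
    nuisance + averaged voxel noise) and the cross-covariance is w^2 + nu,
    hence  w^2 = r * sqrt((1+nu+s^2/Va)(1+nu+s^2/Vb)) - nu.
    """
    nu = _nuisance_var(spec)
    s2 = spec.noise_sd**2
    w2 = r_target * np.sqrt((1 + nu + s2 / n_vox_a) * (1 + nu + s2 / n_vox_b)) - nu
    if not 0 <= w2 <= 1:
        raise CohortParameterError(
            f"target correlation {r_target:.3f} is not calibratable in "
            f"homogeneous mode (required weight^2 = {w2:.3f})"
        )
    return float(np.sqrt(w2))


def focal_weight(spec: CohortSpec, r_target: float) -> float:
    """Shared-latent weight so the expected peak voxel-pair correlation is
    ``r_target``: hotspot series variance is 1 + sigma^2 + nu and the
    cross-covariance w^2 + nu, hence w^2 = r*(1+sigma^2+nu) - nu."""
    nu = _nuisance_var(spec)
    w2 = r_target * (1 + spec.noise_sd**2 + nu) - nu
    if not 0 <= w2 <= 1:
        raise CohortParameterError(
            f"target correlation {r_target:.3f} is not calibratable in focal "
            f"mode with noise_sd {spec.noise_sd} (required weight^2 = {w2:.3f})"
        )
    return float(np.sqrt(w2))


def hotspot_voxels(atlas: RegionAtlas, key: str, fraction: float) -> np.ndarray:
    """First ``fraction`` of the region's voxels in scan order (corner block)."""
    idx = atlas.voxel_indices(key)
    n = max(1, int(round(fraction * len(idx))))
    return idx[:n]


# ---------------------------------------------------------------------------
# simulation


def _check_effects(spec: CohortSpec, atlas: RegionAtlas) -> None:
    seen: set[str] = set()
    for eff in spec.planted_effects:
        for key in eff.edge:
            if key not in atlas:
                raise CohortParameterError(f"planted edge references unknown region {key}")
            if key in seen:
                raise CohortParameterError(
                    f"region {key} appears in more than one planted effect; "
                    "planted effects must use disjoint region pairs"
                )
            seen.add(key)


def simulate_subject(
    spec: CohortSpec,
    record: SubjectRecord,
    atlas: RegionAtlas,
    seed: int,
) -> tuple[LabeledVolume, MotionTrace]:
    """Generate one subject's labeled 4D volume and motion trace."""
    _check_effects(spec, atlas)
    rng = np.random.default_rng(seed)
    t = spec.n_volumes
    shape = atlas.label_volume.shape
    sigma = spec.noise_sd

    data = rng.standard_normal((*shape, t)) * sigma

    # independent unit-variance latent per region
    latents = {key: rng.standard_normal(t) for key in atlas.keys}

    for eff in spec.planted_effects:
        r_t = target_correlation(spec, eff, record.age, record.sex)
        shared = rng.standard_normal(t)
        if eff.mode == "homogeneous":
            key_a, key_b = eff.edge
            w = homogeneous_weight(
                spec, r_t, atlas.voxel_count(key_a), atlas.voxel_count(key_b)
            )
            for key in eff.edge:
                latents[key] = w * shared + np.sqrt(1 - w**2) * latents[key]
        else:  # focal: overwrite the hotspot after the region fill below
            pass

    # fill regions with their latent signal
    for key in atlas.keys:
        roi = atlas.label_volume == atlas.region(key).label
        data[roi] += latents[key]

    # focal hotspots: one coherent locus per region, sharing a noise draw
    for eff in spec.planted_effects:
        if eff.mode != "focal":
            continue
        r_t = target_correlation(spec, eff, record.age, record.sex)
        w = focal_weight(spec, r_t)
        shared = rng.standard_normal(t)
        for key in eff.edge:
            hot = w * shared + np.sqrt(1 - w**2) * latents[key]
            hot = hot + sigma * rng.standard_normal(t)
            hv = hotspot_voxels(atlas, key, eff.hotspot_fraction)
            data[hv[:, 0], hv[:, 1], hv[:, 2], :] = hot

    # global nuisance signals mixed into every voxel
    wm = rng.standard_normal(t)
    csf = rng.standard_normal(t)
    data += spec.nuisance_weight * (wm + csf)

    # motion: gentle random walk plus occasional spikes
    steps = rng.normal(0.0, 0.01, size=(t, 6))
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    rel = np.abs(rng.normal(0.0, 0.08, size=t))
    rel = np.minimum(rel, 0.45)
    spikes = rng.random(t) < spec.motion_spike_prob
    spikes[0] = False
    rel[spikes] = rng.uniform(0.55, 1.5, size=int(spikes.sum()))
    rel[0] = 0.0
    params[spikes, 0] += rel[spikes]  # spike shows up in the raw parameters too
    data[..., spikes] += spec.spike_offset

    volume = LabeledVolume(
        data=data,
        labels=atlas.label_volume.copy(),
        brain_mask=np.ones(shape, dtype=bool),
        tr=spec.tr,
        voxel_dims=spec.voxel_dims,
        wm_series=wm,
        csf_series=csf,
    )
    return volume, MotionTrace(params, rel)


def subject_seed(spec_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    return int(np.random.SeedSequence([spec_seed, index]).generate_state(1)[0])


def draw_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Cohort covariate table: ages uniform over the range, sexes assigned
    to match ``sex_ratio`` exactly, behavioral score = sqrt(Poisson(9))."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    n = spec.n_subjects
    ages = rng.uniform(*spec.age_range, size=n)
    sex = np.zeros(n, dtype=int)
    n_male = int(round(n * spec.sex_ratio))
    sex[rng.permutation(n)[:n_male]] = 1
    cbcl = np.sqrt(rng.poisson(9.0, size=n).astype(float))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "cbcl_sqrt_total": cbcl,
        }
    )


def simulate_cohort(
    spec: CohortSpec, attach_data: bool = True
) -> tuple[list[SubjectRecord], RegionAtlas]:
    """Generate the full cohort. Identical specs yield identical cohorts.

    With ``attach_data=False`` only covariates and the atlas are produced
    (cheap path for covariate-level checks).
    """
    atlas = build_phantom_atlas(
        spec.grid_shape, spec.regions_per_group, spec.block_shape
    )
    _check_effects(spec, atlas)
    cov = draw_covariates(spec)
    records: list[SubjectRecord] = []
    for i, row in cov.iterrows():
        rec = SubjectRecord(
            subject_id=row["subject_id"],
            age=float(row["age"]),
            sex=int(row["sex"]),
            cbcl_sqrt_total=float(row["cbcl_sqrt_total"]),
        )
        if attach_data:
            vol, motion = simulate_subject(spec, rec, atlas, subject_seed(spec.seed, i))
            rec.data = vol
            rec.motion = motion
        records.append(rec)
    return records, atlas


# ---------------------------------------------------------------------------
# on-disk cohort layout


def covariate_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "cbcl_sqrt_total": [r.cbcl_sqrt_total for r in records],
        }
    )


def write_cohort(
    records: Sequence[SubjectRecord], atlas: RegionAtlas, outdir: Path
) -> None:
    """Write NIfTI volumes, motion TSVs, covariates.tsv and atlas.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    covariate_frame(records).to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    (outdir / "atlas.json").write_text(atlas.to_json())
    first = next((r for r in records if r.data is not None), None)
    if first is not None:
        affine = np.diag([*first.data.voxel_dims, 1.0])
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(atlas.label_volume.astype(np.int32), affine),
            outdir / "atlas_labels.nii",
        )
    for rec in records:
        if rec.data is None:
            continue
        save_labeled_volume(rec.data, outdir / "func" / rec.subject_id)
        save_motion(rec.motion, outdir / "motion" / f"{rec.subject_id}.tsv")


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain (YAML/JSON-loaded) mapping."""
    d = dict(d)
    effects = [
        PlantedEffect(
            edge=tuple(e["edge"]),
            beta_age=float(e.get("beta_age", 0.0)),
            beta_sex=float(e.get("beta_sex", 0.0)),
            mode=e.get("mode", "homogeneous"),
            hotspot_fraction=float(e.get("hotspot_fraction", 0.1)),
        )
        for e in d.pop("planted_effects", [])
    ]
    for key in ("age_range", "voxel_dims", "grid_shape", "block_shape"):
        if key in d:
            d[key] = tuple(d[key])
    allowed = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(d) - allowed
    if unknown:
        raise CohortParameterError(f"unknown cohort spec keys: {sorted(unknown)}")
    return CohortSpec(planted_effects=effects, **d)
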