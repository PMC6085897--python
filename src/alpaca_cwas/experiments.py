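"""Reference simulation studies: calibration, error control, dissociation.

These are the package's canonical Monte-Carlo experiments, run both by the
test suite and by ``scripts/acceptance.py``. Each study generates seeded
synthetic cohorts on the compact 10-region phantom (27-voxel mirrored block
regions on a 16 x 12 x 8 grid), computes connectomes straight from the
generator output, and summarizes the edgewise statistics. Motion spikes and
preprocessing are exercised elsewhere (the pipeline tests); here the
generator's nuisance compensation keeps planted targets exact, so these
studies isolate the statistical properties of the association stage.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec, PlantedEffect, covariate_frame, simulate_cohort
from .connectome import build_connectome
from .stats import correct, edge_matrix_from_connectomes, fit_all_edges, significant_edges

COMPACT_GEOMETRY = dict(
    grid_shape=(16, 12, 8),
    block_shape=(3, 3, 3),
    regions_per_group={"Fro": 1, "Occ": 1, "Par": 1, "Sub": 1, "Temp": 1},
)

#: three disjoint region pairs used for planted age effects
RECOVERY_EDGES = (
    ("Cac_L", "Cun_L"),
    ("IPa_L", "Acc_L"),
    ("BSt_L", "Cac_R"),
)


def _cohort_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def _analyze(records, atlas, method: str):
    conns = [build_connectome(r.data, atlas, atlas.keys, method) for r in records]
    edge_mat = edge_matrix_from_connectomes(conns)
    covs = covariate_frame(records)
    table = fit_all_edges(edge_mat, covs)
    correction = correct(edge_mat.to_numpy(), method)
    return table, correction


def _edge_row(table, edge):
    a, b = edge
    row = table[(table.region_a == a) & (table.region_b == b)]
    if row.empty:
        row = table[(table.region_a == b) & (table.region_b == a)]
    return row.iloc[0]


def parameter_recovery_study(
    n_cohorts: int = 100,
    n_subjects: int = 200,
    beta_age: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of planted age slopes by the MeanTS association stage.

    Each cohort plants ``beta_age`` (z units/year) on three disjoint edges
    of the 10-region phantom. Returns the mean estimated slope, its relative
    bias, and the fraction of planted edge-cohort pairs significant at the
    per-cohort Sidak threshold.
    """
    betas, detected, total = [], 0, 0
    for c in range(n_cohorts):
        spec = CohortSpec(
            n_subjects=n_subjects,
            seed=_cohort_seed(seed, c),
            motion_spike_prob=0.0,
            planted_effects=[
                PlantedEffect(edge=e, beta_age=beta_age) for e in RECOVERY_EDGES
            ],
            **COMPACT_GEOMETRY,
        )
        records, atlas = simulate_cohort(spec)
        table, correction = _analyze(records, atlas, "meants")
        sig = significant_edges(table, correction, "age")
        sig_set = {frozenset(e) for e in zip(sig.region_a, sig.region_b)}
        for e in RECOVERY_EDGES:
            betas.append(float(_edge_row(table, e)["beta_age"]))
            detected += frozenset(e) in sig_set
            total += 1
    mean_beta = float(np.mean(betas))
    return {
        "true_beta_age": beta_age,
        "mean_beta_age": mean_beta,
        "relative_bias": (mean_beta - beta_age) / beta_age,
        "detection_rate": detected / total,
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def null_fwer_study(
    n_cohorts: int = 100, n_subjects: int = 100, seed: int = 0
) -> dict:
    """Family-wise error of the Sidak-corrected age test under the global null."""
    families_with_error = 0
    for c in range(n_cohorts):
        spec = CohortSpec(
            n_subjects=n_subjects,
            seed=_cohort_seed(seed, 10_000 + c),
            motion_spike_prob=0.0,
            **COMPACT_GEOMETRY,
        )
        records, atlas = simulate_cohort(spec)
        table, correction = _analyze(records, atlas, "meants")
        if len(significant_edges(table, correction, "age")):
            families_with_error += 1
    return {
        "fwer": families_with_error / n_cohorts,
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def focal_dissociation_study(
    n_seeds: int = 50,
    n_subjects: int = 60,
    beta_age: float = 0.1,
    hotspot_fraction: float = 0.1,
    seed: int = 0,
) -> dict:
    """Detection of a focal planted age effect: peak voxel-pair vs region mean.

    One focal edge (10% hotspot by default) carries the age effect; the
    region-mean statistic is diluted by roughly the squared hotspot fraction,
    while the peak statistic sees the full planted slope. Returns per-method
    detection rates of the planted edge at each method's Sidak threshold.
    """
    edge = ("Cac_L", "Cun_L")
    hits = {"meants": 0, "alpaca": 0}
    for c in range(n_seeds):
        spec = CohortSpec(
            n_subjects=n_subjects,
            seed=_cohort_seed(seed, 20_000 + c),
            motion_spike_prob=0.0,
            planted_effects=[
                PlantedEffect(
                    edge=edge,
                    beta_age=beta_age,
                    mode="focal",
                    hotspot_fraction=hotspot_fraction,
                )
            ],
            **COMPACT_GEOMETRY,
        )
        records, atlas = simulate_cohort(spec)
        for method in ("meants", "alpaca"):
            table, correction = _analyze(records, atlas, method)
            sig = significant_edges(table, correction, "age")
            sig_set = {frozenset(e) for e in zip(sig.region_a, sig.region_b)}
            hits[method] += frozenset(edge) in sig_set
    return {
        "alpaca_detection_rate": hits["alpaca"] / n_seeds,
        "meants_detection_rate": hits["meants"] / n_seeds,
        "n_seeds": n_seeds,
        "n_subjects": n_subjects,
    }
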