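"""End-to-end orchestration: simulate -> preprocess -> connectome -> stats -> viz.

A single YAML/dict config drives the whole run; every study-level parameter
(volume truncation at 160, 4 dropped volumes, 0.01 Hz high-pass, 0.5 mm
scrub threshold, 125-volume exclusion floor, 90% ROI overlap, alpha = 0.05)
is a named key with that default. The run manifest accounts for every
subject exactly once — included, or excluded with a reason — and identical
configs produce identical manifests and association tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import connectome as conn_mod
from . import preprocess as pre_mod
from . import stats as stats_mod
from . import viz as viz_mod
from .atlas import RegionAtlas

logger = logging.getLogger(__name__)

PREPROCESS_DEFAULTS = {
    "max_volumes": 160,
    "drop_first": 4,
    "hp_cutoff_hz": 0.01,
    "scrub_threshold_mm": 0.5,
    "min_volumes": 125,
    "overlap_threshold": 0.90,
    "manual_exclusions": list(pre_mod.SUSCEPTIBILITY_EXCLUDED_NAMES),
}

STATS_DEFAULTS = {"alpha": 0.05, "interaction": False, "estimator": "fractional"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        where = f"stage {stage!r}" + (f", subject {subject!r}" if subject else "")
        super().__init__(f"{where}: {cause}")


@dataclass
class RunManifest:
    config_hash: str
    subjects: list[dict] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # id -> reason
    corrections: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    included_regions: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @property
    def manifest_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def load_config(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: Mapping[str, Any] | Path | str) -> RunManifest:
    """Run the full analysis described by ``config``; returns the manifest.

    Any stage failure aborts with the stage name, subject id and cause.
    """
    if isinstance(config, (str, Path)):
        config = load_config(Path(config))
    config = dict(config)
    out_dir = Path(config.get("out_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    pp = {**PREPROCESS_DEFAULTS, **config.get("preprocess", {})}
    st = {**STATS_DEFAULTS, **config.get("stats", {})}
    manifest = RunManifest(config_hash=_config_hash(config))

    # ---- simulate -------------------------------------------------------
    try:
        spec = cohort_mod.spec_from_dict(config["cohort"])
        records, atlas = cohort_mod.simulate_cohort(spec)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", None, exc) from exc

    # ---- ROI inclusion --------------------------------------------------
    try:
        included, overlaps = pre_mod.roi_overlap_filter(
            atlas,
            [rec.data.brain_mask for rec in records],
            mean_threshold=pp["overlap_threshold"],
            manual_exclusions=pp["manual_exclusions"],
        )
        manifest.included_regions = included
    except Exception as exc:
        raise PipelineError("roi_overlap", None, exc) from exc

    # ---- per-subject preprocessing and connectomes ----------------------
    connectomes: dict[str, list] = {"meants": [], "alpaca": []}
    kept_records: list[cohort_mod.SubjectRecord] = []
    for rec in records:
        try:
            v, m = pre_mod.trim_volumes(
                rec.data, rec.motion, pp["max_volumes"], pp["drop_first"]
            )
            volumes_in = rec.data.n_volumes
            trimmed = volumes_in - v.n_volumes
            v = pre_mod.highpass_filter(v, pp["hp_cutoff_hz"])
            v = pre_mod.regress_confounds(v, m)
            v, m, report = pre_mod.scrub(
                v, m, pp["scrub_threshold_mm"], pp["min_volumes"]
            )
            report.volumes_in = volumes_in
            report.volumes_trimmed = trimmed
            report.roi_overlap = {k: overlaps[k] for k in included}
            manifest.subjects.append(
                {
                    "subject_id": rec.subject_id,
                    "volumes_in": report.volumes_in,
                    "volumes_trimmed": report.volumes_trimmed,
                    "n_scrubbed": len(report.scrubbed_indices),
                    "volumes_kept": report.volumes_kept,
                    "included": not report.excluded_subject,
                }
            )
            if report.excluded_subject:
                manifest.excluded[rec.subject_id] = "min_volumes"
                continue
            v = pre_mod.median_filter_3x3x3(v)
            for method in conn_mod.METHODS:
                connectomes[method].append(
                    conn_mod.build_connectome(v, atlas, included, method)
                )
            kept_records.append(rec)
        except Exception as exc:
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError("preprocess", rec.subject_id, exc) from exc

    cohort_mod.covariate_frame(records).to_csv(
        out_dir / "covariates.tsv", sep="\t", index=False
    )
    if not kept_records:
        raise PipelineError("stats", None, ValueError("no subjects survived preprocessing"))

    # ---- statistics -----------------------------------------------------
    covs = cohort_mod.covariate_frame(kept_records)
    tables: dict[str, pd.DataFrame] = {}
    corrections: dict[str, stats_mod.CorrectionResult] = {}
    try:
        for method in conn_mod.METHODS:
            edge_mat = stats_mod.edge_matrix_from_connectomes(connectomes[method])
            table = stats_mod.fit_all_edges(edge_mat, covs, interaction=st["interaction"])
            correction = stats_mod.correct(
                edge_mat.to_numpy(), method, st["alpha"], st["estimator"]
            )
            tables[method] = table
            corrections[method] = correction
            table.to_csv(out_dir / f"associations_{method}.tsv", sep="\t", index=False)
            (out_dir / f"correction_{method}.json").write_text(
                json.dumps(dataclasses.asdict(correction), indent=1)
            )
            manifest.corrections[method] = dataclasses.asdict(correction)
            for covariate in ("age", "sex"):
                sig = stats_mod.significant_edges(table, correction, covariate)
                sig.to_csv(
                    out_dir / f"significant_{covariate}_{method}.tsv",
                    sep="\t",
                    index=False,
                )
                if covariate == "age":
                    stats_mod.classify_symmetry(sig, atlas).to_csv(
                        out_dir / f"symmetry_{method}.tsv", sep="\t", index=False
                    )
                    stats_mod.tally_by_group(sig, atlas).to_csv(
                        out_dir / f"tally_{method}.tsv", sep="\t", index=False
                    )
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("stats", None, exc) from exc

    # ---- figures --------------------------------------------------------
    try:
        for method in conn_mod.METHODS:
            for covariate in ("age", "sex"):
                sig = stats_mod.significant_edges(
                    tables[method], corrections[method], covariate
                )
                layout = viz_mod.connectogram_layout(
                    sig, atlas, corrections[method].alpha_corr
                )
                path = out_dir / f"connectogram_{covariate}_{method}.svg"
                viz_mod.render_connectogram(layout, path, f"{method} ~ {covariate}")
                manifest.outputs[path.name] = str(path)
        for covariate in ("age", "sex"):
            wl = viz_mod.worm_layout(tables, corrections, atlas, covariate)
            path = out_dir / f"worm_{covariate}.svg"
            viz_mod.render_worm(wl, path, f"associations with {covariate}")
            manifest.outputs[path.name] = str(path)
    except Exception as exc:
        raise PipelineError("viz", None, exc) from exc

    for p in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.json")):
        if p.name != "manifest.json":
            manifest.outputs.setdefault(p.name, str(p))
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
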