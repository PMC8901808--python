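"""Run orchestration, configuration files, and report bundles.

``run_pipeline`` drives the whole analysis — cohort generation (or NIfTI
ingestion), kinetic maps, regions, feature extraction for one or both
arms, reduction, the repeated-seed modeling protocol — and writes a report
bundle: feature tables (CSV), per-arm performance and selected features
(JSON), the resolved configuration (YAML) and a structured log.  The CR
and DLB arms share every stage except feature extraction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backbone import Backbone, BackboneConfig
from .model import SLNPredictionModel, SLNPredictionResults
from .modeling import ModelConfig
from .phantom import (CLINICAL_FEATURE_NAMES, ClinicalRecord, DCEStudy,
                      PhantomConfig, generate_cohort)
from .reduction import ReductionGrid, ReductionParams
from .regions import MIN_ROI_VOXELS, validate_roi

__all__ = ["RunConfig", "load_study", "run_pipeline", "save_config", "load_config"]

log = logging.getLogger("slnrad")


@dataclass
class RunConfig:
    mode: str = "synthetic"              # synthetic | real
    analysis: str = "intra_peri"         # intra_peri | intra_only
    arm: str = "both"                    # CR | DLB | both
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    reduction_params: ReductionParams = field(default_factory=ReductionParams)
    search_grid: bool = False            # grid-search reduction params first
    grid: ReductionGrid = field(default_factory=ReductionGrid)
    model: ModelConfig = field(default_factory=ModelConfig)
    backbone: BackboneConfig = field(
        default_factory=lambda: BackboneConfig(architecture_id="tiny")
    )
    output_dir: str = "slnrad_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.analysis not in ("intra_peri", "intra_only"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        if self.arm not in ("CR", "DLB", "both"):
            raise ValueError(f"unknown arm {self.arm!r}")

    @property
    def arms(self) -> tuple[str, ...]:
        return ("CR", "DLB") if self.arm == "both" else (self.arm,)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    raw["phantom"] = PhantomConfig(**_tuplify(raw.get("phantom", {}), ("grid_shape",)))
    raw["reduction_params"] = ReductionParams(**raw.get("reduction_params", {}))
    raw["grid"] = ReductionGrid(**{
        k: tuple(v) for k, v in raw.get("grid", {}).items()
    })
    raw["model"] = ModelConfig(**raw.get("model", {}))
    raw["backbone"] = BackboneConfig(**raw.get("backbone", {}))
    return RunConfig(**raw)


def _tuplify(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and v is not None else v for k, v in d.items()}


# ---------------------------------------------------------------------------
# real-mode ingestion
# ---------------------------------------------------------------------------

def load_study(
    phase_paths: list[str | Path],
    mask_path: str | Path,
    clinical: ClinicalRecord,
    label: bool,
    subject_id: str,
) -> DCEStudy:
    """Load one subject from NIfTI phase volumes and a binary mask.

    Validates the five-phase contract, a shared grid, mask binarity and the
    64-voxel ROI inclusion rule; spacing is read from the image header.
    """
    import nibabel as nib

    if len(phase_paths) != 5:
        raise ValueError(
            f"{subject_id}: a DCE study needs exactly 5 phase volumes "
            f"(one pre-contrast + four post-contrast), got {len(phase_paths)}"
        )
    imgs = [nib.load(str(p)) for p in phase_paths]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"{subject_id}: phase volumes on mismatched grids {shapes}")
    mask_img = nib.load(str(mask_path))
    if mask_img.shape != imgs[0].shape:
        raise ValueError(f"{subject_id}: mask grid does not match the phases")
    mask_data = np.asanyarray(mask_img.dataobj)
    uniq = set(np.unique(mask_data).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"{subject_id}: mask is not binary (values {sorted(uniq)[:5]})")
    mask = mask_data.astype(bool)
    if not validate_roi(mask):
        raise ValueError(
            f"{subject_id}: tumor ROI has {int(mask.sum())} voxels, below the "
            f"{MIN_ROI_VOXELS}-voxel inclusion bound"
        )
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    phases = [np.asanyarray(im.dataobj).astype(np.float32) for im in imgs]
    return DCEStudy(phases=phases, spacing=spacing, intratumoral_mask=mask,
                    label=label, clinical=clinical, subject_id=subject_id)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    studies: list[DCEStudy] | None = None,
) -> dict[str, SLNPredictionResults]:
    """Execute the configured analysis and write the report bundle.

    In synthetic mode the cohort is generated from ``config.phantom`` (with
    ``config.seed`` overriding the phantom seed); in real mode ``studies``
    must be supplied (e.g. via :func:`load_study`).  Returns the per-arm
    results keyed "CR"/"DLB".
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        if config.mode == "synthetic":
            phantom = dataclasses.replace(config.phantom, seed=config.seed)
            log.info("stage=cohort seed=%d n=%d", config.seed,
                     phantom.n_train + phantom.n_val + phantom.n_test)
            studies, manifest = generate_cohort(phantom)
            (out / "manifest.json").write_text(json.dumps({
                "planted_mechanisms": manifest.planted_mechanisms,
                "clinical_associations": manifest.clinical_associations,
                "seed": manifest.seed,
                "labels": {k: bool(v["label"]) for k, v in manifest.subjects.items()},
            }, indent=2))
        else:
            if studies is None:
                raise ValueError("real mode requires pre-loaded studies")
            phantom = config.phantom

        results: dict[str, SLNPredictionResults] = {}
        for arm in config.arms:
            backbone = Backbone(config.backbone) if arm == "DLB" else None
            log.info("stage=extract arm=%s analysis=%s subjects=%d",
                     arm, config.analysis, len(studies))
            model = SLNPredictionModel.from_cohort(
                studies, phantom, arm=arm, analysis=config.analysis,
                backbone=backbone,
                reduction_params=config.reduction_params, config=config.model,
            )
            feats = model.features.copy()
            feats["label"] = model.labels
            feats.to_csv(out / f"features_{arm}.csv")
            if arm == "CR":
                from .cr import default_catalog
                (out / "catalog_CR.json").write_text(
                    default_catalog(config.analysis).to_json())
            log.info("stage=features arm=%s rows=%d cols=%d",
                     arm, feats.shape[0], feats.shape[1] - 1)

            if config.search_grid:
                winner, scores = model.search_reduction_params(
                    config.grid, n_seeds=config.model.n_seeds)
                scores.to_csv(out / f"grid_scores_{arm}.csv", index=False)
                log.info("stage=grid arm=%s winner=%s", arm, winner)

            res = model.fit(seed=config.seed)
            results[arm] = res
            log.info("stage=model arm=%s winning_seed=%d selected=%d",
                     arm, res.pipeline.seed, len(res.selected_features))

            import sklearn

            from . import __version__

            bundle = {
                "arm": arm,
                "analysis": config.analysis,
                "seed": config.seed,
                "versions": {
                    "slnrad": __version__,
                    "numpy": np.__version__,
                    "sklearn": sklearn.__version__,
                    "pandas": pd.__version__,
                },
                "winning_seed": res.pipeline.seed,
                "reduction_params": dataclasses.asdict(model.reduction_params),
                "selected_features": res.selected_features,
                "coefficients": {k: float(v) for k, v in res.params.items()},
                "threshold": res.threshold,
                "performance": {k: v.as_dict() for k, v in res.reports.items()},
            }
            (out / f"report_{arm}.json").write_text(json.dumps(bundle, indent=2))
            (out / f"summary_{arm}.txt").write_text(res.summary() + "\n")
        return results
    finally:
        log.removeHandler(handler)
        handler.close()
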