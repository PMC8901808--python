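"""Subject-level feature table assembly for the two feature arms.

A feature table is a pandas DataFrame, one row per subject, columns keyed
``<source>:<region>:<map>:<feature>`` for image features and
``clinical:<name>`` for the 11-number clinical block; the source prefix
(``CR`` / ``DLB`` / ``clinical``) is the provenance tag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import backbone as bb
from .cr import FeatureCatalog, default_catalog, extract_cr_vector
from .kinetics import compute_kinetic_maps
from .phantom import DCEStudy
from .regions import build_peritumoral_ring, validate_roi

__all__ = ["extract_study_features", "build_feature_table", "clinical_columns_of"]


def clinical_columns_of(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("clinical:")]


def extract_study_features(
    study: DCEStudy,
    arm: str,
    analysis: str = "intra_peri",
    catalog: FeatureCatalog | None = None,
    backbone: "bb.Backbone | None" = None,
) -> dict[str, float]:
    """One subject's feature row (clinical block plus one image arm).

    ``arm`` is ``"CR"`` or ``"DLB"``; ``analysis`` selects whether the
    peritumoral region contributes features.
    """
    if not validate_roi(study.intratumoral_mask):
        raise ValueError(
            f"{study.subject_id}: tumor ROI below the 64-voxel inclusion bound"
        )
    maps = compute_kinetic_maps(study)
    rois = build_peritumoral_ring(study.intratumoral_mask, study.spacing)
    row: dict[str, float] = dict(study.clinical.encode())
    regions = ("intratumoral",) if analysis == "intra_only" else ("intratumoral", "peritumoral")
    if arm == "CR":
        cat = catalog or default_catalog(analysis)
        row.update(extract_cr_vector(study, maps, rois, cat))
    elif arm == "DLB":
        if backbone is None:
            raise ValueError("the DLB arm needs a backbone")
        for region in regions:
            row.update(bb.extract_dlb_vector(maps, rois.region(region), backbone,
                                             region_kind=region))
    else:
        raise ValueError(f"unknown arm {arm!r}")
    bad = [k for k, v in row.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"{study.subject_id}: non-finite features {bad[:5]}")
    return row


def build_feature_table(
    studies: list[DCEStudy],
    arm: str,
    analysis: str = "intra_peri",
    catalog: FeatureCatalog | None = None,
    backbone: "bb.Backbone | None" = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table and label vector for a list of subjects."""
    if arm == "CR" and catalog is None:
        catalog = default_catalog(analysis)
    rows = {
        s.subject_id: extract_study_features(s, arm, analysis, catalog, backbone)
        for s in studies
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    name_sets = {frozenset(r) for r in rows.values()}
    if len(name_sets) > 1:
        raise ValueError("inconsistent feature name sets across subjects")
    labels = pd.Series({s.subject_id: int(s.label) for s in studies}, name="label")
    return table, labels.loc[table.index]
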