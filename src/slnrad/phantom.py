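"""Synthetic two-resolution DCE-MRI phantom cohorts with planted class signal.

Real cohorts for this problem are private, so tests and demonstrations run
on phantoms that emulate the study conditions: a 5-phase DCE series per
subject (one pre-contrast, four post-contrast), an ellipsoidal tumor mask,
~1:2 positive:negative class imbalance, a main in-plane resolution of
0.7 mm for the train/validation subjects and 0.78 mm for an independent
test subset, 2 mm slices, and clinical covariates.

Class signal is planted through recoverable mechanisms:

* kinetic contrast — positive subjects draw a higher wash-out fraction
  (standardized mean difference ``effect_sizes["washout_mean"]``) and a more
  heterogeneous enhancement texture (``"texture_heterogeneity"``);
* clinical covariates — lymphovascular invasion and tumor grade are shifted
  on the log-odds / latent scale by ``clinical_effects``.

Setting every effect to zero yields a null cohort in which the label is
independent of everything downstream.

Voxelwise enhancement follows a piecewise-linear five-point curve: baseline
``S0 = b``, rapid rise to ``S1 = b (1 + a)``, then linear wash-out to
``S4 = S1 (1 - w)``; ``a`` is modulated inside the tumor by a smoothed
Gaussian texture field so texture features are non-degenerate.  Noise is
additive Gaussian with SD a configurable fraction of baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "ClinicalRecord",
    "DCEStudy",
    "GroundTruthManifest",
    "TumorLatents",
    "generate_cohort",
    "make_tumor_phantom",
    "split_cohort",
    "CLINICAL_FEATURE_NAMES",
]

MOLECULAR_SUBTYPES = ("LuminalA", "LuminalB", "HER2", "TripleNegative")
PATHOLOGICAL_TYPES = ("IDC", "ILC")

CLINICAL_FEATURE_NAMES = (
    "clinical:upper_inner_quadrant",
    "clinical:multifocality",
    "clinical:age",
    "clinical:tumor_grade",
    "clinical:lymphovascular_invasion",
    "clinical:molecular_subtype_LuminalA",
    "clinical:molecular_subtype_LuminalB",
    "clinical:molecular_subtype_HER2",
    "clinical:molecular_subtype_TripleNegative",
    "clinical:pathological_type_IDC",
    "clinical:pathological_type_ILC",
)


@dataclass(frozen=True)
class ClinicalRecord:
    upper_inner_quadrant: bool
    multifocality: bool
    age: float
    pathological_type: str
    tumor_grade: int
    molecular_subtype: str
    lymphovascular_invasion: bool

    def encode(self) -> dict[str, float]:
        """The 11-number clinical vector: 5 fields as-is plus one-hot
        molecular subtype (4) and pathological type (2)."""
        vec = {
            "clinical:upper_inner_quadrant": float(self.upper_inner_quadrant),
            "clinical:multifocality": float(self.multifocality),
            "clinical:age": float(self.age),
            "clinical:tumor_grade": float(self.tumor_grade),
            "clinical:lymphovascular_invasion": float(self.lymphovascular_invasion),
        }
        for s in MOLECULAR_SUBTYPES:
            vec[f"clinical:molecular_subtype_{s}"] = float(self.molecular_subtype == s)
        for t in PATHOLOGICAL_TYPES:
            vec[f"clinical:pathological_type_{t}"] = float(self.pathological_type == t)
        return vec


@dataclass
class DCEStudy:
    """One subject: five co-registered phase volumes plus mask and metadata."""

    phases: list[np.ndarray]
    spacing: tuple[float, float, float]
    intratumoral_mask: np.ndarray
    label: bool
    clinical: ClinicalRecord
    subject_id: str

    def __post_init__(self) -> None:
        if len(self.phases) != 5:
            raise ValueError(f"a DCE study needs exactly 5 phases, got {len(self.phases)}")
        shapes = {p.shape for p in self.phases}
        if len(shapes) != 1:
            raise ValueError("phase volumes have mismatched shapes")
        if self.intratumoral_mask.shape != self.phases[0].shape:
            raise ValueError("mask grid does not match the phase grid")
        if not self.intratumoral_mask.any():
            raise ValueError("empty intratumoral mask")


@dataclass(frozen=True)
class TumorLatents:
    """Per-subject kinetic and geometric parameters."""

    baseline: float          # pre-contrast signal level (arbitrary MR units)
    uptake: float            # fractional enhancement a: S1 = S0 (1 + a)
    washout: float           # fractional wash-out w: S4 = S1 (1 - w)
    heterogeneity: float     # texture modulation depth of the uptake field
    radii_mm: tuple[float, float, float]
    noise_frac: float        # noise SD as a fraction of baseline


@dataclass
class GroundTruthManifest:
    subjects: dict[str, dict]
    planted_mechanisms: list[str]
    clinical_associations: dict[str, float]
    seed: int


@dataclass(frozen=True)
class PhantomConfig:
    n_train: int = 109
    n_val: int = 54
    n_test: int = 35
    positive_fraction: float = 0.34          # ~67/198
    inplane_res_main: float = 0.7            # mm
    inplane_res_test: float = 0.78           # mm
    slice_thickness: float = 2.0             # mm
    grid_shape: tuple[int, int, int] = (56, 56, 10)
    effect_sizes: dict[str, float] = field(default_factory=lambda: {
        "washout_mean": 1.2,            # standardized mean difference
        "texture_heterogeneity": 1.0,   # standardized mean difference
    })
    clinical_effects: dict[str, float] = field(default_factory=lambda: {
        "lymphovascular_invasion": 2.2,  # log-odds shift for positives
        "tumor_grade": 0.9,              # latent-scale shift for positives
    })
    noise_frac: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) <= 0:
            raise ValueError("all cohort counts must be positive")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if min(self.inplane_res_main, self.inplane_res_test, self.slice_thickness) <= 0:
            raise ValueError("resolutions must be positive")


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float = 1.5) -> np.ndarray:
    """Smoothed unit-SD Gaussian noise field."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_tumor_phantom(
    latents: TumorLatents,
    grid: tuple[int, int, int],
    spacing: tuple[float, float, float],
    seed: int,
    min_voxels: int = 64,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Build the five phase volumes and the tumor mask for one subject.

    Returns ``(phases, mask)``; attach label/clinical via :class:`DCEStudy`.
    Raises if the grid cannot hold a tumor of ``min_voxels`` voxels.
    """
    rng = np.random.default_rng(seed)
    grid = tuple(grid)
    b = latents.baseline

    # ellipsoidal mask around the (jittered) grid center
    center = np.array(grid) / 2.0 - 0.5 + rng.uniform(-1.0, 1.0, size=3)
    coords = np.indices(grid, dtype=np.float64)
    radii_vox = np.array(latents.radii_mm) / np.array(spacing)
    dist2 = sum(
        ((coords[ax] - center[ax]) / radii_vox[ax]) ** 2 for ax in range(3)
    )
    mask = dist2 <= 1.0
    if int(mask.sum()) < min_voxels:
        raise ValueError(
            f"grid {grid} at spacing {spacing} cannot hold a "
            f">={min_voxels}-voxel tumor with radii {latents.radii_mm} mm"
        )

    # textured uptake field inside the tumor; mild smooth background uptake
    tex = _smooth_field(rng, grid)
    tex_bg = _smooth_field(rng, grid, sigma=3.0)
    uptake = np.where(
        mask,
        latents.uptake * np.clip(1.0 + latents.heterogeneity * tex, 0.05, None),
        0.08 * np.clip(1.0 + 0.3 * tex_bg, 0.2, None),
    )
    washout = np.where(
        mask,
        latents.washout * np.clip(1.0 + 0.5 * latents.heterogeneity * tex, 0.05, None)
        if latents.washout != 0 else 0.0,
        0.05,
    )

    s0 = np.full(grid, b)
    s1 = s0 * (1.0 + uptake)
    phases_clean = [s0, s1]
    for t in (2, 3):  # linear wash-out from S1 toward S4
        phases_clean.append(s1 * (1.0 - washout * (t - 1) / 3.0))
    phases_clean.append(s1 * (1.0 - washout))

    noise_sd = latents.noise_frac * b
    phases = [
        (p + rng.normal(0.0, noise_sd, size=grid)).astype(np.float32)
        for p in phases_clean
    ]
    return phases, mask


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_clinical(rng: np.random.Generator, label: bool,
                   effects: dict[str, float]) -> ClinicalRecord:
    e_lvi = effects.get("lymphovascular_invasion", 0.0)
    e_grade = effects.get("tumor_grade", 0.0)
    base_logit = np.log(0.15 / 0.85)
    p_lvi = 1.0 / (1.0 + np.exp(-(base_logit + e_lvi * label)))
    latent_grade = rng.normal(e_grade * label, 1.0)
    grade = 1 + int(latent_grade > -0.67) + int(latent_grade > 0.67)
    return ClinicalRecord(
        upper_inner_quadrant=bool(rng.random() < 0.10),
        multifocality=bool(rng.random() < 0.20),
        age=float(rng.normal(55.0, 10.0)),
        pathological_type=str(rng.choice(PATHOLOGICAL_TYPES, p=[0.8, 0.2])),
        tumor_grade=grade,
        molecular_subtype=str(rng.choice(MOLECULAR_SUBTYPES, p=[0.4, 0.3, 0.15, 0.15])),
        lymphovascular_invasion=bool(rng.random() < p_lvi),
    )


def _draw_latents(rng: np.random.Generator, label: bool,
                  effects: dict[str, float], noise_frac: float) -> TumorLatents:
    d_w = effects.get("washout_mean", 0.0)
    d_h = effects.get("texture_heterogeneity", 0.0)
    washout = rng.normal(0.18 + d_w * 0.08 * label, 0.08)
    heterogeneity = rng.normal(0.20 + d_h * 0.07 * label, 0.07)
    return TumorLatents(
        baseline=float(rng.uniform(400.0, 600.0)),
        uptake=float(np.clip(rng.normal(1.8, 0.3), 0.5, None)),
        washout=float(np.clip(washout, -0.10, 0.48)),
        heterogeneity=float(np.clip(heterogeneity, 0.02, None)),
        radii_mm=(
            float(rng.uniform(4.5, 6.5)),
            float(rng.uniform(4.5, 6.5)),
            float(rng.uniform(2.4, 3.6)),
        ),
        noise_frac=noise_frac,
    )


def generate_cohort(config: PhantomConfig) -> tuple[list[DCEStudy], GroundTruthManifest]:
    """Generate the full two-resolution phantom cohort.

    The first ``n_train + n_val`` subjects are at the main in-plane
    resolution; the final ``n_test`` are at the test resolution.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_train + config.n_val + config.n_test
    studies: list[DCEStudy] = []
    manifest_subjects: dict[str, dict] = {}
    for i in range(n_total):
        is_test = i >= config.n_train + config.n_val
        res = config.inplane_res_test if is_test else config.inplane_res_main
        spacing = (res, res, config.slice_thickness)
        label = bool(rng.random() < config.positive_fraction)
        latents = _draw_latents(rng, label, config.effect_sizes, config.noise_frac)
        clinical = _draw_clinical(rng, label, config.clinical_effects)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        phases, mask = make_tumor_phantom(latents, config.grid_shape, spacing,
                                          seed=subject_seed)
        sid = f"sub-{i:04d}"
        studies.append(DCEStudy(
            phases=phases, spacing=spacing, intratumoral_mask=mask,
            label=label, clinical=clinical, subject_id=sid,
        ))
        manifest_subjects[sid] = {
            "label": label,
            "latents": latents,
            "spacing": spacing,
            "phantom_seed": subject_seed,
        }
    planted = [k for k, v in config.effect_sizes.items() if v != 0]
    planted += [k for k, v in config.clinical_effects.items() if v != 0]
    manifest = GroundTruthManifest(
        subjects=manifest_subjects,
        planted_mechanisms=planted,
        clinical_associations=dict(config.clinical_effects),
        seed=config.seed,
    )
    return studies, manifest


def split_cohort(
    cohort: list[DCEStudy],
    config: PhantomConfig,
    train_fraction: float | None = None,
) -> tuple[list[DCEStudy], list[DCEStudy], list[DCEStudy]]:
    """Partition a cohort into train / validation / test.

    The test split is exactly the subjects at the test in-plane resolution;
    the remaining subjects are randomly partitioned (seeded by
    ``config.seed``) into train and validation at the configured ratio.
    """
    test = [s for s in cohort if s.spacing[0] == config.inplane_res_test]
    main = [s for s in cohort if s.spacing[0] != config.inplane_res_test]
    if not test:
        raise ValueError("no subjects at the test resolution: empty test split")
    if not main:
        raise ValueError("no subjects at the main resolution")
    frac = (
        train_fraction
        if train_fraction is not None
        else config.n_train / (config.n_train + config.n_val)
    )
    n_tr = int(round(frac * len(main)))
    if n_tr == 0 or n_tr == len(main):
        raise ValueError("degenerate train/validation split")
    order = np.random.default_rng(config.seed).permutation(len(main))
    train = [main[i] for i in sorted(order[:n_tr])]
    val = [main[i] for i in sorted(order[n_tr:])]
    return train, val, test
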