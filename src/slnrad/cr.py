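"""Conventional radiomics: shape, first-order, texture-matrix and Laws features.

All texture families operate on grey-level volumes quantized after absolute
resampling (see :mod:`slnrad.kinetics`), so a grey level has the same
physical meaning for every subject.  Matrix conventions:

* GLCM / GLRLM aggregate over the 13 unique 3D directions at distance 1;
  co-occurrences are symmetric and only in-ROI voxel pairs count.
* NGLDM uses 26-connected in-ROI neighborhoods (Amadasun-style grey-level
  difference vector).
* GLZLM zones are 26-connected components of equal grey level within the ROI.
* Grey levels are weighted 1-based inside matrix statistics (level 0 becomes
  grey value 1) so low-grey-level emphases stay finite.
* Laws features are 2D per slice: the 25 outer products of the five 5-tap
  kernels (L5, E5, S5, W5, R5), numbered row-major 1..25 in that order,
  convolved zero-padded at native size; responses are pooled over all in-ROI
  pixels of all slices before taking the Energy (mean square) and Skewness
  statistics.

Shape features are geometric only and defined for the intratumoral region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .kinetics import (DEFAULT_WINDOWS, KineticMapSet, QuantizationSpec,
                       apply_window, quantize)
from .regions import ROIPair

__all__ = [
    "FeatureDef",
    "FeatureCatalog",
    "default_catalog",
    "extract_shape",
    "extract_first_order",
    "extract_glcm",
    "extract_ngldm",
    "extract_glrlm",
    "extract_glzlm",
    "extract_laws",
    "extract_cr_vector",
    "LAWS_KERNELS",
    "laws_filter_bank",
]

EPS = 1e-6  # guards zero-sum denominators (e.g. NGLDM coarseness on constants)

# The 13 unique 3D directions at distance 1 (first nonzero component positive).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def extract_shape(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """Geometric descriptors of a binary tumor mask.

    volume (mm^3), surface area (mm^2, exposed-face counting), extent
    (volume / bounding-box volume), sphericity and its reciprocal compacity.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("shape features need a nonempty mask")
    sx, sy, sz = spacing
    voxel_vol = sx * sy * sz
    volume = n * voxel_vol

    # exposed faces per axis: mask voxel whose neighbor along the axis is
    # outside the mask (or outside the volume)
    face_areas = (sy * sz, sx * sz, sx * sy)
    surface = 0.0
    for axis, a in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        lo = np.take(padded, range(0, mask.shape[axis]), axis=axis)
        hi = np.take(padded, range(2, mask.shape[axis] + 2), axis=axis)
        surface += a * float(np.sum(mask & ~lo) + np.sum(mask & ~hi))

    idx = np.nonzero(mask)
    bbox_vol = voxel_vol
    for ax in range(3):
        bbox_vol *= int(idx[ax].max() - idx[ax].min() + 1)
    extent = volume / bbox_vol

    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface
    return {
        "volume": volume,
        "surface_area": surface,
        "extent": extent,
        "sphericity": sphericity,
        "compacity": 1.0 / sphericity,
    }


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def _roi_levels(quantized: np.ndarray, roi: np.ndarray) -> np.ndarray:
    vals = np.asarray(quantized)[np.asarray(roi, dtype=bool)]
    return vals[vals >= 0]  # drop invalid voxels (coded -1)


def extract_first_order(quantized: np.ndarray, roi: np.ndarray) -> dict[str, float]:
    """Histogram statistics of the in-ROI grey levels."""
    vals = _roi_levels(quantized, roi).astype(np.float64)
    if vals.size < 2:
        raise ValueError("first-order statistics need >= 2 valid ROI voxels")
    var = float(np.var(vals))
    if var > 0:
        skew = float(sps.skew(vals, bias=True))
        kurt = float(sps.kurtosis(vals, bias=True, fisher=True))
    else:
        skew = kurt = 0.0
    counts = np.bincount(vals.astype(np.int64))
    p = counts[counts > 0] / vals.size
    return {
        "mean": float(np.mean(vals)),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy_log2": float(-np.sum(p * np.log2(p))),
        "energy": float(np.sum(p ** 2)),
    }


# ---------------------------------------------------------------------------
# helpers shared by matrix families
# ---------------------------------------------------------------------------

def _bbox(roi: np.ndarray, margin: int = 0) -> tuple[slice, slice, slice]:
    idx = np.nonzero(roi)
    return tuple(
        slice(max(int(i.min()) - margin, 0), int(i.max()) + 1 + margin)
        for i in idx
    )


def _shifted(arr: np.ndarray, d: tuple[int, int, int], fill) -> np.ndarray:
    """Array whose value at p is arr[p + d], out-of-bounds filled."""
    out = np.full_like(arr, fill)
    src = tuple(slice(max(di, 0), arr.shape[ax] + min(di, 0)) for ax, di in enumerate(d))
    dst = tuple(slice(max(-di, 0), arr.shape[ax] + min(-di, 0)) for ax, di in enumerate(d))
    out[dst] = arr[src]
    return out


def _masked_levels(quantized: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Grey-level array with out-of-ROI / invalid voxels coded -1, on the ROI bbox."""
    roi = np.asarray(roi, dtype=bool)
    box = _bbox(roi)
    lev = np.where(roi[box], np.asarray(quantized)[box], -1)
    return lev.astype(np.int64)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(quantized: np.ndarray, roi: np.ndarray, distance: int = 1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix over the 13 3D directions."""
    lev = _masked_levels(quantized, roi)
    n_levels = int(lev.max()) + 1
    if n_levels <= 0:
        raise ValueError("no valid ROI voxels")
    mat = np.zeros((n_levels, n_levels), dtype=np.float64)
    for d in DIRECTIONS_13:
        dd = tuple(distance * c for c in d)
        nb = _shifted(lev, dd, -1)
        ok = (lev >= 0) & (nb >= 0)
        if not ok.any():
            continue
        np.add.at(mat, (lev[ok], nb[ok]), 1.0)
    mat = mat + mat.T  # symmetric accumulation
    total = mat.sum()
    if total == 0:
        raise ValueError("no in-ROI voxel pairs for GLCM")
    return mat / total


def extract_glcm(quantized: np.ndarray, roi: np.ndarray, distance: int = 1) -> dict[str, float]:
    p = glcm_matrix(quantized, roi, distance)
    i = np.arange(1, p.shape[0] + 1, dtype=np.float64)  # 1-based grey values
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    energy = float(np.sum(p ** 2))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    dissimilarity = float(np.sum(np.abs(ii - jj) * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum((ii - mu_i) ** 2 * p))
    var_j = float(np.sum((jj - mu_j) ** 2 * p))
    if var_i > 0 and var_j > 0:
        correlation = float(np.sum((ii - mu_i) * (jj - mu_j) * p) / np.sqrt(var_i * var_j))
    else:
        correlation = 1.0  # degenerate single-level matrix
    return {
        "entropy_log2": entropy,
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "homogeneity": homogeneity,
        "dissimilarity": dissimilarity,
    }


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_vectors(quantized: np.ndarray, roi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occupancy probabilities ``p_i`` and difference sums ``s_i``.

    ``s_i`` accumulates |level - mean(26-neighborhood levels)| over ROI voxels
    of level ``i`` that have at least one in-ROI neighbor.
    """
    lev = _masked_levels(quantized, roi)
    n_levels = int(lev.max()) + 1
    valid = lev >= 0
    vals = np.where(valid, lev, 0).astype(np.float64)
    w = _STRUCT_26.astype(np.float64).copy()
    w[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(vals, w, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(valid.astype(np.float64), w, mode="constant", cval=0.0)
    has_nb = valid & (nb_cnt > 0)
    if not has_nb.any():
        raise ValueError("no ROI voxel has an in-ROI neighbor")
    diff = np.abs(lev[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    levels_here = lev[has_nb]
    s = np.zeros(n_levels)
    np.add.at(s, levels_here, diff)
    counts = np.bincount(levels_here, minlength=n_levels).astype(np.float64)
    p = counts / counts.sum()
    return p, s


def extract_ngldm(quantized: np.ndarray, roi: np.ndarray) -> dict[str, float]:
    p, s = ngldm_vectors(quantized, roi)
    n = float(np.sum(p > 0))  # number of occupied levels
    n_vox = float((_masked_levels(quantized, roi) >= 0).sum())
    grey = np.arange(1, p.size + 1, dtype=np.float64)
    coarseness = 1.0 / (EPS + float(np.sum(p * s)))
    if n > 1:
        occ = p > 0
        pi = p[occ][:, None]
        pj = p[occ][None, :]
        gi = grey[occ][:, None]
        gj = grey[occ][None, :]
        contrast = (float(np.sum(pi * pj * (gi - gj) ** 2)) / (n * (n - 1))) * \
            (float(s.sum()) / n_vox)
        busy_den = float(np.sum(np.abs(gi * pi - gj * pj)))
        busyness = float(np.sum(p * s)) / busy_den if busy_den > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(quantized: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Run-length matrix summed over the 13 directions; runs confined to ROI.

    Entry [i, l-1] counts maximal runs of grey level i and length l.
    """
    lev = _masked_levels(quantized, roi)
    n_levels = int(lev.max()) + 1
    max_len = max(lev.shape)
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    valid = lev >= 0
    for d in DIRECTIONS_13:
        nxt = _shifted(lev, d, -1)
        same_next = valid & (nxt >= 0) & (lev == nxt)
        # run length via DP: L[p] = 1 + L[p+d] if continuing, else 1
        L = np.ones(lev.shape, dtype=np.int64)
        for _ in range(max_len - 1):
            L_next = _shifted(L, d, 0)
            new = np.where(same_next, 1 + L_next, 1)
            if np.array_equal(new, L):
                break
            L = new
        prv = _shifted(lev, tuple(-c for c in d), -1)
        start = valid & ~((prv >= 0) & (prv == lev))
        np.add.at(mat, (lev[start], L[start] - 1), 1.0)
    return mat


def extract_glrlm(quantized: np.ndarray, roi: np.ndarray) -> dict[str, float]:
    mat = glrlm_matrix(quantized, roi)
    n_runs = mat.sum()
    if n_runs == 0:
        raise ValueError("empty GLRLM")
    lengths = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    n_vox = float((_masked_levels(quantized, roi) >= 0).sum())
    return {
        "sre": float(np.sum(mat / lengths[None, :] ** 2) / n_runs),
        "lre": float(np.sum(mat * lengths[None, :] ** 2) / n_runs),
        "glnu": float(np.sum(mat.sum(axis=1) ** 2) / n_runs),
        "rlnu": float(np.sum(mat.sum(axis=0) ** 2) / n_runs),
        "rp": float(n_runs / (n_vox * len(DIRECTIONS_13))),
    }


# ---------------------------------------------------------------------------
# GLZLM
# ---------------------------------------------------------------------------

def glzlm_matrix(quantized: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Zone matrix: 26-connected equal-level components within the ROI.

    Entry [i, s-1] counts zones of grey level i and size s.
    """
    lev = _masked_levels(quantized, roi)
    n_levels = int(lev.max()) + 1
    if n_levels <= 0:
        raise ValueError("no valid ROI voxels")
    zones: list[tuple[int, int]] = []
    for g in np.unique(lev[lev >= 0]):
        labels, n = ndimage.label(lev == g, structure=_STRUCT_26)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            zones.extend((int(g), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, s in zones:
        mat[g, s - 1] += 1.0
    return mat


def extract_glzlm(quantized: np.ndarray, roi: np.ndarray) -> dict[str, float]:
    mat = glzlm_matrix(quantized, roi)
    n_zones = mat.sum()
    sizes = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    grey = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    n_vox = float((_masked_levels(quantized, roi) >= 0).sum())
    return {
        "sze": float(np.sum(mat / sizes[None, :] ** 2) / n_zones),
        "lze": float(np.sum(mat * sizes[None, :] ** 2) / n_zones),
        "zp": float(n_zones / n_vox),
        "lzlge": float(np.sum(mat * sizes[None, :] ** 2 / grey[:, None] ** 2) / n_zones),
    }


# ---------------------------------------------------------------------------
# Laws
# ---------------------------------------------------------------------------

LAWS_KERNELS: dict[str, np.ndarray] = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
_LAWS_ORDER = ("L5", "E5", "S5", "W5", "R5")


def laws_filter_bank() -> list[np.ndarray]:
    """The 25 2D Laws filters, numbered 1..25 row-major over (L5,E5,S5,W5,R5)."""
    return [
        np.outer(LAWS_KERNELS[a], LAWS_KERNELS[b])
        for a in _LAWS_ORDER
        for b in _LAWS_ORDER
    ]


def extract_laws(
    percent_map: np.ndarray,
    roi: np.ndarray,
    filters: tuple[int, ...] | None = None,
) -> dict[str, float]:
    """Laws texture statistics on a windowed (unquantized) percent map.

    Each filter is applied slice-by-slice (2D, same-size, zero-padded);
    responses at in-ROI pixels of every slice are pooled into one sample per
    filter, from which ``laws_energy_k`` (mean squared response) and
    ``laws_skewness_k`` are taken.  ``filters`` restricts to a subset of the
    filter numbers 1..25 (default: all 25).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI for Laws features")
    arr = np.asarray(percent_map, dtype=np.float64)
    arr = np.where(np.isfinite(arr), arr, 0.0)
    bank = laws_filter_bank()
    wanted = tuple(range(1, 26)) if filters is None else tuple(filters)
    box = _bbox(roi, margin=4)
    arr = arr[box]
    roi_b = roi[box]
    z_slices = [z for z in range(roi_b.shape[2]) if roi_b[:, :, z].any()]
    out: dict[str, float] = {}
    for k in wanted:
        kernel = bank[k - 1]
        responses = []
        for z in z_slices:
            resp = ndimage.convolve(arr[:, :, z], kernel, mode="constant", cval=0.0)
            responses.append(resp[roi_b[:, :, z]])
        pooled = np.concatenate(responses)
        out[f"laws_energy_{k}"] = float(np.mean(pooled ** 2))
        sk = sps.skew(pooled, bias=True) if np.var(pooled) > 0 else 0.0
        out[f"laws_skewness_{k}"] = float(sk)
    return out


# ---------------------------------------------------------------------------
# catalog + subject-level extraction
# ---------------------------------------------------------------------------

_FAMILY_STATS = {
    "first_order": ("mean", "variance", "skewness", "kurtosis", "entropy_log2", "energy"),
    "glcm": ("entropy_log2", "energy", "contrast", "correlation", "homogeneity", "dissimilarity"),
    "ngldm": ("coarseness", "contrast", "busyness"),
    "glrlm": ("sre", "lre", "glnu", "rlnu", "rp"),
    "glzlm": ("sze", "lze", "zp", "lzlge"),
}
_SHAPE_STATS = ("volume", "surface_area", "extent", "sphericity", "compacity")

# Pinned Laws filter numbers per (map, region); see module docstring for the
# numbering convention.  Chosen so the default catalog has 93 intratumoral
# and 146 total features, matching the published model-input counts, while
# covering every Laws feature named in the published selected-feature tables.
_DEFAULT_LAWS_FILTERS = {
    ("wash_in", "intratumoral"): (1, 5, 9),
    ("wash_out", "intratumoral"): (7, 13),
    ("ser", "intratumoral"): (4, 8, 19),
    ("wash_in", "peritumoral"): (9,),
    ("wash_out", "peritumoral"): (7,),
    ("ser", "peritumoral"): (4, 8),
}
_PERITUMORAL_FAMILIES = ("first_order", "glcm", "ngldm")
_INTRATUMORAL_FAMILIES = ("first_order", "glcm", "ngldm", "glrlm", "glzlm")


@dataclass(frozen=True)
class FeatureDef:
    family: str       # shape | first_order | glcm | ngldm | glrlm | glzlm | laws
    statistic: str    # family statistic, e.g. "entropy_log2" or "laws_energy_8"
    map_kind: str     # wash_in | wash_out | ser | "" for shape
    region: str       # intratumoral | peritumoral

    @property
    def name(self) -> str:
        mk = self.map_kind or "shape"
        return f"CR:{self.region}:{mk}:{self.statistic}"


@dataclass
class FeatureCatalog:
    """Ordered, fixed-per-run list of conventional-radiomics feature definitions."""

    definitions: list[FeatureDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalog")
        for d in self.definitions:
            if d.family == "shape" and d.region != "intratumoral":
                raise ValueError("shape features are intratumoral-only")

    def __len__(self) -> int:
        return len(self.definitions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def regions(self) -> set[str]:
        return {d.region for d in self.definitions}

    def to_json(self) -> str:
        import json

        return json.dumps([vars(d) for d in self.definitions], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FeatureCatalog":
        import json

        return cls([FeatureDef(**d) for d in json.loads(text)])


def default_catalog(analysis: str = "intra_peri") -> FeatureCatalog:
    """The pinned default feature catalog.

    ``analysis="intra_only"`` yields 93 features; ``"intra_peri"`` yields 146
    (93 intratumoral + 53 peritumoral), the model-input counts of the two
    published analyses.
    """
    defs: list[FeatureDef] = []
    for stat in _SHAPE_STATS:
        defs.append(FeatureDef("shape", stat, "", "intratumoral"))
    regions = ("intratumoral",) if analysis == "intra_only" else ("intratumoral", "peritumoral")
    if analysis not in ("intra_only", "intra_peri"):
        raise ValueError(f"unknown analysis {analysis!r}")
    for region in regions:
        families = _INTRATUMORAL_FAMILIES if region == "intratumoral" else _PERITUMORAL_FAMILIES
        for map_kind in ("wash_in", "wash_out", "ser"):
            for fam in families:
                for stat in _FAMILY_STATS[fam]:
                    defs.append(FeatureDef(fam, f"{fam}_{stat}", map_kind, region))
            for k in _DEFAULT_LAWS_FILTERS[(map_kind, region)]:
                defs.append(FeatureDef("laws", f"laws_energy_{k}", map_kind, region))
                defs.append(FeatureDef("laws", f"laws_skewness_{k}", map_kind, region))
    return FeatureCatalog(defs)


def extract_cr_vector(
    study,
    maps: KineticMapSet,
    rois: ROIPair,
    catalog: FeatureCatalog,
    levels: int = 128,
) -> dict[str, float]:
    """One subject's conventional-radiomics row, keyed by canonical names.

    Each (map, region) pair is windowed with its own absolute-resampling
    window and quantized to ``levels`` grey levels before matrix features;
    Laws features see the windowed, unquantized map.
    """
    out: dict[str, float] = {}
    needed = {(d.map_kind, d.region) for d in catalog.definitions if d.family != "shape"}
    windowed: dict[tuple[str, str], np.ndarray] = {}
    quantized: dict[tuple[str, str], np.ndarray] = {}
    for map_kind, region in needed:
        window = DEFAULT_WINDOWS[(map_kind, region)]
        wm = apply_window(maps.by_kind(map_kind), window)
        windowed[(map_kind, region)] = wm
        quantized[(map_kind, region)] = quantize(wm, QuantizationSpec(window, levels))

    family_cache: dict[tuple[str, str, str], dict[str, float]] = {}

    def family_values(fam: str, map_kind: str, region: str) -> dict[str, float]:
        key = (fam, map_kind, region)
        if key in family_cache:
            return family_cache[key]
        roi = rois.region(region)
        try:
            if fam == "shape":
                vals = extract_shape(rois.intratumoral, rois.spacing)
            elif fam == "first_order":
                vals = extract_first_order(quantized[(map_kind, region)], roi)
            elif fam == "glcm":
                vals = extract_glcm(quantized[(map_kind, region)], roi)
            elif fam == "ngldm":
                vals = extract_ngldm(quantized[(map_kind, region)], roi)
            elif fam == "glrlm":
                vals = extract_glrlm(quantized[(map_kind, region)], roi)
            elif fam == "glzlm":
                vals = extract_glzlm(quantized[(map_kind, region)], roi)
            elif fam == "laws":
                ks = tuple(
                    int(d.statistic.rsplit("_", 1)[1])
                    for d in catalog.definitions
                    if d.family == "laws" and d.map_kind == map_kind and d.region == region
                )
                vals = extract_laws(windowed[(map_kind, region)], roi, filters=tuple(sorted(set(ks))))
            else:
                raise ValueError(f"unknown feature family {fam!r}")
        except ValueError as exc:
            raise ValueError(
                f"feature extraction failed for family={fam} map={map_kind or '-'} "
                f"region={region}: {exc}"
            ) from exc
        family_cache[key] = vals
        return vals

    for d in catalog.definitions:
        vals = family_values(d.family, d.map_kind, d.region)
        stat = d.statistic
        if d.family not in ("shape", "laws") and stat.startswith(d.family + "_"):
            stat = stat[len(d.family) + 1:]
        out[d.name] = vals[stat]
    return out
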