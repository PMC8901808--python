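"""Contrast-kinetics ratio maps from a 5-phase DCE-MRI series.

Three ratio maps summarize the enhancement curve of each voxel using the
pre-contrast phase ``S0``, the first post-contrast phase ``S1`` and the last
post-contrast phase ``S4``::

    wash_in  = 100 * (S1 - S0) / S0
    wash_out = 100 * (S1 - S4) / S1
    ser      = 100 * (S1 - S0) / (S4 - S0)      (signal enhancement ratio)

Being ratios, the maps are independent of the scanner's arbitrary signal
scale.  Voxels where any denominator vanishes are recorded in a validity
mask and excluded from downstream region statistics rather than imputed.

Before texture analysis each map is *absolutely resampled*: clipped into a
fixed physical window (percent units, region- and map-specific) and
quantized to a fixed number of grey levels, so grey levels mean the same
thing across subjects and field strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticMapSet",
    "ResamplingWindow",
    "QuantizationSpec",
    "DEFAULT_WINDOWS",
    "compute_kinetic_maps",
    "apply_window",
    "quantize",
]

MAP_KINDS = ("wash_in", "wash_out", "ser")
REGION_KINDS = ("intratumoral", "peritumoral")


@dataclass(frozen=True)
class ResamplingWindow:
    """Fixed physical intensity window (percent) for one map/region pair."""

    map_kind: str
    region_kind: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.map_kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.map_kind!r}")
        if self.region_kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.region_kind!r}")
        if not self.lower < self.upper:
            raise ValueError("window lower bound must be < upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


#: The six default windows: intratumoral wash-in 0–640 %, wash-out −156–100 %,
#: SER −1280–1280 %; peritumoral identical except wash-out −540–100 %.
DEFAULT_WINDOWS: dict[tuple[str, str], ResamplingWindow] = {
    ("wash_in", "intratumoral"): ResamplingWindow("wash_in", "intratumoral", 0.0, 640.0),
    ("wash_out", "intratumoral"): ResamplingWindow("wash_out", "intratumoral", -156.0, 100.0),
    ("ser", "intratumoral"): ResamplingWindow("ser", "intratumoral", -1280.0, 1280.0),
    ("wash_in", "peritumoral"): ResamplingWindow("wash_in", "peritumoral", 0.0, 640.0),
    ("wash_out", "peritumoral"): ResamplingWindow("wash_out", "peritumoral", -540.0, 100.0),
    ("ser", "peritumoral"): ResamplingWindow("ser", "peritumoral", -1280.0, 1280.0),
}


@dataclass(frozen=True)
class QuantizationSpec:
    """Grey-level quantization of a windowed map (default 128 levels)."""

    window: ResamplingWindow
    levels: int = 128

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("quantization needs at least 2 grey levels")


@dataclass
class KineticMapSet:
    """The three kinetic maps plus the mask of voxels where all are defined.

    Values outside ``valid_mask`` are NaN, never silently zero.
    """

    wash_in: np.ndarray
    wash_out: np.ndarray
    ser: np.ndarray
    valid_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shapes = {self.wash_in.shape, self.wash_out.shape, self.ser.shape,
                  self.valid_mask.shape}
        if len(shapes) != 1:
            raise ValueError("kinetic maps must share one grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.wash_in.shape

    def by_kind(self, kind: str) -> np.ndarray:
        if kind not in MAP_KINDS:
            raise KeyError(kind)
        return getattr(self, kind)


def compute_kinetic_maps(study) -> KineticMapSet:
    """Compute wash-in, wash-out and SER maps from a 5-phase study.

    Parameters
    ----------
    study : DCEStudy
        Must carry exactly five co-registered phase volumes.

    Returns
    -------
    KineticMapSet
        Percent-valued maps; voxels with a zero denominator in *any* of the
        three formulas are NaN in the affected map(s) and excluded from
        ``valid_mask``.
    """
    phases = study.phases
    if len(phases) != 5:
        raise ValueError(f"expected 5 phases, got {len(phases)}")
    shapes = {p.shape for p in phases}
    if len(shapes) != 1:
        raise ValueError("phase volumes have mismatched shapes")

    s0 = np.asarray(phases[0], dtype=np.float64)
    s1 = np.asarray(phases[1], dtype=np.float64)
    s4 = np.asarray(phases[4], dtype=np.float64)

    d_wi = s0
    d_wo = s1
    d_ser = s4 - s0
    ok_wi = d_wi != 0
    ok_wo = d_wo != 0
    ok_ser = d_ser != 0

    with np.errstate(divide="ignore", invalid="ignore"):
        wash_in = np.where(ok_wi, 100.0 * (s1 - s0) / d_wi, np.nan)
        wash_out = np.where(ok_wo, 100.0 * (s1 - s4) / d_wo, np.nan)
        ser = np.where(ok_ser, 100.0 * (s1 - s0) / d_ser, np.nan)

    valid = ok_wi & ok_wo & ok_ser
    return KineticMapSet(wash_in=wash_in, wash_out=wash_out, ser=ser,
                         valid_mask=valid)


def apply_window(map_values: np.ndarray, window: ResamplingWindow) -> np.ndarray:
    """Clip a percent map into its absolute-resampling window.

    NaN (invalid) voxels pass through untouched; in-window values are
    returned unchanged, so windowing is idempotent.
    """
    arr = np.asarray(map_values, dtype=np.float64)
    out = arr.copy()
    finite = np.isfinite(arr)
    out[finite] = np.clip(arr[finite], window.lower, window.upper)
    return out


def quantize(map_values: np.ndarray, spec: QuantizationSpec) -> np.ndarray:
    """Quantize a windowed percent map to integer grey levels.

    ``level(v) = min(levels-1, floor((v - lower) / (upper - lower) * levels))``
    — left-closed equal-width bins with the last bin closed at the upper
    bound.  Invalid (NaN) voxels map to -1.
    """
    if spec.levels < 2:
        raise ValueError("quantization needs at least 2 grey levels")
    w = spec.window
    arr = np.asarray(map_values, dtype=np.float64)
    finite = np.isfinite(arr)
    scaled = np.zeros_like(arr)
    scaled[finite] = (arr[finite] - w.lower) / w.width * spec.levels
    levels = np.floor(scaled).astype(np.int64)
    levels = np.minimum(levels, spec.levels - 1)
    levels = np.maximum(levels, 0)  # windowed input cannot go below, but be safe
    levels[~finite] = -1
    return levels
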