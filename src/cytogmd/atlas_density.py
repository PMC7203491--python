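"""Probability-weighted regional gray-matter-density extraction.

A cytoarchitectonic probabilistic map assigns each voxel the probability
(0-1) that it belongs to a microscopically defined brain region.  Given a
modulated voxelwise gray-matter density (GMD) volume ``g`` and per-voxel
region weights ``w``, the standardized regional density is the
probability-weighted mean pooled across both hemispheres::

    value = (sum_v g_v w_v^L + sum_v g_v w_v^R) / (sum_v w_v^L + sum_v w_v^R)

i.e. the weighted sums are pooled bilaterally *before* the division by the
total weight.  The result is bounded by the min/max of ``g`` on the union
support of the weights, is linear in ``g`` and invariant to rescaling of
the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "ProbabilisticRegionMap",
    "GrayMatterMap",
    "StandardizedDensity",
    "load_probability_map",
    "load_gray_matter_map",
    "apply_atlas_translation",
    "extract_regional_density",
    "extract_all_regions",
]


@dataclass(frozen=True)
class ProbabilisticRegionMap:
    """A single-hemisphere probabilistic region map on a voxel grid.

    ``probabilities`` are unitless in [0, 1]; ``affine`` is the 4x4
    voxel-to-mm placement matrix.
    """

    region_name: str
    hemisphere: Literal["left", "right"]
    probabilities: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 3:
            raise ValueError(f"probability map must be 3D, got {p.ndim}D")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.any(p > 0):
            raise ValueError("empty probability map")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))


@dataclass(frozen=True)
class GrayMatterMap:
    """A modulated gray-matter density volume for one scan."""

    values: np.ndarray
    affine: np.ndarray
    subject: str = ""
    session_month: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"gray matter map must be 3D, got {v.ndim}D")
        if np.any(v < 0):
            raise ValueError("gray matter density values must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))


@dataclass(frozen=True)
class StandardizedDensity:
    region_name: str
    value: float


def _load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, np.asarray(img.affine, dtype=float)


def load_probability_map(
    path: str | Path,
    region_name: str | None = None,
    hemisphere: Literal["left", "right"] = "left",
    scale_hint: Literal["unit", "percent", "auto"] = "auto",
) -> ProbabilisticRegionMap:
    """Load a probabilistic region map from a NIfTI volume.

    Atlas maps are distributed either on a 0-1 or a 0-100 (percent) scale;
    ``scale_hint="auto"`` divides by 100 whenever the maximum exceeds 1 so
    that probabilities are always stored in [0, 1].
    """
    data, affine = _load_volume(path)
    if np.any(data < 0):
        raise ValueError(f"{path}: negative values in probability map")
    if not np.any(data > 0):
        raise ValueError(f"{path}: empty probability map")
    if scale_hint == "percent" or (scale_hint == "auto" and data.max() > 1.0):
        data = data / 100.0
    if data.max() > 1.0:
        raise ValueError(f"{path}: probabilities exceed 1 after rescaling")
    name = region_name if region_name is not None else Path(path).stem
    return ProbabilisticRegionMap(name, hemisphere, data, affine)


def load_gray_matter_map(
    path: str | Path,
    subject: str = "",
    session_month: float = 0.0,
    replicate: int = 1,
) -> GrayMatterMap:
    """Load a modulated gray-matter density volume from a NIfTI file."""
    data, affine = _load_volume(path)
    if np.any(data < 0):
        raise ValueError(f"{path}: negative gray matter density values")
    return GrayMatterMap(data, affine, subject, session_month, replicate)


def apply_atlas_translation(
    region_map: ProbabilisticRegionMap, dy_mm: float, dz_mm: float
) -> ProbabilisticRegionMap:
    """Shift the map's affine placement by (0, dy, dz) millimetres.

    Atlas maps normalised to a different template convention need a rigid
    y/z offset (typically +4 mm and +5 mm) to land on the data's MNI grid;
    the voxel data are untouched, only the placement moves.
    """
    if not (np.isfinite(dy_mm) and np.isfinite(dz_mm)):
        raise ValueError("translation offsets must be finite")
    affine = region_map.affine.copy()
    affine[1, 3] += dy_mm
    affine[2, 3] += dz_mm
    return replace(region_map, affine=affine)


def _resample_nearest(
    region_map: ProbabilisticRegionMap, target_shape: tuple[int, ...], target_affine: np.ndarray
) -> np.ndarray:
    """Nearest-neighbour resampling of the map onto the target grid."""
    src_inv = np.linalg.inv(region_map.affine)
    ii, jj, kk = np.meshgrid(
        np.arange(target_shape[0]),
        np.arange(target_shape[1]),
        np.arange(target_shape[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4).T
    src_vox = src_inv @ target_affine @ vox
    idx = np.rint(src_vox[:3]).astype(int)
    shape = region_map.probabilities.shape
    inside = np.all((idx >= 0) & (idx < np.array(shape)[:, None]), axis=0)
    out = np.zeros(vox.shape[1])
    out[inside] = region_map.probabilities[idx[0, inside], idx[1, inside], idx[2, inside]]
    return out.reshape(target_shape)


def _weights_on_grid(
    region_map: ProbabilisticRegionMap, gm: GrayMatterMap, resample: bool
) -> np.ndarray:
    same_grid = region_map.probabilities.shape == gm.values.shape and np.allclose(
        region_map.affine, gm.affine
    )
    if same_grid:
        return region_map.probabilities
    if not resample:
        raise ValueError(
            f"region {region_map.region_name!r}: atlas grid "
            f"{region_map.probabilities.shape} does not match gray-matter grid "
            f"{gm.values.shape} (pass resample=True to allow nearest-neighbour "
            "resampling)"
        )
    return _resample_nearest(region_map, gm.values.shape, gm.affine)


def extract_regional_density(
    gm: GrayMatterMap,
    left: ProbabilisticRegionMap,
    right: ProbabilisticRegionMap,
    *,
    resample: bool = False,
    per_hemisphere: bool = False,
) -> StandardizedDensity | tuple[StandardizedDensity, StandardizedDensity]:
    """Standardized regional GMD: bilateral probability-weighted mean.

    The per-voxel gray-matter value is multiplied by the probabilistic
    weighting; weighted values are summed over both hemispheres and the sum
    is standardized by the total weight.  With ``per_hemisphere=True`` each
    hemisphere is standardized separately instead (non-default).
    """
    wl = _weights_on_grid(left, gm, resample)
    wr = _weights_on_grid(right, gm, resample)
    g = gm.values
    if per_hemisphere:
        out = []
        for w, m in ((wl, left), (wr, right)):
            sw = float(w.sum())
            if sw <= 0:
                raise ValueError(f"region {m.region_name!r}: zero total weight")
            out.append(StandardizedDensity(m.region_name, float((g * w).sum() / sw)))
        return tuple(out)
    total_weight = float(wl.sum() + wr.sum())
    if total_weight <= 0:
        raise ValueError(f"region {left.region_name!r}: zero total weight")
    value = float(((g * wl).sum() + (g * wr).sum()) / total_weight)
    return StandardizedDensity(left.region_name, value)


def extract_all_regions(
    gm: GrayMatterMap,
    atlas: Mapping[str, tuple[ProbabilisticRegionMap, ProbabilisticRegionMap]]
    | Iterable[tuple[ProbabilisticRegionMap, ProbabilisticRegionMap]],
    *,
    resample: bool = False,
) -> dict[str, float]:
    """Extract standardized densities for every region of an atlas.

    ``atlas`` maps region name to a (left, right) pair of probabilistic
    maps.  Returns an ordered ``{region: value}`` dict following the atlas
    iteration order.  Errors from individual regions are re-raised tagged
    with the region name.
    """
    if isinstance(atlas, Mapping):
        items = list(atlas.items())
    else:
        items = [(pair[0].region_name, pair) for pair in atlas]
    if not items:
        raise ValueError("atlas contains no regions")
    out: dict[str, float] = {}
    for name, (left, right) in items:
        try:
            sd = extract_regional_density(gm, left, right, resample=resample)
        except ValueError as err:
            raise ValueError(f"region {name!r}: {err}") from err
        assert isinstance(sd, StandardizedDensity)
        out[name] = sd.value
    return out
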