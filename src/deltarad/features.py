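"""3D radiomic texture features with fixed-bin-number quantisation.

Features are computed over a tumour ROI of a single 3D volume, in 3D
(no slice-wise aggregation), without resampling and without
re-segmentation: only voxels inside the supplied mask contribute, and
the grey-level discretisation uses a fixed number of equal-width bins
spanning the ROI's own min-max intensity range. This is the
IBSI-recommended discretisation for arbitrary-unit modalities such as
MRI.

Six feature classes are available: ``firstorder``, ``glcm``, ``glrlm``,
``glszm``, ``gldm`` and ``ngtdm``. Texture matrices are computed over
the 13 unique 3D direction offsets where directional, and directional
feature values are aggregated by averaging across directions.

Degenerate inputs follow documented conventions rather than raising:
a constant-intensity ROI quantises to a single level (level 1), and
matrix features that would divide by a zero level variance return 0.0
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "FeatureVector",
    "FEATURE_CLASSES",
    "quantise_roi",
    "extract_features",
    "perturb_mask",
    "MaskEmptiedError",
]

FEATURE_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")

#: The 13 unique direction offsets of the 26-connected 3D neighbourhood
#: (one representative per +/- pair).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

_EPS = np.finfo(float).tiny


class MaskEmptiedError(RuntimeError):
    """A morphological perturbation removed every foreground voxel."""


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing and modality metadata.

    ``acquisition_params`` carries optional named scalars (TR, TE, ...)
    used only by the acquisition-parameter screen downstream.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "T2WI"
    acquisition_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("volume must be 3D with all extents >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")


@dataclass
class FeatureVector:
    """Named feature values ('class.Name' -> scalar) plus extraction metadata."""

    values: dict[str, float]
    modality: str = ""
    time_point: str = ""
    n_bins: int = 0

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self, order: Iterable[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.names()
        return np.array([self.values[k] for k in order], dtype=float)


def _as_voxels(volume: ImageVolume | np.ndarray) -> np.ndarray:
    if isinstance(volume, ImageVolume):
        return volume.voxels
    v = np.asarray(volume, dtype=float)
    if v.ndim != 3:
        raise ValueError("volume must be 3D")
    return v


def _check_mask(mask: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError("mask and volume shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def quantise_roi(
    volume: ImageVolume | np.ndarray, mask: np.ndarray, n_bins: int
) -> np.ndarray:
    """Discretise ROI intensities into ``n_bins`` equal-width levels.

    Bin edges span the ROI's own min-max range (fixed bin number, no
    re-segmentation); the maximum intensity maps to level ``n_bins``.
    Returns an integer grid of the volume's shape with levels
    ``1..n_bins`` inside the mask and 0 outside. A constant ROI maps
    every voxel to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vox = _as_voxels(volume)
    mask = _check_mask(mask, vox.shape)
    vals = vox[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vox.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
        return levels
    lv = np.floor(n_bins * (vals - lo) / (hi - lo)).astype(np.int64) + 1
    np.clip(lv, 1, n_bins, out=lv)
    levels[mask] = lv
    return levels


def perturb_mask(
    mask: np.ndarray,
    mode: str,
    structuring_element: np.ndarray | None = None,
) -> np.ndarray:
    """Binary morphological opening or closing of an ROI mask.

    Raises :class:`MaskEmptiedError` if the perturbation empties the
    mask (e.g. opening of a mask thinner than the structuring element);
    the robustness pipeline catches this and skips the sample with a
    log entry.
    """
    mask = np.asarray(mask).astype(bool)
    if structuring_element is None:
        structuring_element = np.ones((3, 3, 3), dtype=bool)
    structuring_element = np.asarray(structuring_element).astype(bool)
    if not structuring_element.any():
        raise ValueError("structuring element is empty")
    if mode == "opening":
        out = ndimage.binary_opening(mask, structure=structuring_element)
    elif mode == "closing":
        # pad so the dilation can extend past the grid edge; otherwise
        # closing is not extensive for border voxels
        pad = max(structuring_element.shape)
        padded = np.pad(mask, pad)
        out = ndimage.binary_closing(padded, structure=structuring_element)
        out = out[tuple(slice(pad, -pad) for _ in mask.shape)]
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    if not out.any():
        raise MaskEmptiedError(f"{mode} emptied the mask")
    return out


# ---------------------------------------------------------------------------
# first order


def _firstorder(vals: np.ndarray, levels_in_mask: np.ndarray, n_bins: int) -> dict:
    n = vals.size
    mean = float(vals.mean())
    var = float(vals.var())  # population variance
    sd = np.sqrt(var)
    hist = np.bincount(levels_in_mask, minlength=n_bins + 1)[1:]
    p = hist / n
    pnz = p[p > 0]
    out = {
        "Mean": mean,
        "Median": float(np.median(vals)),
        "Minimum": float(vals.min()),
        "Maximum": float(vals.max()),
        "Range": float(vals.max() - vals.min()),
        "Percentile10": float(np.percentile(vals, 10)),
        "Percentile90": float(np.percentile(vals, 90)),
        "InterquartileRange": float(
            np.percentile(vals, 75) - np.percentile(vals, 25)
        ),
        "Variance": var,
        "MeanAbsoluteDeviation": float(np.abs(vals - mean).mean()),
        "RootMeanSquared": float(np.sqrt((vals**2).mean())),
        "Energy": float((vals**2).sum()),
        "Entropy": float(-(pnz * np.log2(pnz)).sum()),
        "Uniformity": float((p**2).sum()),
    }
    if sd > 0:
        z = (vals - mean) / sd
        out["Skewness"] = float((z**3).mean())
        out["Kurtosis"] = float((z**4).mean())
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    return out


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrices(levels: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Symmetric, normalised co-occurrence matrix per 3D direction.

    Only voxel pairs with both members inside the ROI contribute.
    Directions with no valid pair are dropped.
    """
    mats = []
    for d in DIRECTIONS_3D:
        a, b = _shifted_pairs(levels, d)
        if a.size == 0:
            continue
        m = np.zeros((n_levels, n_levels))
        np.add.at(m, (a - 1, b - 1), 1.0)
        m = m + m.T
        mats.append(m / m.sum())
    return mats


def _shifted_pairs(levels: np.ndarray, d: tuple[int, int, int]):
    """Pairs of levels (voxel, voxel+d) where both lie inside the ROI."""
    sl_a, sl_b = [], []
    for off, ext in zip(d, levels.shape):
        if off == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif off > 0:
            sl_a.append(slice(0, ext - off))
            sl_b.append(slice(off, ext))
        else:
            sl_a.append(slice(-off, ext))
            sl_b.append(slice(0, ext + off))
    a = levels[tuple(sl_a)].ravel()
    b = levels[tuple(sl_b)].ravel()
    keep = (a > 0) & (b > 0)
    return a[keep], b[keep]


def _glcm_features(p: np.ndarray) -> dict:
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())  # marginal mean (symmetric: mu_x == mu_y)
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)
    pnz = p[p > 0]

    # difference and sum distributions
    k_diff = np.arange(0, n)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * n + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    pd_nz = p_diff[p_diff > 0]
    ps_nz = p_sum[p_sum > 0]
    diff_avg = float((k_diff * p_diff).sum())

    out = {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(pd_nz * np.log2(pd_nz)).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "SumEntropy": float(-(ps_nz * np.log2(ps_nz)).sum()),
        "SumSquares": sigma2,
    }
    if sigma > 0:
        out["Correlation"] = float(
            ((p * ii * jj).sum() - mu * mu) / (sigma * sigma)
        )
    else:
        warnings.warn("single-level ROI: glcm.Correlation set to 0")
        out["Correlation"] = 0.0
    return out


# ---------------------------------------------------------------------------
# GLRLM


def _glrlm_matrix(levels: np.ndarray, n_levels: int, d: tuple[int, int, int]):
    """Run-length matrix along one direction (grey level x run length)."""
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum((e * o) ** 2 for e, o in zip(shape, d)))))
    max_len = max(max_len, max(shape))
    m = np.zeros((n_levels, max_len))
    # run starts: ROI voxel whose predecessor along d is outside ROI or differs
    prev = np.zeros(shape, dtype=np.int64)
    src_a, src_b = [], []
    for off, ext in zip(d, shape):
        if off == 0:
            src_a.append(slice(None))
            src_b.append(slice(None))
        elif off > 0:
            src_a.append(slice(off, ext))
            src_b.append(slice(0, ext - off))
        else:
            src_a.append(slice(0, ext + off))
            src_b.append(slice(-off, ext))
    prev[tuple(src_a)] = levels[tuple(src_b)]
    starts = np.argwhere((levels > 0) & (levels != prev))
    d_arr = np.array(d)
    for pos in starts:
        g = levels[tuple(pos)]
        length = 1
        nxt = pos + d_arr
        while (
            (nxt >= 0).all()
            and (nxt < shape).all()
            and levels[tuple(nxt)] == g
        ):
            length += 1
            nxt = nxt + d_arr
        m[g - 1, length - 1] += 1
    return m[:, : max(1, int(np.max(np.nonzero(m.sum(axis=0))[0])) + 1) if m.any() else 1]


def _size_distribution_features(m: np.ndarray, n_voxels: int, prefix_small: str,
                                prefix_large: str, axis_name: str) -> dict:
    """Shared feature formulas for GLRLM/GLSZM/GLDM-style matrices.

    ``m[g-1, s-1]`` counts runs/zones/dependencies of grey level g and
    size s. Returns the standard emphasis/non-uniformity/variance set,
    with names assembled from the supplied prefixes.
    """
    ns = m.sum()
    p = m / ns
    n_levels, max_s = m.shape
    gi = np.arange(1, n_levels + 1)[:, None].astype(float)
    sj = np.arange(1, max_s + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((np.arange(1, n_levels + 1) * pg).sum())
    mu_s = float((np.arange(1, max_s + 1) * ps).sum())
    pnz = p[p > 0]
    out = {
        prefix_small: float((p / sj**2).sum()),
        prefix_large: float((p * sj**2).sum()),
        "GrayLevelNonUniformity": float((m.sum(axis=1) ** 2).sum() / ns),
        f"{axis_name}NonUniformity": float((m.sum(axis=0) ** 2).sum() / ns),
        f"{axis_name}NonUniformityNormalized": float(
            (m.sum(axis=0) ** 2).sum() / ns**2
        ),
        "GrayLevelVariance": float((p * (gi - mu_g) ** 2).sum()),
        f"{axis_name}Variance": float((p * (sj - mu_s) ** 2).sum()),
        f"{axis_name}Entropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((p / gi**2).sum()),
        "HighGrayLevelEmphasis": float((p * gi**2).sum()),
        f"{prefix_small}LowGrayLevel": float((p / (gi**2 * sj**2)).sum()),
        f"{prefix_small}HighGrayLevel": float((p * gi**2 / sj**2).sum()),
        f"{prefix_large}LowGrayLevel": float((p * sj**2 / gi**2).sum()),
        f"{prefix_large}HighGrayLevel": float((p * gi**2 * sj**2).sum()),
    }
    return out


def _glrlm_features(levels: np.ndarray, n_levels: int, n_voxels: int) -> dict:
    per_dir: list[dict] = []
    for d in DIRECTIONS_3D:
        m = _glrlm_matrix(levels, n_levels, d)
        feats = _size_distribution_features(
            m, n_voxels, "ShortRunEmphasis", "LongRunEmphasis", "RunLength"
        )
        feats["RunPercentage"] = float(m.sum() / n_voxels)
        per_dir.append(feats)
    return _average_dicts(per_dir)


# ---------------------------------------------------------------------------
# GLSZM


def _glszm_features(levels: np.ndarray, n_levels: int, n_voxels: int) -> dict:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    zones: dict[tuple[int, int], float] = {}
    max_size = 1
    for g in np.unique(levels[levels > 0]):
        lab, n_zones = ndimage.label(levels == g, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones[(g, s)] = zones.get((g, s), 0) + 1
            max_size = max(max_size, int(s))
    m = np.zeros((n_levels, max_size))
    for (g, s), c in zones.items():
        m[g - 1, s - 1] = c
    feats = _size_distribution_features(
        m, n_voxels, "SmallAreaEmphasis", "LargeAreaEmphasis", "ZoneSize"
    )
    feats["ZonePercentage"] = float(m.sum() / n_voxels)
    return feats


# ---------------------------------------------------------------------------
# GLDM


def _neighbour_stack(levels: np.ndarray):
    """Levels of all 26 neighbours per voxel (0 where outside grid/ROI)."""
    shape = levels.shape
    stack = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                sh = np.zeros(shape, dtype=np.int64)
                src_a, src_b = [], []
                for off, ext in zip((dx, dy, dz), shape):
                    if off == 0:
                        src_a.append(slice(None))
                        src_b.append(slice(None))
                    elif off > 0:
                        src_a.append(slice(off, ext))
                        src_b.append(slice(0, ext - off))
                    else:
                        src_a.append(slice(0, ext + off))
                        src_b.append(slice(-off, ext))
                sh[tuple(src_a)] = levels[tuple(src_b)]
                stack.append(sh)
    return np.stack(stack)  # (26, *shape)


def _gldm_features(levels: np.ndarray, n_levels: int, n_voxels: int,
                   alpha: int = 0) -> dict:
    nb = _neighbour_stack(levels)
    roi = levels > 0
    dependent = (nb > 0) & (np.abs(nb - levels[None]) <= alpha)
    dep_count = dependent.sum(axis=0)[roi]  # 0..26
    g = levels[roi]
    # dependence size j = count + 1, keeping 1/j^2 finite for isolated voxels
    m = np.zeros((n_levels, 27))
    np.add.at(m, (g - 1, dep_count), 1.0)
    m = m[:, : int(dep_count.max()) + 1]
    feats = _size_distribution_features(
        m, n_voxels, "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "Dependence"
    )
    return feats


# ---------------------------------------------------------------------------
# NGTDM


def _ngtdm_features(levels: np.ndarray, n_levels: int, n_voxels: int) -> dict:
    nb = _neighbour_stack(levels).astype(float)
    roi = levels > 0
    valid = nb > 0
    n_valid = valid.sum(axis=0)
    sums = (nb * valid).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nb = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), 0.0)
    has_nb = (n_valid > 0) & roi
    g = levels[has_nb]
    diffs = np.abs(levels[has_nb] - mean_nb[has_nb])
    n_i = np.bincount(g, minlength=n_levels + 1)[1:].astype(float)
    s_i = np.zeros(n_levels)
    np.add.at(s_i, g - 1, diffs)
    n_tot = n_i.sum()
    p_i = n_i / n_tot if n_tot else n_i
    present = p_i > 0
    ngp = int(present.sum())
    i_val = np.arange(1, n_levels + 1, dtype=float)

    coarse_den = float((p_i * s_i).sum())
    out = {"Coarseness": float(1.0 / coarse_den) if coarse_den > 0 else 1e6}

    if ngp > 1:
        ipi = i_val * p_i
        pair_num = 0.0
        busy_den = 0.0
        complexity = 0.0
        strength_num = 0.0
        idx = np.where(present)[0]
        for a in idx:
            for b in idx:
                pair_num += p_i[a] * p_i[b] * (i_val[a] - i_val[b]) ** 2
                busy_den += abs(ipi[a] - ipi[b])
                complexity += (
                    abs(i_val[a] - i_val[b])
                    * (p_i[a] * s_i[a] + p_i[b] * s_i[b])
                    / (p_i[a] + p_i[b])
                )
                strength_num += (p_i[a] + p_i[b]) * (i_val[a] - i_val[b]) ** 2
        out["Contrast"] = float(
            pair_num / (ngp * (ngp - 1)) * s_i.sum() / n_tot
        )
        out["Busyness"] = float(coarse_den / busy_den) if busy_den > 0 else 0.0
        out["Complexity"] = float(complexity / n_tot)
        out["Strength"] = (
            float(strength_num / s_i.sum()) if s_i.sum() > 0 else 0.0
        )
    else:
        warnings.warn("single-level ROI: ngtdm contrast-type features set to 0")
        out.update(Contrast=0.0, Busyness=0.0, Complexity=0.0, Strength=0.0)
    return out


# ---------------------------------------------------------------------------


def _average_dicts(dicts: list[dict]) -> dict:
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


def extract_features(
    volume: ImageVolume | np.ndarray,
    mask: np.ndarray,
    n_bins: int,
    classes: Iterable[str] = FEATURE_CLASSES,
    *,
    modality: str = "",
    time_point: str = "",
) -> FeatureVector:
    """Compute the requested 3D feature classes over the masked ROI.

    Directional matrices (GLCM, GLRLM) are averaged over the 13 unique
    3D directions; co-occurrence matrices are symmetrised and normalised
    per direction before feature computation. The result is
    deterministic: identical inputs give a bit-identical vector.
    """
    classes = tuple(classes)
    unknown = set(classes) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    vox = _as_voxels(volume)
    mask_b = _check_mask(mask, vox.shape)
    levels = quantise_roi(vox, mask_b, n_bins)
    n_levels = int(levels.max())
    n_voxels = int(mask_b.sum())
    vals = vox[mask_b]
    lv_in = levels[mask_b]

    out: dict[str, float] = {}
    if "firstorder" in classes:
        for k, v in _firstorder(vals, lv_in, n_bins).items():
            out[f"firstorder.{k}"] = v
    if "glcm" in classes:
        mats = _glcm_matrices(levels, n_levels)
        if mats:
            feats = _average_dicts([_glcm_features(p) for p in mats])
        else:
            warnings.warn("no co-occurring voxel pairs; glcm features set to 0")
            feats = {k: 0.0 for k in _glcm_features(np.ones((1, 1)))}
        for k, v in feats.items():
            out[f"glcm.{k}"] = v
    if "glrlm" in classes:
        for k, v in _glrlm_features(levels, n_levels, n_voxels).items():
            out[f"glrlm.{k}"] = v
    if "glszm" in classes:
        for k, v in _glszm_features(levels, n_levels, n_voxels).items():
            out[f"glszm.{k}"] = v
    if "gldm" in classes:
        for k, v in _gldm_features(levels, n_levels, n_voxels).items():
            out[f"gldm.{k}"] = v
    if "ngtdm" in classes:
        for k, v in _ngtdm_features(levels, n_levels, n_voxels).items():
            out[f"ngtdm.{k}"] = v

    if isinstance(volume, ImageVolume) and not modality:
        modality = volume.modality
    return FeatureVector(out, modality=modality, time_point=time_point,
                         n_bins=n_bins)
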