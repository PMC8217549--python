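"""3D radiomic feature extraction: 107 IBSI-style features in six classes.

The extractor computes, per (volume, mask, bin-count) configuration:

* 18 first-order intensity statistics,
* 14 shape features from the 3D mask (mesh- and covariance-based),
* 24 grey-level co-occurrence matrix (GLCM) features,
* 16 grey-level run-length matrix (GLRLM) features,
* 16 grey-level size-zone matrix (GLSZM) features,
* 14 grey-level dependence matrix (GLDM) features,
*  5 neighbouring grey-tone difference matrix (NGTDM) features,

for a total of 107.  Texture matrices are computed in 3D on the voxel
lattice (no resampling, no resegmentation); shape features use the physical
voxel spacing.  Intensities are discretised by fixed bin count over the
ROI's own intensity range — never by fixed bin width — which makes every
discretised-texture feature invariant under a constant intensity shift.

Conventions (matching the reference radiomics tooling widely used in the
field):

* GLCM and GLRLM are accumulated over the 13 unique direction pairs at
  Chebyshev distance 1; each feature is computed per direction and then
  averaged without distance weighting.
* GLSZM zones are 26-connected components of equal grey level; GLDM uses the
  26-neighbourhood with similarity tolerance alpha = 0, the centre voxel
  counting towards its own dependence; NGTDM uses 26-neighbourhood means.
* A grey level's value in a formula is its 1-based bin index.  GLCM/GLRLM
  keep all levels 1..G_max in the matrix dimensions; GLSZM/GLDM/NGTDM drop
  empty levels but keep the level *values* in the formulas.
* Degenerate ROIs (single grey level, or too few voxels for a mesh) yield
  NaN in the slots whose formula is undefined, except where a convention is
  fixed: GLCM Correlation = 1 and Imc1 = 0 at zero grey-level variance,
  NGTDM Coarseness = 1e6 when its denominator vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .core import ImageVolume, RoiMask

_EPS = np.finfo(float).eps

# The 13 unique 3D direction pairs at Chebyshev distance 1 (one of each
# antipodal pair, lexicographically positive).
ANGLES = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(ANGLES) == 13

FEATURE_CLASSES = (
    "firstorder",
    "shape",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
)

CLASS_SIZES = {
    "firstorder": 18,
    "shape": 14,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}


@dataclass
class QuantisationConfig:
    """Fixed-bin-count discretisation over the ROI intensity range."""

    n_bins: int = 128

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class DiscretisedRoi:
    """Grey levels (1..n_bins) on the in-mask voxels of a cropped grid.

    ``levels`` is 0 outside the mask; ``degenerate`` flags a constant ROI
    (all voxels in level 1).
    """

    levels: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray  # bool array, same shape
    n_bins: int
    degenerate: bool = False

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _crop_to_mask(arrays: list[np.ndarray], mask: np.ndarray, pad: int = 1):
    """Crop arrays to the mask bounding box plus a 1-voxel margin."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return [a[sl] for a in arrays], mask[sl]


def discretise(volume: ImageVolume, mask: RoiMask, q: QuantisationConfig) -> DiscretisedRoi:
    """Fixed-bin-count discretisation of the in-mask intensities.

    Bin edges partition [min, max] of the ROI intensities into ``n_bins``
    equal-width bins; level(v) = floor((I(v) - min) / width) + 1, with the
    maximum mapped into the top bin.  A constant ROI maps every voxel to
    level 1 and is flagged degenerate.
    """
    if volume.data.shape != mask.data.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.data.any():
        raise ValueError("empty mask")
    (vals,), m = _crop_to_mask([volume.data], mask.data)
    inten = vals[m]
    lo, hi = float(inten.min()), float(inten.max())
    levels = np.zeros(m.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
        return DiscretisedRoi(levels, m, q.n_bins, degenerate=True)
    width = (hi - lo) / q.n_bins
    lv = np.floor((inten - lo) / width).astype(np.int32) + 1
    np.clip(lv, 1, q.n_bins, out=lv)
    levels[m] = lv
    return DiscretisedRoi(levels, m, q.n_bins)


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def first_order_features(
    intensities: np.ndarray,
    roi: DiscretisedRoi,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """The 18 first-order statistics of the ROI intensity distribution.

    Entropy and Uniformity are computed on the discretised histogram; all
    others on the raw intensities.  Moments are population moments.
    Skewness and Kurtosis are NaN for a zero-variance ROI (undefined);
    Kurtosis is not excess-corrected.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("first-order features need at least one voxel")
    n = x.size
    mean = float(x.mean())
    dev = x - mean
    m2 = float(np.mean(dev**2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    hist = np.bincount(roi.in_mask_levels)[1:]
    p = hist[hist > 0] / n
    robust = x[(x >= p10) & (x <= p90)]
    out = {
        "firstorder_Energy": float(np.sum(x**2)),
        "firstorder_TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "firstorder_Entropy": float(-np.sum(p * np.log2(p))),
        "firstorder_Minimum": float(x.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": mean,
        "firstorder_Median": float(p50),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "firstorder_RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else np.nan
        ),
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "firstorder_Skewness": float(np.mean(dev**3) / m2**1.5) if m2 > 0 else np.nan,
        "firstorder_Kurtosis": float(np.mean(dev**4) / m2**2) if m2 > 0 else np.nan,
        "firstorder_Variance": m2,
        "firstorder_Uniformity": float(np.sum(p**2)),
    }
    return out


# ---------------------------------------------------------------------------
# 3D shape features
# ---------------------------------------------------------------------------

def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    # light pre-smoothing (0.5 voxel) before marching cubes: the raw binary
    # staircase overestimates surface area by ~10%; 0.5 voxel keeps volume
    # within ~3% while bringing a digitised sphere's sphericity near 1
    padded = np.pad(mask.astype(float), 2)
    smoothed = ndimage.gaussian_filter(padded, 0.5)
    if smoothed.max() <= 0.5:  # very small masks can smooth away entirely
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 10 and pts.shape[1] >= 2:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(pts).max())


def shape_features_3d(mask: RoiMask) -> dict[str, float]:
    """The 14 mesh- and covariance-based 3D shape features of a mask.

    Mesh volume and surface area come from a marching-cubes triangulation of
    the zero-padded mask at level 0.5, in physical (mm) coordinates; axis
    lengths are 4 * sqrt(eigenvalues) of the physical-coordinate covariance
    of the mask voxel centres; maximum 2D diameters are the largest pairwise
    mesh-vertex distances within the projection orthogonal to each axis
    (axis order: row, column, slice).  Masks with fewer than 4 voxels get
    NaN in the mesh-based slots.
    """
    if not mask.data.any():
        raise ValueError("empty mask")
    _, m = _crop_to_mask([mask.data], mask.data)
    spacing = np.asarray(mask.spacing)
    n = int(m.sum())
    voxel_volume = float(np.prod(spacing))
    coords = np.argwhere(m) * spacing  # physical voxel centres

    out: dict[str, float] = {}
    out["shape_VoxelVolume"] = n * voxel_volume

    if n >= 4:
        verts, faces = _mesh(m, spacing)
        area = float(measure.mesh_surface_area(verts, faces))
        vol = _mesh_volume(verts, faces)
        out["shape_MeshVolume"] = vol
        out["shape_SurfaceArea"] = area
        out["shape_SurfaceVolumeRatio"] = area / vol if vol > 0 else np.nan
        out["shape_Sphericity"] = (
            (36 * np.pi * vol**2) ** (1 / 3) / area if area > 0 else np.nan
        )
        out["shape_Maximum3DDiameter"] = _max_pairwise(verts)
        # projections orthogonal to each axis; names follow the dropped axis
        out["shape_Maximum2DDiameterRow"] = _max_pairwise(verts[:, [1, 2]])
        out["shape_Maximum2DDiameterColumn"] = _max_pairwise(verts[:, [0, 2]])
        out["shape_Maximum2DDiameterSlice"] = _max_pairwise(verts[:, [0, 1]])
    else:
        for k in (
            "MeshVolume",
            "SurfaceArea",
            "SurfaceVolumeRatio",
            "Sphericity",
            "Maximum3DDiameter",
            "Maximum2DDiameterRow",
            "Maximum2DDiameterColumn",
            "Maximum2DDiameterSlice",
        ):
            out[f"shape_{k}"] = np.nan

    if n >= 2:
        cov = np.cov(coords, rowvar=False, bias=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0, None)
        out["shape_MajorAxisLength"] = 4 * float(np.sqrt(eig[0]))
        out["shape_MinorAxisLength"] = 4 * float(np.sqrt(eig[1]))
        out["shape_LeastAxisLength"] = 4 * float(np.sqrt(eig[2]))
        out["shape_Elongation"] = (
            float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan
        )
        out["shape_Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else np.nan
    else:
        for k in ("MajorAxisLength", "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness"):
            out[f"shape_{k}"] = np.nan
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(roi: DiscretisedRoi) -> np.ndarray:
    """Symmetric, normalised GLCMs, one per direction: shape (13, G, G)."""
    lv = roi.levels
    g = int(lv.max())
    mats = np.zeros((len(ANGLES), g, g))
    for a, (dx, dy, dz) in enumerate(ANGLES):
        s0 = tuple(
            slice(max(d, 0), lv.shape[i] + min(d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        s1 = tuple(
            slice(max(-d, 0), lv.shape[i] + min(-d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        u, v = lv[s0], lv[s1]
        ok = (u > 0) & (v > 0)
        np.add.at(mats[a], (u[ok] - 1, v[ok] - 1), 1.0)
        mats[a] += mats[a].T.copy()
        tot = mats[a].sum()
        if tot > 0:
            mats[a] /= tot
    return mats


def _glcm_features_single(P: np.ndarray, n_levels: int) -> dict[str, float]:
    g = P.shape[0]
    # drop all-zero grey levels: they contribute nothing to any sum below;
    # n_levels keeps the full (empty-bin-retaining) dimension for Idmn/Idn
    occupied = P.sum(axis=1) > 0
    P = P[np.ix_(occupied, occupied)]
    i = np.arange(1, g + 1)[occupied]
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())
    sig = np.sqrt(sig2)

    # diagonal / cross-diagonal distributions
    k_sum = np.arange(2, 2 * g + 1)
    p_sum = np.bincount((I + J).ravel(), weights=P.ravel(), minlength=2 * g + 1)[2:]
    k_diff = np.arange(0, g)
    p_diff = np.bincount(np.abs(I - J).ravel(), weights=P.ravel(), minlength=g)

    pnz = P[P > 0]
    HXY = float(-np.sum(pnz * np.log2(pnz)))
    pxnz = px[px > 0]
    HX = float(-np.sum(pxnz * np.log2(pxnz)))
    PxPy = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        HXY1 = float(-np.sum(P * np.log2(PxPy + _EPS)))
        HXY2 = float(-np.sum(PxPy * np.log2(PxPy + _EPS)))

    da = float((k_diff * p_diff).sum())
    out = {
        "glcm_Autocorrelation": float((I * J * P).sum()),
        "glcm_JointAverage": mu,
        "glcm_ClusterProminence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "glcm_ClusterShade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "glcm_ClusterTendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "glcm_Contrast": float(((I - J) ** 2 * P).sum()),
        "glcm_Correlation": (
            float(((I - mu) * (J - mu) * P).sum() / sig2) if sig2 > 0 else 1.0
        ),
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": float(
            -np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))
        ),
        "glcm_DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_Id": float((P / (1 + np.abs(I - J))).sum()),
        "glcm_Idm": float((P / (1 + (I - J) ** 2)).sum()),
        "glcm_Idmn": float((P / (1 + ((I - J) / n_levels) ** 2)).sum()),
        "glcm_Idn": float((P / (1 + np.abs(I - J) / n_levels)).sum()),
        "glcm_Imc1": ((HXY - HXY1) / HX if HX > 0 else 0.0),
        "glcm_Imc2": float(np.sqrt(max(0.0, 1 - np.exp(-2 * (HXY2 - HXY))))),
        "glcm_InverseVariance": float(
            (P[I != J] / (I[I != J] - J[I != J]) ** 2).sum()
        ),
        "glcm_JointEnergy": float((P**2).sum()),
        "glcm_JointEntropy": HXY,
        "glcm_MCC": _glcm_mcc(P, px),
        "glcm_MaximumProbability": float(P.max()),
        "glcm_SumAverage": float((k_sum * p_sum).sum()),
        "glcm_SumEntropy": float(
            -np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))
        ),
        "glcm_SumSquares": sig2,
    }
    return out


def _glcm_mcc(P: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k))."""
    nz = px > 0
    Pn = P[np.ix_(nz, nz)]
    pxn = px[nz]
    if Pn.shape[0] < 2:
        return 1.0
    Q = (Pn / pxn[:, None]) @ (Pn / pxn[None, :]).T
    ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
    return float(np.sqrt(max(0.0, ev[1])))


def glcm_features(roi: DiscretisedRoi) -> dict[str, float]:
    """The 24 GLCM features, computed per direction and averaged."""
    if roi.voxel_count < 2:
        raise ValueError("GLCM needs at least 2 voxels")
    mats = glcm_matrices(roi)
    g = mats.shape[1]
    per_dir = [_glcm_features_single(mats[a], g) for a in range(len(ANGLES)) if mats[a].sum() > 0]
    if not per_dir:
        raise ValueError("no co-occurring voxel pairs in any direction")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrices(roi: DiscretisedRoi) -> list[np.ndarray]:
    """Run-length matrices P(g, l), one per direction (counts)."""
    lv = roi.levels
    g = int(lv.max())
    max_len = int(np.ceil(np.sqrt(np.sum(np.square(lv.shape))))) + 1
    out = []
    for dx, dy, dz in ANGLES:
        same = np.zeros(lv.shape, dtype=bool)
        s0 = tuple(
            slice(max(d, 0), lv.shape[i] + min(d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        s1 = tuple(
            slice(max(-d, 0), lv.shape[i] + min(-d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        # same[v] = v and its predecessor (v - d) are both in-mask, equal level
        pred_eq = (lv[s1] > 0) & (lv[s1] == lv[s0])
        same[s0] = pred_eq
        same &= lv > 0
        # propagate run length along the direction
        L = (lv > 0).astype(np.int32)
        for _ in range(max(lv.shape)):
            Lp = np.zeros_like(L)
            Lp[s0] = L[s1]
            newL = np.where(same, Lp + 1, (lv > 0).astype(np.int32))
            if np.array_equal(newL, L):
                break
            L = newL
        # run ends: in-mask voxels whose successor does not continue the run
        succ_same = np.zeros(lv.shape, dtype=bool)
        succ_same[s1] = same[s0]
        ends = (lv > 0) & ~succ_same
        mat = np.zeros((g, max_len), dtype=float)
        np.add.at(mat, (lv[ends] - 1, L[ends] - 1), 1.0)
        nz = mat.sum(axis=0).nonzero()[0]
        out.append(mat[:, : nz.max() + 1] if nz.size else mat[:, :1])
    return out


def _rl_style_features(P: np.ndarray, prefix: str, np_voxels: int, j_name: str) -> dict[str, float]:
    """Shared formula block for run-length / size-zone style matrices.

    P is a (grey level, size) count matrix; ``j_name`` picks the naming
    family ('Run' or 'Zone'/'Area')."""
    Ns = P.sum()
    if Ns == 0:
        raise ValueError("empty texture matrix")
    g, smax = P.shape
    i = np.arange(1, g + 1)[:, None]
    j = np.arange(1, smax + 1)[None, :]
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    p = P / Ns
    mu_i = float((np.arange(1, g + 1) * pg / Ns).sum())
    mu_j = float((np.arange(1, smax + 1) * ps / Ns).sum())
    pnz = p[p > 0]

    if j_name == "Run":
        names = dict(
            small="ShortRunEmphasis", large="LongRunEmphasis",
            gln="GrayLevelNonUniformity", glnn="GrayLevelNonUniformityNormalized",
            sn="RunLengthNonUniformity", snn="RunLengthNonUniformityNormalized",
            pct="RunPercentage", glv="GrayLevelVariance", sv="RunVariance",
            ent="RunEntropy", lgl="LowGrayLevelRunEmphasis", hgl="HighGrayLevelRunEmphasis",
            slgl="ShortRunLowGrayLevelEmphasis", shgl="ShortRunHighGrayLevelEmphasis",
            llgl="LongRunLowGrayLevelEmphasis", lhgl="LongRunHighGrayLevelEmphasis",
        )
    else:
        names = dict(
            small="SmallAreaEmphasis", large="LargeAreaEmphasis",
            gln="GrayLevelNonUniformity", glnn="GrayLevelNonUniformityNormalized",
            sn="SizeZoneNonUniformity", snn="SizeZoneNonUniformityNormalized",
            pct="ZonePercentage", glv="GrayLevelVariance", sv="ZoneVariance",
            ent="ZoneEntropy", lgl="LowGrayLevelZoneEmphasis", hgl="HighGrayLevelZoneEmphasis",
            slgl="SmallAreaLowGrayLevelEmphasis", shgl="SmallAreaHighGrayLevelEmphasis",
            llgl="LargeAreaLowGrayLevelEmphasis", lhgl="LargeAreaHighGrayLevelEmphasis",
        )

    out = {
        f"{prefix}_{names['small']}": float((P / j**2).sum() / Ns),
        f"{prefix}_{names['large']}": float((P * j**2).sum() / Ns),
        f"{prefix}_{names['gln']}": float((pg**2).sum() / Ns),
        f"{prefix}_{names['glnn']}": float((pg**2).sum() / Ns**2),
        f"{prefix}_{names['sn']}": float((ps**2).sum() / Ns),
        f"{prefix}_{names['snn']}": float((ps**2).sum() / Ns**2),
        f"{prefix}_{names['pct']}": float(Ns / np_voxels),
        f"{prefix}_{names['glv']}": float((p * (i - mu_i) ** 2).sum()),
        f"{prefix}_{names['sv']}": float((p * (j - mu_j) ** 2).sum()),
        f"{prefix}_{names['ent']}": float(-np.sum(pnz * np.log2(pnz))),
        f"{prefix}_{names['lgl']}": float((P / i**2).sum() / Ns),
        f"{prefix}_{names['hgl']}": float((P * i**2).sum() / Ns),
        f"{prefix}_{names['slgl']}": float((P / (i**2 * j**2)).sum() / Ns),
        f"{prefix}_{names['shgl']}": float((P * i**2 / j**2).sum() / Ns),
        f"{prefix}_{names['llgl']}": float((P * j**2 / i**2).sum() / Ns),
        f"{prefix}_{names['lhgl']}": float((P * i**2 * j**2).sum() / Ns),
    }
    return out


def glrlm_features(roi: DiscretisedRoi) -> dict[str, float]:
    """The 16 GLRLM features, averaged over the 13 directions."""
    if roi.voxel_count < 2:
        raise ValueError("GLRLM needs at least 2 voxels")
    n = roi.voxel_count
    per_dir = [_rl_style_features(P, "glrlm", n, "Run") for P in glrlm_matrices(roi)]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(roi: DiscretisedRoi) -> np.ndarray:
    """Size-zone count matrix P(g, s): 26-connected equal-level zones."""
    lv = roi.levels
    g = int(lv.max())
    zones: list[tuple[int, int]] = []
    for level in np.unique(lv[lv > 0]):
        lab, nlab = ndimage.label(lv == level, structure=_STRUCT26)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(level), int(s)) for s in sizes)
    smax = max(s for _, s in zones)
    P = np.zeros((g, smax))
    for level, s in zones:
        P[level - 1, s - 1] += 1
    return P


def glszm_features(roi: DiscretisedRoi) -> dict[str, float]:
    """The 16 GLSZM features (single matrix; no directionality)."""
    if roi.voxel_count < 2:
        raise ValueError("GLSZM needs at least 2 voxels")
    return _rl_style_features(glszm_matrix(roi), "glszm", roi.voxel_count, "Zone")


# ---------------------------------------------------------------------------
# GLDM and NGTDM share the 26-neighbourhood accumulators
# ---------------------------------------------------------------------------

def _neighbour_sums(lv: np.ndarray):
    """Per-voxel count / level-sum / equal-level count over in-mask 26-neighbours."""
    inmask = lv > 0
    cnt = np.zeros(lv.shape, dtype=np.int32)
    tot = np.zeros(lv.shape, dtype=np.float64)
    eq = np.zeros(lv.shape, dtype=np.int32)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                s0 = tuple(
                    slice(max(d, 0), lv.shape[i] + min(d, 0))
                    for i, d in enumerate((dx, dy, dz))
                )
                s1 = tuple(
                    slice(max(-d, 0), lv.shape[i] + min(-d, 0))
                    for i, d in enumerate((dx, dy, dz))
                )
                nb_in = inmask[s1]
                cnt[s0] += nb_in
                tot[s0] += np.where(nb_in, lv[s1], 0)
                eq[s0] += nb_in & (lv[s1] == lv[s0])
    return cnt, tot, eq


def gldm_matrix(roi: DiscretisedRoi) -> np.ndarray:
    """Dependence count matrix P(g, d) with alpha = 0.

    A 26-neighbour is dependent iff its level equals the centre's; the
    dependence size d includes the centre voxel itself, so d >= 1.
    """
    lv = roi.levels
    _, _, eq = _neighbour_sums(lv)
    m = lv > 0
    dep = eq[m] + 1
    g = int(lv.max())
    P = np.zeros((g, int(dep.max())))
    np.add.at(P, (lv[m] - 1, dep - 1), 1.0)
    return P


def gldm_features(roi: DiscretisedRoi) -> dict[str, float]:
    """The 14 GLDM features."""
    if roi.voxel_count < 2:
        raise ValueError("GLDM needs at least 2 voxels")
    P = gldm_matrix(roi)
    Ns = P.sum()
    g, dmax = P.shape
    i = np.arange(1, g + 1)[:, None]
    j = np.arange(1, dmax + 1)[None, :]
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    p = P / Ns
    mu_i = float((np.arange(1, g + 1) * pg).sum() / Ns)
    mu_j = float((np.arange(1, dmax + 1) * pd).sum() / Ns)
    pnz = p[p > 0]
    return {
        "gldm_SmallDependenceEmphasis": float((P / j**2).sum() / Ns),
        "gldm_LargeDependenceEmphasis": float((P * j**2).sum() / Ns),
        "gldm_GrayLevelNonUniformity": float((pg**2).sum() / Ns),
        "gldm_DependenceNonUniformity": float((pd**2).sum() / Ns),
        "gldm_DependenceNonUniformityNormalized": float((pd**2).sum() / Ns**2),
        "gldm_GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "gldm_DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "gldm_DependenceEntropy": float(-np.sum(pnz * np.log2(pnz))),
        "gldm_LowGrayLevelEmphasis": float((P / i**2).sum() / Ns),
        "gldm_HighGrayLevelEmphasis": float((P * i**2).sum() / Ns),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / Ns),
        "gldm_SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / Ns),
        "gldm_LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / Ns),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / Ns),
    }


def ngtdm_features(roi: DiscretisedRoi) -> dict[str, float]:
    """The 5 NGTDM features (Coarseness, Contrast, Busyness, Complexity, Strength).

    s_i sums |i - mean neighbour level| over voxels of level i with at least
    one in-mask 26-neighbour; p_i = n_i / N over those voxels.
    """
    if roi.voxel_count < 2:
        raise ValueError("NGTDM needs at least 2 voxels")
    lv = roi.levels
    cnt, tot, _ = _neighbour_sums(lv)
    m = (lv > 0) & (cnt > 0)
    nvp = int(m.sum())
    if nvp == 0:
        raise ValueError("no voxel has an in-mask neighbour")
    avg = tot[m] / cnt[m]
    levels = lv[m]
    g = int(lv.max())
    n_i = np.bincount(levels, minlength=g + 1)[1:].astype(float)
    s_i = np.zeros(g)
    np.add.at(s_i, levels - 1, np.abs(levels - avg))
    p_i = n_i / nvp
    ivals = np.arange(1, g + 1, dtype=float)
    nz = p_i > 0
    ngp = int(nz.sum())

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
        ii, jj = np.meshgrid(ivals[nz], ivals[nz], indexing="ij")
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p_i * s_i).sum() / busy_den) if busy_den > 0 else 0.0
        si_nz = s_i[nz]
        sI, sJ = np.meshgrid(si_nz, si_nz, indexing="ij")
        complexity = float(
            (np.abs(ii - jj) * (pi * sI + pj * sJ) / (pi + pj)).sum() / nvp
        )
        s_sum = float(s_i.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def feature_names() -> list[str]:
    """The 107 feature names in canonical order (classes in fixed order)."""
    dummy = _dummy_vector()
    return list(dummy)


_NAMES_CACHE: list[str] | None = None


def _dummy_vector() -> dict[str, float]:
    global _NAMES_CACHE
    if _NAMES_CACHE is None:
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.normal(size=(6, 6, 6)), (1, 1, 1))
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        vec = extract_feature_vector(vol, RoiMask(mask, (1, 1, 1)), QuantisationConfig(8))
        _NAMES_CACHE = [k for k in vec if k not in ("sequence", "mask_version", "n_bins")]
    return dict.fromkeys(_NAMES_CACHE, 0.0)


def extract_feature_vector(
    volume: ImageVolume,
    mask: RoiMask,
    q: QuantisationConfig,
) -> dict[str, float]:
    """Compute the full 107-feature vector plus provenance fields.

    Returns a dict with the 107 feature values keyed ``class_Name`` and the
    provenance keys ``sequence``, ``mask_version``, ``n_bins``.  Degenerate
    ROIs (constant intensity) yield NaN in the texture slots whose formulas
    are undefined; downstream robustness screening treats NaN as non-robust.
    """
    roi = discretise(volume, mask, q)
    (vals,), m = _crop_to_mask([volume.data], mask.data)
    intensities = vals[m]
    voxvol = float(np.prod(mask.spacing))

    out: dict[str, float] = {}
    out.update(first_order_features(intensities, roi, voxvol))
    out.update(shape_features_3d(mask))
    if roi.degenerate:
        warnings.warn("constant-intensity ROI: texture features degenerate")
    out.update(glcm_features(roi))
    out.update(glrlm_features(roi))
    out.update(glszm_features(roi))
    out.update(gldm_features(roi))
    out.update(ngtdm_features(roi))
    out["sequence"] = volume.sequence
    out["mask_version"] = mask.version
    out["n_bins"] = q.n_bins
    return out
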