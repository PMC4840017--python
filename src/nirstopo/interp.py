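"""Per-subject contrast images on the canonical scalp surface.

2D path: piecewise-linear interpolation of channel contrasts over the channel
triangulation on the 10-20 disc, followed by mask-aware Gaussian smoothing
(FWHM default 14 mm) and NIfTI-1 serialization.

3D path: spherical-spline interpolation (order m = 4 by default) on the
triangular scalp mesh, serialized as GIfTI.  The spline interpolant is

    f(r_i) = k_0 + sum_j k_j g_m(cos(r_i, r_j)),

with the Legendre-series kernel
g_m(x) = (1/4 pi) sum_{n>=1} (2n+1) / (n^m (n+1)^m) P_n(x), subject to
sum_j k_j = 0 and exact reproduction of the channel data.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from numpy.polynomial import legendre
from scipy import sparse
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay, QhullError
from sklearn.base import BaseEstimator, RegressorMixin

from .first_level import ChannelContrast
from .scalp import ScalpGrid2D, ScalpMesh

__all__ = [
    "ContrastImage",
    "GridInterpolator",
    "SphericalSplineInterpolator",
    "interp2d_linear",
    "smooth_gaussian",
    "spline_g",
    "fit_spherical_spline",
    "eval_spherical_spline",
    "write_image",
    "read_image",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ContrastImage:
    """Interpolated effect map on the 2D grid or 3D mesh.

    ``values`` is (n, n) for grid space and (V,) for mesh space; entries
    outside ``mask`` are NaN.
    """

    space: str  # "grid2d" | "mesh3d"
    values: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    smoothing_fwhm: float | None = None
    grid: ScalpGrid2D | None = None
    mesh: ScalpMesh | None = None

    def __post_init__(self) -> None:
        if self.space not in ("grid2d", "mesh3d"):
            raise ValueError("space must be 'grid2d' or 'mesh3d'")
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")

    def masked(self) -> np.ndarray:
        """Values with NaN outside the mask."""
        out = np.where(self.mask, self.values, np.nan)
        return out


def _contrast_values(w) -> np.ndarray:
    if isinstance(w, ChannelContrast):
        return np.asarray(w.w, dtype=float)
    return np.asarray(w, dtype=float).ravel()


class GridInterpolator(BaseEstimator, RegressorMixin):
    """Piecewise-linear scattered interpolation onto a fixed pixel grid.

    Precomputes the sparse barycentric-weight operator from channel disc
    coordinates to grid pixels, so repeated interpolation of per-subject
    contrast vectors is a single sparse matrix-vector product.  Pixels
    outside the channel convex hull (or outside the grid mask) are NaN.
    """

    def __init__(self, grid: ScalpGrid2D | None = None):
        self.grid = grid

    def fit(self, channel_xy: np.ndarray, y=None) -> "GridInterpolator":
        grid = self.grid if self.grid is not None else ScalpGrid2D()
        pts = np.atleast_2d(np.asarray(channel_xy, dtype=float))
        if len(pts) < 3:
            raise ValueError("need at least 3 channels for triangulation")
        try:
            tri = Delaunay(pts)
        except QhullError as err:
            raise ValueError(
                "degenerate channel triangulation (collinear channels?)"
            ) from err
        xx, yy = grid.pixel_centers()
        q = np.column_stack([xx.ravel(), yy.ravel()])
        simplex = tri.find_simplex(q)
        inside = simplex >= 0
        trans = tri.transform[simplex[inside]]
        bary2 = np.einsum(
            "ijk,ik->ij", trans[:, :2, :], q[inside] - trans[:, 2, :]
        )
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        verts = tri.simplices[simplex[inside]]
        rows = np.repeat(np.flatnonzero(inside), 3)
        W = sparse.csr_matrix(
            (bary.ravel(), (rows, verts.ravel())),
            shape=(q.shape[0], len(pts)),
        )
        self.grid_ = grid
        self.weights_ = W
        self.hull_mask_ = inside.reshape(xx.shape) & grid.mask
        return self

    def predict(self, w) -> ContrastImage:
        return self.transform(w)

    def transform(self, w, subject_id: str = "") -> ContrastImage:
        vals = _contrast_values(w)
        if vals.size != self.weights_.shape[1]:
            raise ValueError("contrast length does not match fitted channels")
        img = (self.weights_ @ vals).reshape(self.hull_mask_.shape)
        img = np.where(self.hull_mask_, img, np.nan)
        sid = w.subject_id if isinstance(w, ChannelContrast) else subject_id
        return ContrastImage(
            space="grid2d",
            values=img,
            mask=self.hull_mask_,
            subject_id=sid,
            grid=self.grid_,
        )


def interp2d_linear(
    channel_xy: np.ndarray, w, grid: ScalpGrid2D | None = None
) -> ContrastImage:
    """One-shot linear interpolation of channel contrasts onto the grid."""
    return GridInterpolator(grid=grid).fit(channel_xy).transform(w)


def smooth_gaussian(img: ContrastImage, fwhm: float = 14.0) -> ContrastImage:
    """Mask-aware Gaussian smoothing (sigma = FWHM / (2 sqrt(2 ln 2))).

    The kernel is renormalized over defined pixels so constant fields are
    preserved inside the mask and edge pixels are unbiased.
    """
    if img.space != "grid2d":
        raise ValueError("Gaussian smoothing applies to grid2d images only")
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    sigma_px = fwhm * _FWHM_TO_SIGMA / img.grid.pixel_size
    filled = np.where(img.mask, img.values, 0.0)
    num = gaussian_filter(filled, sigma_px, mode="constant")
    den = gaussian_filter(img.mask.astype(float), sigma_px, mode="constant")
    out = np.full_like(filled, np.nan)
    out[img.mask] = num[img.mask] / den[img.mask]
    return ContrastImage(
        space="grid2d",
        values=out,
        mask=img.mask,
        subject_id=img.subject_id,
        smoothing_fwhm=fwhm,
        grid=img.grid,
    )


def _series_length(m: int, tol: float) -> int:
    n = 1
    while (2 * n + 1) / (n * (n + 1)) ** m >= tol:
        n += 1
    return n


def spline_g(x, m: int = 4, tol: float = 1e-10) -> np.ndarray:
    """Legendre-series kernel g_m(x) of the spherical spline.

    The series is truncated once the term bound (2n+1)/(n(n+1))^m drops
    below ``tol``; Legendre polynomials are evaluated by the stable
    three-term recurrence (numpy's Legendre series evaluator).
    """
    if m < 2:
        raise ValueError("spline order m must be >= 2 (series diverges otherwise)")
    x = np.clip(np.asarray(x, dtype=float), -1.0, 1.0)
    N = _series_length(m, tol)
    n = np.arange(1, N + 1, dtype=float)
    coef = np.zeros(N + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1)) ** m / (4.0 * np.pi)
    return legendre.legval(x, coef)


def fit_spherical_spline(
    channel_dirs: np.ndarray,
    w,
    m: int = 4,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> "SphericalSplineInterpolator":
    """Fit the order-m spherical spline through channel contrasts."""
    model = SphericalSplineInterpolator(m=m, tol=tol, ridge=ridge)
    return model.fit(channel_dirs, _contrast_values(w))


def eval_spherical_spline(model: "SphericalSplineInterpolator", points: np.ndarray):
    return model.predict(points)


class SphericalSplineInterpolator(BaseEstimator, RegressorMixin):
    """Spherical-spline interpolation of scalp data (order m >= 2).

    Fitting solves the augmented symmetric system

        [G + ridge I  1] [k ]   [w]
        [1^T          0] [k0] = [0]

    with G_{jk} = g_m(cos(r_j, r_k)), enforcing sum_j k_j = 0 and exact
    reproduction at the channels; prediction evaluates
    k0 + sum_j k_j g_m(cos(r_i, r_j)).  Rotation equivariant: rotating
    channels and evaluation points together leaves values unchanged.

    The smooth kernel makes G ill-conditioned for dense layouts; the solve
    is polished with one step of iterative refinement.  ``ridge`` adds an
    optional Tikhonov term to G's diagonal: note any nonzero ridge trades
    exactness of channel reproduction (error ~ ridge * ||k||) for
    conditioning, so it defaults to 0.
    """

    def __init__(self, m: int = 4, tol: float = 1e-10, ridge: float = 0.0):
        self.m = m
        self.tol = tol
        self.ridge = ridge

    @staticmethod
    def _check_unit(points: np.ndarray, what: str) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        norms = np.linalg.norm(p, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ValueError(f"{what} must be unit-norm direction vectors")
        return p / norms[:, None]

    def fit(self, channel_dirs: np.ndarray, y) -> "SphericalSplineInterpolator":
        dirs = self._check_unit(channel_dirs, "channel directions")
        w = np.asarray(_contrast_values(y), dtype=float)
        J = len(dirs)
        if J < 3:
            raise ValueError("need at least 3 distinct channel directions")
        if w.size != J:
            raise ValueError("data length must match number of channels")
        cosang = np.clip(dirs @ dirs.T, -1.0, 1.0)
        dup = np.argwhere(np.triu(cosang > 1 - 1e-12, k=1))
        if len(dup):
            pairs = [(int(i), int(j)) for i, j in dup]
            raise ValueError(f"duplicate channel directions at index pairs {pairs}")
        G = spline_g(cosang, self.m, self.tol)
        A = np.zeros((J + 1, J + 1))
        A[:J, :J] = G + self.ridge * np.eye(J)
        A[:J, J] = 1.0
        A[J, :J] = 1.0
        rhs = np.concatenate([w, [0.0]])
        sol = np.linalg.solve(A, rhs)
        # mixed-precision iterative refinement: the smooth kernel leaves G
        # ill-conditioned (near-duplicate directions give tiny eigenvalues
        # and huge coefficients), and channel reproduction error equals this
        # system's residual; extended-precision residuals push it to ~1e-10
        A_ld = A.astype(np.longdouble)
        rhs_ld = rhs.astype(np.longdouble)
        target = 1e-11 * max(float(np.linalg.norm(rhs)), 1.0)
        for _ in range(15):
            resid = np.asarray(rhs_ld - A_ld @ sol.astype(np.longdouble), dtype=float)
            sol = sol + np.linalg.solve(A, resid)
            if float(np.linalg.norm(resid)) <= target:
                break
        self.channel_dirs_ = dirs
        self.k_ = sol[:J]
        self.k0_ = float(sol[J])
        return self

    def predict(self, points: np.ndarray) -> np.ndarray:
        pts = self._check_unit(points, "evaluation points")
        cosang = np.clip(pts @ self.channel_dirs_.T, -1.0, 1.0)
        return self.k0_ + spline_g(cosang, self.m, self.tol) @ self.k_

    def to_mesh_image(
        self,
        mesh: ScalpMesh,
        mask: np.ndarray | None = None,
        subject_id: str = "",
    ) -> ContrastImage:
        """Evaluate the spline at (masked) mesh vertices."""
        mask = np.ones(mesh.n_vertices, bool) if mask is None else np.asarray(mask, bool)
        vals = np.full(mesh.n_vertices, np.nan)
        vals[mask] = self.predict(mesh.vertices[mask])
        return ContrastImage(
            space="mesh3d", values=vals, mask=mask, subject_id=subject_id, mesh=mesh
        )


# ---------------------------------------------------------------------------
# serialization


def write_image(img: ContrastImage, path) -> None:
    """Write grid images as NIfTI-1 and mesh images as GIfTI functional files."""
    path = str(path)
    if img.space == "grid2d":
        if not (path.endswith(".nii") or path.endswith(".nii.gz")):
            raise ValueError("grid2d images must be written as .nii/.nii.gz")
        ps = img.grid.pixel_size
        affine = np.diag([ps, ps, 1.0, 1.0])
        affine[0, 3] = -img.grid.extent + ps / 2.0
        affine[1, 3] = -img.grid.extent + ps / 2.0
        data = img.masked()[:, :, None]
        nimg = nib.Nifti1Image(data, affine)
        nimg.header["descrip"] = img.subject_id.encode()[:79]
        nib.save(nimg, path)
    elif img.space == "mesh3d":
        if not path.endswith(".gii"):
            raise ValueError("mesh3d images must be written as .gii")
        da = nib.gifti.GiftiDataArray(
            img.masked().astype(np.float32), intent="NIFTI_INTENT_NONE"
        )
        gimg = nib.gifti.GiftiImage(darrays=[da])
        gimg.meta["subject_id"] = img.subject_id
        gimg.meta["radius_mm"] = repr(float(img.mesh.radius)) if img.mesh else ""
        nib.save(gimg, path)
    else:  # pragma: no cover
        raise ValueError(f"unsupported space {img.space}")


def write_surface(mesh: ScalpMesh, path) -> None:
    """Write the scalp mesh as a GIfTI surface (.surf.gii convention)."""
    coords = nib.gifti.GiftiDataArray(
        mesh.scaled_vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))


def read_image(
    path, mesh: ScalpMesh | None = None
) -> ContrastImage:
    """Read a contrast image written by :func:`write_image`."""
    path = str(path)
    if path.endswith(".nii") or path.endswith(".nii.gz"):
        nimg = nib.load(path)
        data = np.asarray(nimg.dataobj, dtype=float)[:, :, 0]
        ps = float(nimg.affine[0, 0])
        n = data.shape[0]
        extent = n * ps / 2.0
        mask = np.isfinite(data)
        grid = ScalpGrid2D(n=n, extent=extent, mask=mask)
        sid = nimg.header["descrip"].tobytes().split(b"\x00")[0].decode()
        return ContrastImage(
            space="grid2d", values=data, mask=mask, subject_id=sid, grid=grid
        )
    if path.endswith(".gii"):
        gimg = nib.load(path)
        vals = np.asarray(gimg.darrays[0].data, dtype=float)
        mask = np.isfinite(vals)
        sid = dict(gimg.meta).get("subject_id", "")
        return ContrastImage(
            space="mesh3d", values=vals, mask=mask, subject_id=sid, mesh=mesh
        )
    raise ValueError(f"unsupported image extension: {path}")
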