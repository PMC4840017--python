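"""Second-level random effects and topological (RFT) inference.

Per-subject contrast images W_n = c^T beta_hat_n are stacked into the
summary-statistic model W = X_G beta_G + E*, where the mixed-effects error
variance sums within- and between-subject contributions.  Least squares gives
beta_hat_G = X_G^- W and a t-statistic per location; with a one-sample design
this collapses to the classical one-sample t with N - 1 degrees of freedom.

Family-wise error control over the scalp search region is offered through
(a) Bonferroni over channels and (b) random field theory over the image:
the expected Euler characteristic sum_d R_d rho_d(t) of the thresholded
t-field gives FWE p-values for peaks, and a stationary 2-D Gaussian-field
approximation gives cluster-extent p-values.  R_d are resel counts derived
from the residual smoothness (FWHM) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.optimize import brentq
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .interp import ContrastImage
from .scalp import ScalpGrid2D, ScalpMesh

__all__ = [
    "GroupDesign",
    "SecondLevelResult",
    "SecondLevelModel",
    "ReselInfo",
    "InferenceResult",
    "stack_contrasts",
    "fit_second_level",
    "bonferroni_threshold",
    "ec_density",
    "estimate_smoothness",
    "rft_peak_threshold",
    "peak_pvalue",
    "cluster_inference",
    "run_group_inference",
]


@dataclass
class GroupDesign:
    """Between-subject design X_G [N x P] with a contrast over its columns."""

    X_G: np.ndarray
    contrast_G: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X_G = np.atleast_2d(np.asarray(self.X_G, dtype=float))
        if self.X_G.shape[0] == 1 and self.X_G.shape[1] > 1:
            self.X_G = self.X_G.T
        self.contrast_G = np.asarray(self.contrast_G, dtype=float).ravel()
        N, P = self.X_G.shape
        if N <= P:
            raise ValueError("need more subjects than group-level parameters")
        if np.linalg.matrix_rank(self.X_G) < P:
            raise ValueError("group design matrix is rank deficient")
        if self.contrast_G.size != P:
            raise ValueError("group contrast length must equal P")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{n + 1:02d}" for n in range(N)]

    @classmethod
    def one_sample(cls, N: int, subject_ids: list[str] | None = None) -> "GroupDesign":
        return cls(
            X_G=np.ones((N, 1)),
            contrast_G=np.array([1.0]),
            subject_ids=subject_ids or [],
        )

    @property
    def dof(self) -> int:
        return self.X_G.shape[0] - self.X_G.shape[1]


@dataclass
class SecondLevelResult:
    beta_G: np.ndarray  # [P x n_locations]
    var_E: np.ndarray  # mixed-effects error variance per location
    T: np.ndarray  # t statistic per location (NaN where variance is zero)
    dof: int
    residuals: np.ndarray  # [N x n_locations]


def stack_contrasts(
    images: list[ContrastImage],
) -> tuple[np.ndarray, np.ndarray, ContrastImage]:
    """Stack subject images into W [N x n_locations] over the mask intersection.

    Returns (W, group_mask, reference image).  The group mask is the set of
    locations defined for every subject.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 subjects (between-subject variance)")
    space = images[0].space
    shape = images[0].values.shape
    mask = np.ones(shape, dtype=bool)
    for img in images:
        if img.space != space:
            raise ValueError("all images must share one space (grid2d or mesh3d)")
        if img.values.shape != shape:
            raise ValueError("image shapes differ")
        mask &= img.mask
    if not mask.any():
        raise ValueError("empty group mask: subject masks do not overlap")
    W = np.vstack([img.values[mask] for img in images])
    return W, mask, images[0]


class SecondLevelModel:
    """Summary-statistics random-effects fit (sklearn-style).

    ``fit(W, design)`` computes beta_hat_G = X_G^- W, the mixed-effects
    error variance Var[E*] = RSS/(N - P) per location, and the t-map
    T = c^T beta_hat_G / sqrt(Var[E*] c^T (X^T X)^-1 c).  Locations with zero
    residual variance get T = NaN (flagged, not an error).
    """

    def __init__(self, design: GroupDesign | None = None):
        self.design = design

    def fit(self, W: np.ndarray, design: GroupDesign | None = None) -> "SecondLevelModel":
        design = design or self.design
        if design is None:
            design = GroupDesign.one_sample(np.atleast_2d(W).shape[0])
        W = np.atleast_2d(np.asarray(W, dtype=float))
        X = design.X_G
        N, P = X.shape
        if W.shape[0] != N:
            raise ValueError(f"W has {W.shape[0]} rows but design expects {N}")
        pinv = np.linalg.pinv(X)
        beta = pinv @ W
        resid = W - X @ beta
        var_E = np.sum(resid**2, axis=0) / (N - P)
        c = design.contrast_G
        gram_inv = np.linalg.inv(X.T @ X)
        c_var = float(c @ gram_inv @ c)
        # variance indistinguishable from zero at machine precision -> T undefined
        scale = np.max(np.abs(W), axis=0, initial=0.0)
        degenerate = var_E <= (1e-10 * np.maximum(scale, 1e-300)) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            T = (c @ beta) / np.sqrt(var_E * c_var)
        T = np.where(degenerate, np.nan, T)
        self.design_ = design
        self.result_ = SecondLevelResult(
            beta_G=beta, var_E=var_E, T=T, dof=design.dof, residuals=resid
        )
        return self

    @property
    def T_(self) -> np.ndarray:
        return self.result_.T


def fit_second_level(W: np.ndarray, design: GroupDesign) -> SecondLevelResult:
    return SecondLevelModel(design).fit(W).result_


def bonferroni_threshold(alpha: float, n_tests: int, dof: int) -> float:
    """One-sided t threshold controlling FWE over n_tests channels."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(t_dist.isf(alpha / n_tests, dof))


def ec_density(t: float, dof: float, d: int) -> float:
    """Euler-characteristic density rho_d of a t-field (Worsley form).

    d = 0: upper-tail t probability; d = 1, 2: the standard closed forms for
    1- and 2-dimensional resel contributions.  Scalp surfaces are
    2-manifolds, so d > 2 is unsupported.
    """
    if d == 0:
        return float(t_dist.sf(t, dof))
    v = float(dof)
    base = (1.0 + t * t / v) ** (-(v - 1.0) / 2.0)
    if d == 1:
        return float(np.sqrt(4.0 * np.log(2.0)) / (2.0 * np.pi) * base)
    if d == 2:
        lg = gammaln((v + 1.0) / 2.0) - gammaln(v / 2.0)
        c = np.exp(lg) / np.sqrt(v / 2.0)
        return float(
            (4.0 * np.log(2.0)) / (2.0 * np.pi) ** 1.5 * c * t * base
        )
    raise ValueError("EC densities implemented for d in {0, 1, 2} only")


@dataclass
class ReselInfo:
    """Resolution-element summary of the search region."""

    fwhm_est: tuple[float, ...]  # mm per dimension
    resel_counts: tuple[float, float, float]  # (R_0, R_1, R_2)
    search_volume: int  # pixels or vertices in the mask
    element_area: float  # mm^2 per pixel, or total mesh area / n_vertices

    @property
    def fwhm_mean(self) -> float:
        return float(np.exp(np.mean(np.log(self.fwhm_est))))

    @property
    def resels(self) -> float:
        return self.resel_counts[2]


def _grid_euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic of the pixel cubical complex."""
    m = mask.astype(int)
    v = int(m.sum())
    e = int((m[1:] & m[:-1]).sum() + (m[:, 1:] & m[:, :-1]).sum())
    f = int((m[1:, 1:] & m[1:, :-1] & m[:-1, 1:] & m[:-1, :-1]).sum())
    return v - e + f


def _grid_perimeter(mask: np.ndarray, ps: float) -> float:
    pad = np.pad(mask, 1, constant_values=False)
    edges = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int((pad & ~np.roll(pad, shift, axis=ax)).sum())
    return edges * ps


def estimate_smoothness(
    residuals: np.ndarray,
    mask: np.ndarray,
    geometry: ScalpGrid2D | ScalpMesh,
) -> ReselInfo:
    """Residual smoothness (FWHM) and resel counts of the search region.

    ``residuals`` is [N x n_mask_locations] from the second-level fit.  They
    are standardized per location (unit sum of squares over subjects); the
    variance of their spatial derivatives gives the smoothness via
    FWHM = sqrt(4 ln 2 / var(dU/dx)) per dimension, and the resel counts
    follow the standard construction: R_2 = area / prod(FWHM),
    R_1 = half-perimeter / FWHM, R_0 = Euler characteristic of the mask.
    """
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    if R.shape[0] < 2:
        raise ValueError("need at least 2 residual images")
    ss = np.sqrt(np.sum(R**2, axis=0))
    ss = np.where(ss > 0, ss, np.inf)
    U = R / ss

    if isinstance(geometry, ScalpGrid2D):
        ps = geometry.pixel_size
        n = geometry.n
        lam = []
        for ax in (0, 1):
            total, count = 0.0, 0
            full = np.full((R.shape[0], n, n), np.nan)
            full[:, mask] = U
            a = full[:, :-1, :] if ax == 0 else full[:, :, :-1]
            b = full[:, 1:, :] if ax == 0 else full[:, :, 1:]
            d = (b - a) / ps
            valid = np.isfinite(d).all(axis=0)
            count = int(valid.sum())
            total = float(np.sum(d[:, valid] ** 2))
            lam.append(total / count if count else 0.0)
        fwhm = tuple(
            float(np.sqrt(4.0 * np.log(2.0) / l)) if l > 0 else np.inf for l in lam
        )
        area = float(mask.sum()) * ps * ps
        fgeo = float(np.sqrt(fwhm[0] * fwhm[1]))
        R2 = area / (fwhm[0] * fwhm[1]) if np.isfinite(fgeo) else 0.0
        R1 = _grid_perimeter(mask, ps) / 2.0 / fgeo if np.isfinite(fgeo) else 0.0
        R0 = float(_grid_euler_characteristic(mask))
        return ReselInfo(
            fwhm_est=fwhm,
            resel_counts=(R0, float(R1), float(R2)),
            search_volume=int(mask.sum()),
            element_area=ps * ps,
        )

    mesh = geometry
    full = np.full((R.shape[0], mesh.n_vertices), np.nan)
    full[:, mask] = U
    edges = mesh.edges()
    both = mask[edges[:, 0]] & mask[edges[:, 1]]
    e = edges[both]
    v = mesh.scaled_vertices
    elen = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    d = (full[:, e[:, 0]] - full[:, e[:, 1]]) / elen
    lam = float(np.mean(np.sum(d**2, axis=0))) if len(e) else 0.0
    fwhm_val = float(np.sqrt(4.0 * np.log(2.0) / lam)) if lam > 0 else np.inf
    face_in = mask[mesh.faces].all(axis=1)
    area = float(mesh.triangle_areas()[face_in].sum())
    # boundary: masked edges adjacent to fewer than two masked faces
    face_edges = np.sort(
        np.vstack(
            [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
        ),
        axis=1,
    )
    face_edge_in = np.concatenate([face_in, face_in, face_in])
    uniq, inv = np.unique(face_edges, axis=0, return_inverse=True)
    counts = np.bincount(inv[face_edge_in], minlength=len(uniq))
    uniq_mask = mask[uniq[:, 0]] & mask[uniq[:, 1]]
    boundary = uniq[(counts < 2) & uniq_mask]
    blen = float(np.linalg.norm(v[boundary[:, 0]] - v[boundary[:, 1]], axis=1).sum())
    n_v = int(mask.sum())
    n_e = int(both.sum())
    n_f = int(face_in.sum())
    chi = float(n_v - n_e + n_f)
    if np.isfinite(fwhm_val):
        R2 = area / fwhm_val**2
        R1 = blen / 2.0 / fwhm_val
    else:
        R2 = R1 = 0.0
    return ReselInfo(
        fwhm_est=(fwhm_val, fwhm_val),
        resel_counts=(chi, float(R1), float(R2)),
        search_volume=n_v,
        element_area=area / max(n_v, 1),
    )


def _ec_sum(t: float, resels: ReselInfo, dof: float) -> float:
    R0, R1, R2 = resels.resel_counts
    return (
        R0 * ec_density(t, dof, 0)
        + R1 * ec_density(t, dof, 1)
        + R2 * ec_density(t, dof, 2)
    )


def rft_peak_threshold(alpha: float, resels: ReselInfo, dof: float) -> float:
    """Smallest t whose expected Euler characteristic is at most alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    def f(t: float) -> float:
        return _ec_sum(t, resels, dof) - alpha

    lo, hi = 1e-3, 100.0
    if f(hi) > 0:
        raise ValueError(
            "requested alpha unreachable: expected EC exceeds alpha even at "
            "t = 100 (huge resel count or tiny dof)"
        )
    if f(lo) < 0:
        return lo
    return float(brentq(f, lo, hi, xtol=1e-8))


def peak_pvalue(t: float, resels: ReselInfo, dof: float) -> float:
    """FWE-corrected peak p-value: min(1, sum_d R_d rho_d(t))."""
    return float(min(1.0, max(_ec_sum(t, resels, dof), 0.0)))


def _grid_clusters(T_full: np.ndarray, thresh: float) -> list[np.ndarray]:
    exc = np.isfinite(T_full) & (T_full >= thresh)
    labels, n = ndimage.label(exc, structure=np.ones((3, 3), dtype=int))
    return [np.argwhere(labels == k + 1) for k in range(n)]


def _mesh_clusters(
    T_vert: np.ndarray, thresh: float, mesh: ScalpMesh
) -> list[np.ndarray]:
    exc = np.isfinite(T_vert) & (T_vert >= thresh)
    idx = np.flatnonzero(exc)
    if len(idx) == 0:
        return []
    pos = -np.ones(len(T_vert), dtype=int)
    pos[idx] = np.arange(len(idx))
    edges = mesh.edges()
    keep = exc[edges[:, 0]] & exc[edges[:, 1]]
    e = edges[keep]
    graph = sparse.coo_matrix(
        (np.ones(len(e)), (pos[e[:, 0]], pos[e[:, 1]])), shape=(len(idx), len(idx))
    )
    n, labels = connected_components(graph, directed=False)
    return [idx[labels == k] for k in range(n)]


@dataclass
class InferenceResult:
    """Thresholds, peaks and clusters of a group-level t-map."""

    alpha: float
    method: str  # "rft" | "bonferroni"
    space: str
    T_c: float
    dof: int
    peaks: list[dict]
    clusters: list[dict]
    resels: ReselInfo | None = None
    T_map: np.ndarray | None = None
    mask: np.ndarray | None = None

    def to_table(self) -> pd.DataFrame:
        rows = []
        resels = round(self.resels.resels, 1) if self.resels else np.nan
        records = self.clusters if self.clusters else [{}]
        for cl in records:
            rows.append(
                {
                    "method": self.method,
                    "space": self.space,
                    "RESELS": resels,
                    "T_c": round(self.T_c, 2),
                    "cluster_p_FWE": cl.get("p_FWE", np.nan),
                    "k_E": cl.get("k_E", np.nan),
                    "peak_p_FWE": cl.get("peak_p_FWE", np.nan),
                    "T": cl.get("peak_T", np.nan),
                }
            )
        return pd.DataFrame(rows)


def cluster_inference(
    T_map: np.ndarray,
    T_c: float,
    resels: ReselInfo,
    dof: float,
    geometry: ScalpGrid2D | ScalpMesh,
) -> list[dict]:
    """Connected components of the excursion set with extent FWE p-values.

    Cluster extents use the stationary 2-D Gaussian-field approximation:
    the expected number of clusters E[m] is the EC sum at T_c, the expected
    suprathreshold volume is the search volume times the height tail
    probability, and extents are taken exponential,
    P(n >= k) = exp(-k / E[n]); the cluster FWE p-value is
    1 - exp(-E[m] P(n >= k)).
    """
    if isinstance(geometry, ScalpGrid2D):
        comps = _grid_clusters(T_map, T_c)
    else:
        comps = _mesh_clusters(T_map, T_c, geometry)
    E_m = max(_ec_sum(T_c, resels, dof), 1e-12)
    E_N = resels.search_volume * ec_density(T_c, dof, 0)
    E_n = max(E_N / E_m, 1e-12)
    clusters = []
    for comp in comps:
        if isinstance(geometry, ScalpGrid2D):
            vals = T_map[comp[:, 0], comp[:, 1]]
            k = len(comp)
            imax = int(np.argmax(vals))
            loc = tuple(int(x) for x in comp[imax])
        else:
            vals = T_map[comp]
            k = len(comp)
            imax = int(np.argmax(vals))
            loc = int(comp[imax])
        peak_T = float(vals[imax])
        # x = E[m] P(n >= k) in log space to survive extreme thresholds
        log_x = np.log(E_m) - k / E_n
        if log_x < -30.0:
            p_cl = float(np.exp(log_x))  # 1 - exp(-x) ~ x
        else:
            p_cl = float(-np.expm1(-np.exp(log_x)))
        clusters.append(
            {
                "k_E": int(k),
                "p_FWE": min(max(p_cl, np.finfo(float).tiny), 1.0),
                "peak_T": peak_T,
                "peak_loc": loc,
                "peak_p_FWE": peak_pvalue(peak_T, resels, dof),
            }
        )
    clusters.sort(key=lambda c: -c["peak_T"])
    return clusters


def run_group_inference(
    images: list[ContrastImage] | None,
    design: GroupDesign,
    alpha: float = 0.05,
    method: str = "rft",
    channel_values: np.ndarray | None = None,
) -> InferenceResult:
    """Second-level fit plus FWE-controlled inference.

    ``method="rft"`` runs on interpolated images: smoothness estimation,
    peak threshold at ``alpha`` and peak/cluster records.  ``method=
    "bonferroni"`` runs channel-wise on ``channel_values`` [N x J].
    """
    if method == "bonferroni":
        if channel_values is None:
            raise ValueError("bonferroni route needs channel_values [N x J]")
        W = np.atleast_2d(np.asarray(channel_values, dtype=float))
        res = fit_second_level(W, design)
        T_c = bonferroni_threshold(alpha, W.shape[1], res.dof)
        peaks = [
            {
                "channel": int(j),
                "T": float(res.T[j]),
                "p_FWE": float(min(1.0, W.shape[1] * t_dist.sf(res.T[j], res.dof))),
            }
            for j in np.flatnonzero(np.nan_to_num(res.T, nan=-np.inf) >= T_c)
        ]
        return InferenceResult(
            alpha=alpha,
            method="bonferroni",
            space="channels",
            T_c=T_c,
            dof=res.dof,
            peaks=peaks,
            clusters=[],
            T_map=res.T,
        )
    if method != "rft":
        raise ValueError("method must be 'rft' or 'bonferroni'")
    W, mask, ref = stack_contrasts(images)
    res = fit_second_level(W, design)
    geometry = ref.grid if ref.space == "grid2d" else ref.mesh
    resels = estimate_smoothness(res.residuals, mask, geometry)
    T_c = rft_peak_threshold(alpha, resels, res.dof)
    T_full = np.full(mask.shape, np.nan)
    T_full[mask] = res.T
    clusters = cluster_inference(T_full, T_c, resels, res.dof, geometry)
    peaks = [
        {"location": c["peak_loc"], "T": c["peak_T"], "p_FWE": c["peak_p_FWE"]}
        for c in clusters
    ]
    return InferenceResult(
        alpha=alpha,
        method="rft",
        space=ref.space,
        T_c=T_c,
        dof=res.dof,
        peaks=peaks,
        clusters=clusters,
        resels=resels,
        T_map=T_full,
        mask=mask,
    )
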