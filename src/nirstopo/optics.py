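"""Modified Beer-Lambert law conversions between optical density and hemoglobin.

Continuous-wave fNIRS measures optical-density changes :math:`\\Delta\\phi` at two
wavelengths.  Under the modified Beer-Lambert law these are linear in the
concentration changes of oxy- (HbO, :math:`\\Delta H`) and deoxy-hemoglobin
(HbR, :math:`\\Delta Q`):

.. math::

    \\Delta\\phi(\\lambda) = (\\alpha_H(\\lambda)\\,\\Delta H +
        \\alpha_Q(\\lambda)\\,\\Delta Q)\\, d(\\lambda, a)\\, l,

where :math:`\\alpha` are molar absorption coefficients [mM^-1 cm^-1],
:math:`d` is the differential pathlength factor (DPF, dimensionless, a function
of wavelength and subject age) and :math:`l` the source-detector separation
[cm].  Measurements at two wavelengths invert to :math:`(\\Delta H, \\Delta Q)`
through a 2x2 linear system whose determinant
:math:`c = \\alpha_H(\\lambda_1)\\alpha_Q(\\lambda_2) -
\\alpha_H(\\lambda_2)\\alpha_Q(\\lambda_1)` must be nonzero.

Units are fixed: concentrations in mM, distances in cm; no silent rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .scalp import ProbeLayout

__all__ = [
    "MbllCoefficients",
    "OpticalRecording",
    "HbSeries",
    "EXTINCTION_TABLE",
    "get_dpf",
    "get_extinction",
    "od_to_hb",
    "hb_to_od",
]

#: Molar absorption coefficients [mM^-1 cm^-1] for (HbO, HbR) at common fNIRS
#: wavelengths, derived from the Gratzer/Prahl compilation of hemoglobin
#: spectra (values rounded to ~1%).  Overridable: any MbllCoefficients may be
#: constructed with user-supplied values.
EXTINCTION_TABLE: dict[int, tuple[float, float]] = {
    690: (0.2763, 2.0520),
    695: (0.3124, 1.9242),
    750: (0.5180, 1.4052),
    760: (0.5863, 1.5486),
    780: (0.7100, 1.0754),
    808: (0.8654, 0.7408),
    830: (0.9740, 0.6930),
    850: (1.0580, 0.6913),
}

# Scholkmann & Wolf (2013) general DPF formula coefficients; validity range nm.
_GENERAL_DPF_RANGE = (690.0, 880.0)


def get_extinction(wavelength: float) -> tuple[float, float]:
    """Return tabulated ``(alpha_H, alpha_Q)`` [mM^-1 cm^-1] for a wavelength.

    Raises ``KeyError`` naming the available wavelengths when untabulated.
    """
    key = int(round(wavelength))
    if key not in EXTINCTION_TABLE:
        raise KeyError(
            f"no extinction coefficients tabulated for {wavelength} nm; "
            f"available: {sorted(EXTINCTION_TABLE)}"
        )
    return EXTINCTION_TABLE[key]


def get_dpf(wavelength: float, age: float = 30.0, model: object = "general") -> float:
    """Differential pathlength factor d(lambda, age).

    Parameters
    ----------
    wavelength : float
        Wavelength in nm.
    age : float
        Subject age in years (>= 0).
    model : "general" or dict
        ``"general"`` evaluates the published age- and wavelength-dependent
        polynomial fit valid for 690-880 nm (Scholkmann & Wolf 2013).  A dict
        ``{wavelength_nm: dpf}`` acts as a constant lookup table (age ignored).

    Returns
    -------
    float
        Dimensionless pathlength factor, > 0.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if isinstance(model, dict):
        key = int(round(wavelength))
        if key not in model:
            raise ValueError(
                f"wavelength {wavelength} nm not in DPF table; "
                f"valid entries: {sorted(model)}"
            )
        return float(model[key])
    if model != "general":
        raise ValueError(f"unknown DPF model: {model!r}")
    lo, hi = _GENERAL_DPF_RANGE
    if not (lo <= wavelength <= hi):
        raise ValueError(
            f"wavelength {wavelength} nm outside the general DPF model's "
            f"validity range [{lo}, {hi}] nm"
        )
    lam = float(wavelength)
    return float(
        223.3
        + 0.05624 * age**0.8493
        - 5.723e-7 * lam**3
        + 0.001245 * lam**2
        - 0.9025 * lam
    )


@dataclass(frozen=True)
class MbllCoefficients:
    """Coefficients of the two-wavelength modified Beer-Lambert system.

    alpha_H, alpha_Q : (2,) arrays, molar absorption [mM^-1 cm^-1] of HbO/HbR
    at ``wavelengths``; dpf : (2,) pathlength factors; distance_l : cm.
    """

    alpha_H: np.ndarray
    alpha_Q: np.ndarray
    wavelengths: tuple[float, float]
    dpf: np.ndarray
    distance_l: float

    def __post_init__(self) -> None:
        for name in ("alpha_H", "alpha_Q", "dpf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (2,):
                raise ValueError(f"{name} must have shape (2,), got {arr.shape}")
            object.__setattr__(self, name, arr)
        if self.distance_l <= 0:
            raise ValueError("source-detector distance must be > 0 cm")
        if np.any(self.dpf <= 0):
            raise ValueError("DPF values must be > 0")
        if abs(self.determinant) < self._singular_tol():
            raise ValueError(
                "extinction-coefficient matrix is numerically singular "
                f"(|c| = {abs(self.determinant):.3e}); the two wavelengths do "
                "not separate HbO from HbR"
            )

    @property
    def determinant(self) -> float:
        """c = alpha_H(l1) alpha_Q(l2) - alpha_H(l2) alpha_Q(l1)."""
        return float(
            self.alpha_H[0] * self.alpha_Q[1] - self.alpha_H[1] * self.alpha_Q[0]
        )

    def _singular_tol(self) -> float:
        scale = float(np.max(np.abs(self.alpha_H)) * np.max(np.abs(self.alpha_Q)))
        return 1e-12 * max(scale, 1.0)

    @classmethod
    def from_tables(
        cls,
        wavelengths: tuple[float, float] = (695.0, 830.0),
        age: float = 30.0,
        distance_l: float = 3.0,
        dpf_model: object = "general",
    ) -> "MbllCoefficients":
        """Build coefficients from the shipped extinction table and DPF model."""
        aH, aQ = zip(*(get_extinction(w) for w in wavelengths))
        dpf = [get_dpf(w, age, dpf_model) for w in wavelengths]
        return cls(
            alpha_H=np.array(aH),
            alpha_Q=np.array(aQ),
            wavelengths=tuple(float(w) for w in wavelengths),
            dpf=np.array(dpf),
            distance_l=float(distance_l),
        )


@dataclass
class OpticalRecording:
    """Optical-density changes at two wavelengths, time x channel.

    ``od`` has shape (2, M, J): one M x J plane per wavelength.
    """

    od: np.ndarray
    fs: float
    channel_ids: list[str]
    wavelengths: tuple[float, float] = (695.0, 830.0)
    layout: "ProbeLayout | None" = None

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[0] != 2:
            raise ValueError(
                f"od must have shape (2, M, J); got {self.od.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling frequency must be > 0")
        if self.od.shape[2] != len(self.channel_ids):
            raise ValueError("channel_ids length must match od's channel axis")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("duplicate channel labels")

    @property
    def n_samples(self) -> int:
        return self.od.shape[1]

    @property
    def n_channels(self) -> int:
        return self.od.shape[2]


@dataclass
class HbSeries:
    """Hemoglobin concentration changes [mM], time x channel."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError(
                f"hbo {self.hbo.shape} and hbr {self.hbr.shape} shapes differ"
            )
        if self.fs <= 0:
            raise ValueError("sampling frequency must be > 0")
        if not self.channel_ids:
            self.channel_ids = [f"CH{j + 1}" for j in range(self.hbo.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    def chromophore(self, which: str) -> np.ndarray:
        if which not in ("hbo", "hbr"):
            raise ValueError("chromophore must be 'hbo' or 'hbr'")
        return getattr(self, which)


def _design_matrix(coeffs: MbllCoefficients) -> np.ndarray:
    """2x2 matrix A with Delta-phi = A @ (dH, dQ); rows are wavelengths."""
    d = coeffs.dpf
    l = coeffs.distance_l
    return np.array(
        [
            [coeffs.alpha_H[0] * d[0] * l, coeffs.alpha_Q[0] * d[0] * l],
            [coeffs.alpha_H[1] * d[1] * l, coeffs.alpha_Q[1] * d[1] * l],
        ]
    )


def od_to_hb(rec: OpticalRecording, coeffs: MbllCoefficients) -> HbSeries:
    """Invert the two-wavelength Beer-Lambert system per sample and channel."""
    A = _design_matrix(coeffs)
    # stack wavelength planes as trailing axis and solve the shared 2x2 system
    phi = np.stack([rec.od[0], rec.od[1]], axis=-1)  # (M, J, 2)
    sol = np.linalg.solve(A[None, None, :, :], phi[..., None])[..., 0]
    return HbSeries(
        hbo=sol[..., 0], hbr=sol[..., 1], fs=rec.fs, channel_ids=list(rec.channel_ids)
    )


def hb_to_od(
    hb: HbSeries,
    coeffs: MbllCoefficients,
    layout: "ProbeLayout | None" = None,
) -> OpticalRecording:
    """Forward Beer-Lambert model: concentrations to optical-density changes."""
    A = _design_matrix(coeffs)
    conc = np.stack([hb.hbo, hb.hbr], axis=-1)  # (M, J, 2)
    phi = conc @ A.T  # (M, J, 2), wavelength last
    return OpticalRecording(
        od=np.moveaxis(phi, -1, 0),
        fs=hb.fs,
        channel_ids=list(hb.channel_ids),
        wavelengths=coeffs.wavelengths,
        layout=layout,
    )
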