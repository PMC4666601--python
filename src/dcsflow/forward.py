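"""Semi-infinite correlation-diffusion forward model for DCS.

Diffuse correlation spectroscopy (DCS) measures the temporal intensity
autocorrelation function g2(tau) of multiply scattered coherent
near-infrared light. For a point source on a semi-infinite homogeneous
turbid medium with Brownian scatterer dynamics, the normalized field
autocorrelation g1(tau) has the closed extrapolated-boundary form

    K(tau) = sqrt(3*mua*musp + 6*musp^2*k0^2*BFI*tau),   k0 = 2*pi*n/lambda
    G1(tau) = exp(-K*r1)/r1 - exp(-K*r2)/r2,             g1 = G1(tau)/G1(0)

where r1/r2 are the distances from the detector to the (isotropic) source
at depth z0 = 1/(mua+musp) and to its negative image at z0 + 2*zb, and
zb = (2/(3*musp))*(1+Reff)/(1-Reff) is the extrapolated-boundary offset
set by the effective reflection coefficient Reff of the tissue/air
interface. The measured g2 follows from g1 via the Siegert relation
g2 = 1 + beta*g1^2 with the detection coherence factor beta.

Units: lengths in cm, mua/musp in 1/cm, tau in s, BFI (= alpha*D_B, the
blood flow index) in cm^2/s. Wavelength is taken in nm and converted
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import NumericalError

__all__ = [
    "OpticalProperties",
    "LagGrid",
    "FlowModel",
    "effective_reflection_coefficient",
    "g1_semi_infinite",
    "g2_siegert",
]

_NM_PER_CM = 1e7


@dataclass(frozen=True)
class OpticalProperties:
    """Assumed tissue optical constants entering the forward model.

    The defaults (mua = 0.10 /cm, musp = 10 /cm at 785 nm, n = 1.37 against
    air) are canonical near-infrared soft-tissue values; absolute BFI is
    sensitive to them, relative blood flow much less so.
    """

    mua: float = 0.10          # absorption coefficient, 1/cm
    musp: float = 10.0         # reduced scattering coefficient, 1/cm
    n_tissue: float = 1.37     # tissue refractive index
    n_outside: float = 1.0     # external (coupling) refractive index
    wavelength_nm: float = 785.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mua) and self.mua > 0):
            raise ValueError(f"mua must be positive and finite, got {self.mua}")
        if not (math.isfinite(self.musp) and self.musp > 0):
            raise ValueError(f"musp must be positive and finite, got {self.musp}")
        if self.musp <= self.mua:
            raise ValueError(
                f"diffusion regime requires musp > mua, got musp={self.musp}, mua={self.mua}"
            )
        if self.n_tissue < 1 or self.n_outside < 1:
            raise ValueError("refractive indices must be >= 1")
        if not (math.isfinite(self.wavelength_nm) and self.wavelength_nm > 0):
            raise ValueError(f"wavelength_nm must be positive, got {self.wavelength_nm}")

    @property
    def wavelength_cm(self) -> float:
        return self.wavelength_nm / _NM_PER_CM

    @property
    def k0(self) -> float:
        """Optical wavenumber in the tissue, 1/cm."""
        return 2.0 * math.pi * self.n_tissue / self.wavelength_cm

    @property
    def n_rel(self) -> float:
        """Refractive index ratio n_tissue / n_outside."""
        return self.n_tissue / self.n_outside


@dataclass(frozen=True)
class LagGrid:
    """Strictly increasing positive correlator lag times, in seconds."""

    lags_s: NDArray[np.float64]

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_s, dtype=np.float64)
        object.__setattr__(self, "lags_s", lags)
        if lags.ndim != 1 or lags.size == 0:
            raise ValueError("lag grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(lags)):
            raise ValueError("lag grid contains non-finite values")
        if lags[0] <= 0 or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and positive")

    def __len__(self) -> int:
        return int(self.lags_s.size)


@dataclass(frozen=True)
class FlowModel:
    """Brownian-dynamics flow parameters: BFI = alpha*D_B (cm^2/s) and beta.

    Only the product alpha*D_B (fraction of moving scatterers times their
    effective Brownian diffusion coefficient) is identifiable from g2.
    """

    bfi: float
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.bfi) and self.bfi >= 0):
            raise ValueError(f"bfi must be non-negative and finite, got {self.bfi}")
        if not (0 < self.beta <= 1):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")


def effective_reflection_coefficient(n_rel: float) -> float:
    """Effective reflection coefficient Reff of the boundary for index ratio n_rel.

    Standard polynomial approximation
    Reff = -1.440*n_rel^-2 + 0.710*n_rel^-1 + 0.668 + 0.0636*n_rel,
    clipped to [0, 0.999]. For tissue against air (n_rel ~ 1.4) this gives
    the widely used Reff ~ 0.53.
    """
    if not (np.isfinite(n_rel) and n_rel > 0):
        raise ValueError(f"n_rel must be positive and finite, got {n_rel}")
    reff = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return float(min(max(reff, 0.0), 0.999))


def semi_infinite_geometry(optics: OpticalProperties, rho: float) -> tuple[float, float, float, float]:
    """Precompute the scalar constants (a, b, r1, r2) of the semi-infinite model.

    K(tau)^2 = a + b*bfi*tau with a = 3*mua*musp and b = 6*musp^2*k0^2;
    r1/r2 are the real/image source distances for source-detector
    separation ``rho`` (cm). Shared by the forward model and the fast
    fitting kernel.
    """
    if not (np.isfinite(rho) and rho > 0):
        raise ValueError(f"rho must be positive and finite, got {rho}")
    reff = effective_reflection_coefficient(optics.n_rel)
    z0 = 1.0 / (optics.mua + optics.musp)   # transport depth of the isotropic source
    zb = (2.0 / (3.0 * optics.musp)) * (1.0 + reff) / (1.0 - reff)
    r1 = math.sqrt(rho**2 + z0**2)
    r2 = math.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)
    a = 3.0 * optics.mua * optics.musp
    b = 6.0 * optics.musp**2 * optics.k0**2
    return a, b, r1, r2


def _g1_from_geometry(
    lags: NDArray[np.float64], a: float, b: float, r1: float, r2: float, bfi: float
) -> NDArray[np.float64]:
    K = np.sqrt(a + b * bfi * lags)
    k0_static = math.sqrt(a)
    g1_0 = math.exp(-k0_static * r1) / r1 - math.exp(-k0_static * r2) / r2
    assert g1_0 > 0, "G1(0) must be positive for a semi-infinite medium"
    g1 = (np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2) / g1_0
    if not np.all(np.isfinite(g1)):
        raise NumericalError(
            f"non-finite g1 for a={a}, b={b}, r1={r1}, r2={r2}, bfi={bfi}"
        )
    return g1


def g1_semi_infinite(
    lags: LagGrid | ArrayLike,
    optics: OpticalProperties,
    rho: float,
    flow: FlowModel,
) -> NDArray[np.float64]:
    """Normalized field autocorrelation g1(tau) on a semi-infinite medium.

    Parameters
    ----------
    lags
        Lag times in seconds (``LagGrid`` or array-like).
    optics
        Assumed tissue optical properties.
    rho
        Source-detector separation in cm.
    flow
        Brownian flow model; only ``flow.bfi`` enters g1.

    Returns
    -------
    g1 values in (0, 1], non-increasing in tau, with g1 -> 1 as tau -> 0.
    """
    tau = lags.lags_s if isinstance(lags, LagGrid) else np.asarray(lags, dtype=np.float64)
    a, b, r1, r2 = semi_infinite_geometry(optics, rho)
    return _g1_from_geometry(tau, a, b, r1, r2, flow.bfi)


def g2_siegert(g1_values: ArrayLike, beta: float) -> NDArray[np.float64]:
    """Siegert relation: g2 = 1 + beta*g1^2 for coherence factor beta in (0, 1]."""
    if not (np.isfinite(beta) and 0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    g1 = np.asarray(g1_values, dtype=np.float64)
    return 1.0 + beta * g1**2
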