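"""Laminar-flow characterization of rectangular-duct microfluidic devices.

The swimming arena and the stimulus-delivery front channel are both
rectangular ducts carrying slow, steady flow.  Two dimensionless numbers
summarize the transport regime:

* the Reynolds number ``Re = rho * v * D_H / mu`` (inertial vs. viscous
  forces; ``Re << 2000`` implies laminar flow), and
* the Peclet number ``Pe = v * D_H / D`` (advective vs. diffusive solute
  transport; ``Pe >> 1`` implies negligible cross-stream diffusion),

with the hydraulic diameter ``D_H = 2ab/(a+b)`` of a duct of cross-section
``a x b`` as the characteristic length.  Together they predict that a
chemical stream infused through one inlet stays confined to a sharply
bordered zone.  Border sharpness is quantified empirically from intensity
line profiles taken along normals to the border.

All functions take SI units; converters at the CLI boundary accept mm and
uL/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelSpec",
    "DimensionlessNumbers",
    "BorderProfile",
    "hydraulic_diameter",
    "mean_velocity",
    "reynolds",
    "peclet",
    "characterize_channel",
    "border_sharpness",
    "DegenerateProfileError",
]

UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0
MM_TO_M = 1e-3


class DegenerateProfileError(ValueError):
    """Raised when a line profile has no dynamic range across the border."""


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular-duct geometry plus fluid constants, all SI.

    Parameters
    ----------
    a, b:
        Cross-section dimensions (m).
    q_inlet:
        Volumetric flow per inlet (m^3/s).
    n_inlets:
        Number of inlets feeding the duct.
    rho:
        Fluid density (kg/m^3).
    mu:
        Dynamic viscosity (Pa s).
    diffusivity:
        Solute diffusion coefficient (m^2/s).
    """

    a: float
    b: float
    q_inlet: float
    n_inlets: int
    rho: float
    mu: float
    diffusivity: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("cross-section dimensions must be positive")
        if self.q_inlet < 0:
            raise ValueError("q_inlet must be non-negative")
        if self.n_inlets < 1:
            raise ValueError("n_inlets must be >= 1")
        if self.rho <= 0 or self.mu <= 0 or self.diffusivity <= 0:
            raise ValueError("rho, mu and diffusivity must be positive")

    @classmethod
    def from_lab_units(
        cls,
        a_mm: float,
        b_mm: float,
        q_inlet_ul_min: float,
        n_inlets: int,
        rho: float,
        mu: float,
        diffusivity: float,
    ) -> "ChannelSpec":
        """Build a spec from bench units (mm, uL/min); rho/mu/D stay SI."""
        return cls(
            a=a_mm * MM_TO_M,
            b=b_mm * MM_TO_M,
            q_inlet=q_inlet_ul_min * UL_PER_MIN_TO_M3_PER_S,
            n_inlets=n_inlets,
            rho=rho,
            mu=mu,
            diffusivity=diffusivity,
        )


@dataclass(frozen=True)
class DimensionlessNumbers:
    """Hydraulic diameter, mean velocity and the Re/Pe pair for one duct."""

    d_h: float
    velocity: float
    reynolds: float
    peclet: float


def hydraulic_diameter(a: float, b: float) -> float:
    """Hydraulic diameter ``2ab/(a+b)`` of a rectangular duct (m).

    Symmetric in ``(a, b)``; equals ``a`` for a square duct.
    """
    if a <= 0 or b <= 0:
        raise ValueError("duct dimensions must be positive")
    return 2.0 * a * b / (a + b)


def mean_velocity(q_inlet: float, n_inlets: int, a: float, b: float) -> float:
    """Cross-section-averaged flow velocity (m/s).

    Total volumetric rate ``q_inlet * n_inlets`` divided by the duct
    cross-sectional area ``a * b``.
    """
    if a <= 0 or b <= 0:
        raise ValueError("duct dimensions must be positive")
    if q_inlet < 0:
        raise ValueError("q_inlet must be non-negative")
    if n_inlets < 1:
        raise ValueError("n_inlets must be >= 1")
    return q_inlet * n_inlets / (a * b)


def reynolds(rho: float, velocity: float, d_h: float, mu: float) -> float:
    """Reynolds number ``rho * v * D_H / mu`` (dimensionless)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if rho <= 0:
        raise ValueError("rho must be positive")
    if velocity < 0 or d_h < 0:
        raise ValueError("velocity and d_h must be non-negative")
    return rho * velocity * d_h / mu


def peclet(velocity: float, d_h: float, diffusivity: float) -> float:
    """Peclet number ``v * D_H / D`` (dimensionless)."""
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if velocity < 0 or d_h < 0:
        raise ValueError("velocity and d_h must be non-negative")
    return velocity * d_h / diffusivity


def characterize_channel(spec: ChannelSpec) -> DimensionlessNumbers:
    """Compute D_H, mean velocity, Re and Pe for one duct."""
    d_h = hydraulic_diameter(spec.a, spec.b)
    v = mean_velocity(spec.q_inlet, spec.n_inlets, spec.a, spec.b)
    return DimensionlessNumbers(
        d_h=d_h,
        velocity=v,
        reynolds=reynolds(spec.rho, v, d_h, spec.mu),
        peclet=peclet(v, d_h, spec.diffusivity),
    )


@dataclass
class BorderProfile:
    """Normalized intensity line profiles across a chemical-zone border.

    ``distances`` are signed positions along the border-normal vectors
    (mm; positive into the stimulus side).  Each profile is affinely
    rescaled so its mean over the outside window is 0 and its mean over
    the inside window is 1.  ``width_10_90`` is the distance over which
    the pointwise-mean profile rises from 10% to 90% of that range.
    """

    distances: np.ndarray
    intensities: np.ndarray  # (n_profiles, n_points), normalized
    mean_profile: np.ndarray = field(init=False)
    width_10_90: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_profile = self.intensities.mean(axis=0)
        self.width_10_90 = _rise_width(self.distances, self.mean_profile)


def _first_crossing(d: np.ndarray, y: np.ndarray, level: float) -> float:
    """Position of the first upward crossing of ``level`` (linear interp)."""
    above = y >= level
    if above[0]:
        return float(d[0])
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(d[i] + frac * (d[i + 1] - d[i]))


def _rise_width(distances: np.ndarray, profile: np.ndarray) -> float:
    d10 = _first_crossing(distances, profile, 0.1)
    d90 = _first_crossing(distances, profile, 0.9)
    return float(d90 - d10)


def border_sharpness(
    profiles: np.ndarray | list,
    distances: np.ndarray,
    outside_window: tuple[float, float],
    inside_window: tuple[float, float],
) -> BorderProfile:
    """Normalize intensity line profiles and measure border transition width.

    Parameters
    ----------
    profiles:
        ``(n_profiles, n_points)`` raw intensities sampled at ``distances``,
        or a single 1D profile.
    distances:
        Signed positions (mm), increasing, positive into the stimulus side.
    outside_window, inside_window:
        ``(lo, hi)`` distance ranges whose means define intensity levels
        0 (outside the zone) and 1 (inside the stimulus zone).

    Returns
    -------
    BorderProfile
        With per-profile normalized intensities, their pointwise mean, and
        the 10-90% rise width of the mean profile.

    Raises
    ------
    DegenerateProfileError
        If a profile has equal means inside and outside the zone.
    """
    d = np.asarray(distances, dtype=float)
    prof = np.atleast_2d(np.asarray(profiles, dtype=float))
    if prof.shape[1] != d.size:
        raise ValueError("profiles and distances have mismatched lengths")
    if d.size < 2 or np.any(np.diff(d) <= 0):
        raise ValueError("distances must be strictly increasing")
    out_mask = (d >= outside_window[0]) & (d <= outside_window[1])
    in_mask = (d >= inside_window[0]) & (d <= inside_window[1])
    if not out_mask.any() or not in_mask.any():
        raise ValueError("each profile must cover both windows")

    mu_out = prof[:, out_mask].mean(axis=1)
    mu_in = prof[:, in_mask].mean(axis=1)
    span = mu_in - mu_out
    if np.any(np.abs(span) < 1e-30):
        raise DegenerateProfileError(
            "profile has zero dynamic range between outside and inside windows"
        )
    norm = (prof - mu_out[:, None]) / span[:, None]
    return BorderProfile(distances=d, intensities=norm)
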