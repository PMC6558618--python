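"""Goal-function-scan dipole reconstruction and source descriptors.

The goal function scan (GFS) evaluates, for every candidate position, how
well a single dipole explains a measured topography:

    GoF(x_i) = 1 - (|u - L(x_i) L(x_i)^+ u| / |u|)^2

with L(x_i) the per-position gain block and L^+ its Moore-Penrose
pseudoinverse.  Three variants free successively more degrees of freedom:
fixed (strength only), rotating (orientation + strength at a fixed
position) and moving (position too, via the argmax over the grid).

Orientation changes are reported in a Gram-Schmidt frame anchored at the
reference reconstruction: e1 = reference orientation, e2 = radial (toward
the inner skull), e3 = toward the configured interhemispheric-fissure
direction.  ϑ > 0 means a more radial dipole, φ > 0 a tangential rotation
toward the fissure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .headmodel import Leadfield, ShellModel

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for pseudoinverses
SVD_RCOND = 1e-10
#: GoF differences below this are ties (lowest index wins, logged)
TIE_TOL = 1e-12

DEFAULT_FISSURE_DIRECTION = (0.0, 1.0, 0.0)


@dataclass(frozen=True)
class OrientationFrame:
    """Orthonormal triad (e1 reference orientation, e2 radial, e3 fissure)."""

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    def __post_init__(self):
        for name in ("e1", "e2", "e3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class ScanResult:
    """Best-fitting single dipole of a moving scan."""

    best_index: int
    position: np.ndarray
    depth: float
    moment: np.ndarray
    strength: float
    gof: float
    phi: float = np.nan
    theta: float = np.nan


def goodness_of_fit(u_meas: np.ndarray, L: np.ndarray) -> tuple[float, np.ndarray]:
    """GoF of the orthogonal projection of ``u_meas`` onto the columns of
    ``L`` (n×k, k ∈ {1, 3}), and the fitted moment/amplitude ``L^+ u``.

    The pseudoinverse uses an SVD with relative cutoff ``1e-10 · σ_max``;
    rank-deficient blocks are allowed.
    """
    u = np.asarray(u_meas, dtype=float).ravel()
    L = np.asarray(L, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    if L.shape[0] != u.shape[0]:
        raise ValueError(f"channel mismatch: u has {u.shape[0]}, L has {L.shape[0]}")
    nrm2 = float(u @ u)
    if nrm2 == 0.0:
        raise ValueError("GoF undefined for a zero measurement")
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    keep = s > SVD_RCOND * s[0] if s.size and s[0] > 0 else np.zeros_like(s, bool)
    proj_coef = U[:, keep].T @ u
    moment = Vt[keep].T @ (proj_coef / s[keep])
    gof = float(proj_coef @ proj_coef) / nrm2
    return min(gof, 1.0), moment


def gof_profile(u_meas: np.ndarray, gain_blocks: np.ndarray) -> np.ndarray:
    """Vectorised GoF over many 3-column gain blocks.

    ``gain_blocks`` has shape (..., n_channels, 3); the result drops the
    last two axes.  Uses the eigendecomposition of the 3×3 Gram matrices
    with the same relative cutoff as :func:`goodness_of_fit` (eigenvalues
    are squared singular values).
    """
    u = np.asarray(u_meas, dtype=float).ravel()
    G = np.einsum("...ij,...ik->...jk", gain_blocks, gain_blocks)
    c = np.einsum("...ij,i->...j", gain_blocks, u)
    lam, Q = np.linalg.eigh(G)
    lam_max = lam[..., -1:]
    keep = lam > (SVD_RCOND**2) * np.maximum(lam_max, 0.0)
    cq = np.einsum("...ij,...i->...j", Q, c)
    inv = np.where(keep, np.divide(1.0, lam, where=keep, out=np.zeros_like(lam)), 0.0)
    proj = np.einsum("...j,...j,...j->...", cq, cq, inv)
    return np.minimum(proj / float(u @ u), 1.0)


def fit_moments(u_meas: np.ndarray, gain_blocks: np.ndarray) -> np.ndarray:
    """Vectorised least-squares moments ``L^+ u`` for (..., n, 3) blocks."""
    u = np.asarray(u_meas, dtype=float).ravel()
    G = np.einsum("...ij,...ik->...jk", gain_blocks, gain_blocks)
    c = np.einsum("...ij,i->...j", gain_blocks, u)
    lam, Q = np.linalg.eigh(G)
    keep = lam > (SVD_RCOND**2) * np.maximum(lam[..., -1:], 0.0)
    inv = np.where(keep, np.divide(1.0, lam, where=keep, out=np.zeros_like(lam)), 0.0)
    cq = np.einsum("...ij,...i->...j", Q, c)
    return np.einsum("...ij,...j,...j->...i", Q, inv, cq)


def source_depth(position, shells: ShellModel) -> float:
    """Distance (m) from a source position to the inner skull surface."""
    r = float(np.linalg.norm(np.asarray(position, dtype=float)))
    r_in = shells.inner_skull_radius
    if r > r_in:
        raise DomainError(
            f"position at radius {r*1e3:.2f} mm lies outside the inner skull "
            f"({r_in*1e3:.2f} mm)"
        )
    return r_in - r


def build_orientation_frame(
    reference_orientation,
    position,
    fissure_direction=DEFAULT_FISSURE_DIRECTION,
) -> OrientationFrame:
    """Gram-Schmidt orthonormalisation of (reference orientation, outward
    radial, fissure direction), in that order.

    In the sphere model the outward radial +r̂ points from the source toward
    the inner skull; the fissure direction is a configuration vector since
    the sphere has no anatomy (default +y).
    """
    vecs = [
        np.asarray(reference_orientation, dtype=float),
        np.asarray(position, dtype=float),
        np.asarray(fissure_direction, dtype=float),
    ]
    if np.linalg.norm(vecs[1]) == 0:
        raise DomainError("radial direction undefined at the sphere center")
    basis: list[np.ndarray] = []
    for v in vecs:
        w = v.copy()
        for e in basis:
            w -= (w @ e) * e
        nrm = np.linalg.norm(w)
        if nrm < 1e-10 * max(np.linalg.norm(v), 1.0):
            raise DomainError("degenerate orientation frame: collinear inputs")
        basis.append(w / nrm)
    return OrientationFrame(*basis)


def orientation_angles(moment, frame: OrientationFrame) -> tuple[float, float]:
    """(φ, ϑ) in degrees for a moment expressed in ``frame``.

    ϑ = arcsin(m̂·e2) (elevation toward radial); φ = atan2(m̂·e3, m̂·e1)
    (azimuth, positive toward the fissure direction).
    """
    m = np.asarray(moment, dtype=float)
    nrm = np.linalg.norm(m)
    if nrm == 0:
        raise ValueError("orientation angles undefined for a zero moment")
    mh = m / nrm
    theta = np.degrees(np.arcsin(np.clip(mh @ frame.e2, -1.0, 1.0)))
    phi = np.degrees(np.arctan2(mh @ frame.e3, mh @ frame.e1))
    return float(phi), float(theta)


def scan_fixed(u_meas: np.ndarray, l: np.ndarray) -> tuple[float, float]:
    """Fixed scan: free strength only.  Returns (signed strength, GoF)."""
    u = np.asarray(u_meas, dtype=float).ravel()
    l = np.asarray(l, dtype=float).ravel()
    gof, amp = goodness_of_fit(u, l[:, None])
    return float(amp[0]), gof


def scan_rotating(
    u_meas: np.ndarray,
    L3: np.ndarray,
    frame: OrientationFrame | None = None,
) -> tuple[np.ndarray, float, float, float, float]:
    """Rotating scan at a fixed position: free orientation and strength.

    Returns (moment, strength, φ, ϑ, GoF); angles are NaN when no frame is
    given.
    """
    gof, moment = goodness_of_fit(u_meas, np.asarray(L3, dtype=float))
    strength = float(np.linalg.norm(moment))
    phi = theta = float("nan")
    if frame is not None and strength > 0:
        phi, theta = orientation_angles(moment, frame)
    return moment, strength, phi, theta, gof


def scan_moving(
    u_meas: np.ndarray,
    leadfield: Leadfield,
    shells: ShellModel | None = None,
    frame: OrientationFrame | None = None,
) -> ScanResult:
    """Moving scan: GoF at every source position, argmax wins.

    Ties (ΔGoF < 1e-12) are broken by the lowest index and logged.  Depth
    is reported when ``shells`` is given, orientation angles when ``frame``
    is given.
    """
    if leadfield.n_sources == 0:
        raise DomainError("cannot scan an empty leadfield")
    blocks = leadfield.gain.reshape(leadfield.n_electrodes, -1, 3).transpose(1, 0, 2)
    gofs = gof_profile(u_meas, blocks)
    best = int(np.argmax(gofs))
    tied = np.flatnonzero(gofs >= gofs[best] - TIE_TOL)
    if tied.size > 1:
        best = int(tied[0])
        logger.warning(
            "moving scan tie between %d positions (ΔGoF < %g); keeping lowest index %d",
            tied.size,
            TIE_TOL,
            best,
        )
    gof, moment = goodness_of_fit(u_meas, blocks[best])
    position = leadfield.source_positions[best]
    depth = source_depth(position, shells) if shells is not None else float("nan")
    strength = float(np.linalg.norm(moment))
    phi = theta = float("nan")
    if frame is not None and strength > 0:
        phi, theta = orientation_angles(moment, frame)
    return ScanResult(
        best_index=best,
        position=position,
        depth=depth,
        moment=moment,
        strength=strength,
        gof=gof,
        phi=phi,
        theta=theta,
    )


def scan_results_to_csv(results, path) -> None:
    """Write scan results as CSV rows
    ``sample_id,best_index,x_mm,y_mm,z_mm,depth_mm,strength_nAm,phi_deg,theta_deg,gof``."""
    import pandas as pd

    rows = [
        {
            "sample_id": i,
            "best_index": r.best_index,
            "x_mm": r.position[0] * 1e3,
            "y_mm": r.position[1] * 1e3,
            "z_mm": r.position[2] * 1e3,
            "depth_mm": r.depth * 1e3,
            "strength_nAm": r.strength * 1e9,
            "phi_deg": r.phi,
            "theta_deg": r.theta,
            "gof": r.gof,
        }
        for i, r in enumerate(results)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
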