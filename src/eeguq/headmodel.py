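"""Concentric multilayer-sphere volume conductor and leadfield assembly.

The head is modelled as nested spherical shells of homogeneous isotropic
conductivity (default five shells: white matter, gray matter, CSF, skull,
skin).  The quasi-static potential of a current dipole inside the sphere is
expanded in spherical harmonics; for each harmonic degree the radial profile
in every shell is ``a (r/r_k)^n + b (r_{k-1}/r)^(n+1)`` plus, in the source
shell, the free-space dipole field.  Continuity of potential and radial
current density at each interface and a zero-current (insulating air)
condition at the scalp yield a small linear system per degree, which is
solved batched over degrees and source positions.

All quantities are SI internally (m, S/m, V, A·m); file interfaces use mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ConvergenceError, DomainError

DEFAULT_TISSUES = ("wm", "gm", "csf", "skull", "skin")
#: Default shell boundary radii in metres (conventional desk-scale geometry,
#: not derived from any subject): wm 70, gm 78, csf 80, skull 86, skin 92 mm.
DEFAULT_RADII_M = (0.070, 0.078, 0.080, 0.086, 0.092)

#: Tissue labels counted as brain (allowed source region).
BRAIN_LABELS = frozenset({"wm", "gm", "brain"})


@dataclass(frozen=True)
class ShellModel:
    """Concentric-shell head geometry with per-shell conductivities.

    Parameters
    ----------
    radii
        Outer radius of each shell in metres, strictly increasing,
        innermost first; the last entry is the scalp surface.
    conductivities
        Conductivity of each shell in S/m, ordered like ``radii``.
    tissue_labels
        One label per shell (default ``wm, gm, csf, skull, skin``).
    """

    radii: np.ndarray
    conductivities: np.ndarray
    tissue_labels: tuple[str, ...] = DEFAULT_TISSUES

    def __post_init__(self):
        radii = np.asarray(self.radii, dtype=float)
        cond = np.asarray(self.conductivities, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "conductivities", cond)
        object.__setattr__(self, "tissue_labels", tuple(self.tissue_labels))
        if radii.ndim != 1 or radii.size < 1:
            raise ValueError("radii must be a non-empty 1-D array")
        if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if cond.shape != radii.shape:
            raise ValueError("conductivities must match radii in length")
        if np.any(cond <= 0):
            raise ValueError("conductivities must be strictly positive")
        if len(self.tissue_labels) != radii.size:
            raise ValueError("tissue_labels must match radii in length")

    @property
    def n_shells(self) -> int:
        return self.radii.size

    @property
    def outer_radius(self) -> float:
        return float(self.radii[-1])

    @property
    def brain_radius(self) -> float:
        """Outer radius of the outermost brain shell (source region bound)."""
        brain = [r for r, t in zip(self.radii, self.tissue_labels) if t in BRAIN_LABELS]
        if not brain:
            return float(self.radii[0])
        return float(max(brain))

    @property
    def inner_skull_radius(self) -> float:
        """Radius of the inner skull surface (outer boundary of CSF when
        present, otherwise the brain radius)."""
        for r, t in zip(self.radii, self.tissue_labels):
            if t == "csf":
                return float(r)
        return self.brain_radius

    def shell_index(self, radius: float) -> int:
        """Shell containing ``radius``; boundary points belong to the inner
        shell (half-open radial intervals, inner-closed)."""
        if radius < 0 or radius > self.outer_radius:
            raise DomainError(f"radius {radius} outside the head model")
        return int(np.searchsorted(self.radii, radius, side="left"))

    def tissue_at(self, radius: float) -> str:
        return self.tissue_labels[self.shell_index(radius)]

    def with_conductivities(self, conductivities) -> "ShellModel":
        """Same geometry with a different conductivity set.

        ``conductivities`` may be an array ordered like the shells or a
        mapping ``label -> S/m`` (missing labels keep their current value).
        """
        if isinstance(conductivities, dict):
            cond = np.array(
                [conductivities.get(t, c) for t, c in zip(self.tissue_labels, self.conductivities)]
            )
        else:
            cond = np.asarray(conductivities, dtype=float)
        return ShellModel(self.radii, cond, self.tissue_labels)


@dataclass(frozen=True)
class ElectrodeArray:
    """Labelled electrode positions on the scalp sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) metres

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("electrode labels must be unique")
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if pos.shape[0] != len(self.labels):
            raise ValueError("labels and positions must align")
        if pos.shape[0] < 4:
            raise ValueError("at least 4 electrodes are required")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def projected(self, radius: float, warn_mm: float = 2.0) -> "ElectrodeArray":
        """Project every electrode radially onto the sphere of ``radius``."""
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms == 0):
            raise ValueError("electrode at the origin cannot be projected")
        moved = np.abs(norms - radius)
        if np.any(moved > warn_mm * 1e-3):
            worst = float(moved.max() * 1e3)
            warnings.warn(
                f"electrode projection moved positions by up to {worst:.2f} mm",
                stacklevel=2,
            )
        return ElectrodeArray(self.labels, self.positions * (radius / norms)[:, None])

    @classmethod
    def from_tsv(cls, path, radius: float | None = None) -> "ElectrodeArray":
        """Read a TSV with header ``label x y z`` (coordinates in mm)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        arr = cls(tuple(df["label"].astype(str)), df[["x", "y", "z"]].to_numpy() * 1e-3)
        return arr.projected(radius) if radius is not None else arr

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "label": self.labels,
                "x": self.positions[:, 0] * 1e3,
                "y": self.positions[:, 1] * 1e3,
                "z": self.positions[:, 2] * 1e3,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m) and moment (A·m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))
        if self.position.shape != (3,) or self.moment.shape != (3,):
            raise ValueError("position and moment must be 3-vectors")

    @property
    def strength(self) -> float:
        return float(np.linalg.norm(self.moment))

    @property
    def orientation(self) -> np.ndarray:
        s = self.strength
        if s == 0:
            raise ValueError("zero-moment dipole has no orientation")
        return self.moment / s


@dataclass(frozen=True)
class Leadfield:
    """Electrodes × (sources·3) gain matrix with metadata.

    Column ``3 k + j`` holds the referenced potential pattern of a unit
    dipole moment along cartesian axis ``j`` at source position ``k``
    (V per A·m).
    """

    gain: np.ndarray
    source_positions: np.ndarray
    electrode_labels: tuple[str, ...]
    conductivities: dict[str, float] = field(default_factory=dict)
    reference: str = "average"

    def __post_init__(self):
        gain = np.asarray(self.gain, dtype=float)
        pos = np.asarray(self.source_positions, dtype=float)
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "source_positions", pos)
        object.__setattr__(self, "electrode_labels", tuple(self.electrode_labels))
        if gain.ndim != 2 or gain.shape[1] != 3 * pos.shape[0]:
            raise ValueError("gain must have shape (n_electrodes, 3*n_sources)")
        if gain.shape[0] != len(self.electrode_labels):
            raise ValueError("gain rows must match electrode labels")
        if not np.all(np.isfinite(gain)):
            raise ValueError("gain contains non-finite entries")

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    def block(self, k: int) -> np.ndarray:
        """(n_electrodes, 3) gain block of source position ``k``."""
        return self.gain[:, 3 * k : 3 * k + 3]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("gain", data=self.gain)
            f.create_dataset("source_positions", data=self.source_positions)
            f.create_dataset(
                "electrode_labels",
                data=np.array(self.electrode_labels, dtype=h5py.string_dtype()),
            )
            f.attrs["reference"] = self.reference
            f.attrs["units"] = "SI: m, S/m, V/(A.m)"
            for tissue, sigma in self.conductivities.items():
                f.attrs[f"conductivity_{tissue}"] = sigma

    @classmethod
    def from_hdf5(cls, path) -> "Leadfield":
        with h5py.File(path, "r") as f:
            cond = {
                k.removeprefix("conductivity_"): float(v)
                for k, v in f.attrs.items()
                if k.startswith("conductivity_")
            }
            return cls(
                gain=f["gain"][()],
                source_positions=f["source_positions"][()],
                electrode_labels=tuple(s.decode() for s in f["electrode_labels"][()]),
                conductivities=cond,
                reference=str(f.attrs["reference"]),
            )


def apply_average_reference(potentials: np.ndarray) -> np.ndarray:
    """Subtract the channel mean (axis 0 = channels); idempotent.

    Accepts a vector of ``n`` channel potentials or an ``(n, m)`` matrix of
    ``m`` potential patterns.
    """
    u = np.asarray(potentials, dtype=float)
    if u.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return u - u.mean(axis=0, keepdims=(u.ndim > 1))


# ---------------------------------------------------------------------------
# per-degree interface systems
# ---------------------------------------------------------------------------


def _interface_matrices(shells: ShellModel, degrees: np.ndarray) -> np.ndarray:
    """Batched (len(degrees), 2K-1, 2K-1) interface matrices.

    Unknown ordering: ``[a_1, a_2, b_2, ..., a_K, b_K]`` where in shell k the
    radial profile is ``a_k (r/r_k)^n + b_k (r_{k-1}/r)^(n+1)`` (shell 1 has
    no decaying term).  Rows: continuity and current continuity at each
    interface, then the insulating scalp condition.
    """
    radii = shells.radii
    sig = shells.conductivities
    K = radii.size
    n = np.asarray(degrees, dtype=float)
    m = n.size
    size = 2 * K - 1
    A = np.zeros((m, size, size))

    def a_col(k):
        return 0 if k == 0 else 2 * k - 1

    def b_col(k):
        return None if k == 0 else 2 * k

    r_inner = np.concatenate([[0.0], radii[:-1]])

    def u_val(k, r):
        return (r / radii[k]) ** n

    def u_der(k, r):
        return (n / r) * (r / radii[k]) ** n

    def v_val(k, r):
        return (r_inner[k] / r) ** (n + 1)

    def v_der(k, r):
        return -((n + 1) / r) * (r_inner[k] / r) ** (n + 1)

    row = 0
    for j in range(K - 1):
        r = radii[j]
        A[:, row, a_col(j)] += u_val(j, r)
        if b_col(j) is not None:
            A[:, row, b_col(j)] += v_val(j, r)
        A[:, row, a_col(j + 1)] -= u_val(j + 1, r)
        A[:, row, b_col(j + 1)] -= v_val(j + 1, r)
        row += 1
        A[:, row, a_col(j)] += sig[j] * u_der(j, r)
        if b_col(j) is not None:
            A[:, row, b_col(j)] += sig[j] * v_der(j, r)
        A[:, row, a_col(j + 1)] -= sig[j + 1] * u_der(j + 1, r)
        A[:, row, b_col(j + 1)] -= sig[j + 1] * v_der(j + 1, r)
        row += 1
    r = radii[-1]
    A[:, row, a_col(K - 1)] = u_der(K - 1, r)
    if b_col(K - 1) is not None:
        A[:, row, b_col(K - 1)] = v_der(K - 1, r)
    return A


def _source_rhs(shells: ShellModel, degrees: np.ndarray, b: float, s: int) -> np.ndarray:
    """Batched RHS (len(degrees), 2K-1, 2) for unit radial / unit tangential
    moment of a dipole at radius ``b`` in shell ``s`` (1/(4πσ_s) included)."""
    radii = shells.radii
    sig = shells.conductivities
    K = radii.size
    n = np.asarray(degrees, dtype=float)
    c = 1.0 / (4 * np.pi * sig[s])

    # b^(n-1) with the 0^0 = 1 convention for the central dipole
    with np.errstate(divide="ignore"):
        if b > 0:
            bn1 = b ** (n - 1)
        else:
            bn1 = np.where(n == 1, 1.0, 0.0)

    def prim(r):
        """primary radial profiles (value, derivative) at r, both channels."""
        if r >= b:
            fr = bn1 / r ** (n + 1)
            val_rad = c * n * fr
            val_tan = c * fr
            der_rad = -c * n * (n + 1) * fr / r
            der_tan = -c * (n + 1) * fr / r
        else:
            fr = r**n / b ** (n + 2)
            val_rad = -c * (n + 1) * fr
            val_tan = c * fr
            der_rad = -c * (n + 1) * n * fr / r
            der_tan = c * n * fr / r
        return np.stack([val_rad, val_tan], axis=-1), np.stack([der_rad, der_tan], axis=-1)

    rhs = np.zeros((n.size, 2 * K - 1, 2))
    row = 0
    for j in range(K - 1):
        r = radii[j]
        if j == s:
            val, der = prim(r)
            rhs[:, row, :] -= val
            rhs[:, row + 1, :] -= sig[j] * der
        if j + 1 == s:
            val, der = prim(r)
            rhs[:, row, :] += val
            rhs[:, row + 1, :] += sig[j + 1] * der
        row += 2
    if s == K - 1:
        _, der = prim(radii[-1])
        rhs[:, row, :] -= der
    return rhs


def _surface_coefficients(
    shells: ShellModel,
    degrees: np.ndarray,
    radii_sources: np.ndarray,
    source_shells: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-degree scalp-surface transfer coefficients for unit radial and
    unit tangential dipole moments.

    Returns ``(A_n, B_n)`` of shape (n_sources, n_degrees): the potential at
    scalp angle γ from a dipole at radius b is
    ``Σ_n A_n m_r P_n(cos γ) + B_n P_n'(cos γ) (ê·t)``.
    """
    K = shells.n_shells
    n = np.asarray(degrees, dtype=float)
    A = _interface_matrices(shells, degrees)  # (m, 2K-1, 2K-1)
    P = radii_sources.size
    rhs = np.empty((n.size, 2 * K - 1, 2 * P))
    for p, (b, s) in enumerate(zip(radii_sources, source_shells)):
        rhs[:, :, 2 * p : 2 * p + 2] = _source_rhs(shells, degrees, float(b), int(s))
    x = np.linalg.solve(A, rhs)  # (m, 2K-1, 2P)

    r_scalp = shells.outer_radius
    if K > 1:
        a_K = x[:, 2 * K - 3, :]
        b_K = x[:, 2 * K - 2, :]
        v_surf = (shells.radii[-2] / r_scalp) ** (n + 1)
        surf = a_K + v_surf[:, None] * b_K  # u_K(r_K) = 1
    else:
        surf = x[:, 0, :]
    # primary contribution when the source shell is the outermost shell
    c = 1.0 / (4 * np.pi * shells.conductivities[-1])
    out_A = np.empty((P, n.size))
    out_B = np.empty((P, n.size))
    for p, (b, s) in enumerate(zip(radii_sources, source_shells)):
        col = surf[:, 2 * p : 2 * p + 2]  # (m, 2) radial, tangential
        add_rad = np.zeros(n.size)
        add_tan = np.zeros(n.size)
        if int(s) == K - 1:
            b = float(b)
            bn1 = b ** (n - 1) if b > 0 else np.where(n == 1, 1.0, 0.0)
            fr = bn1 / r_scalp ** (n + 1)
            add_rad = c * n * fr
            add_tan = c * fr
        out_A[p] = col[:, 0] + add_rad
        out_B[p] = col[:, 1] + add_tan
    return out_A, out_B


def _dipole_frame(position: np.ndarray, moment: np.ndarray):
    """Split a moment into radial scalar and tangential vector at ``position``.

    For a central dipole the moment direction serves as the polar axis (the
    field is then purely 'radial-channel' by construction).
    """
    b = float(np.linalg.norm(position))
    if b < 1e-12:
        norm = np.linalg.norm(moment)
        zhat = moment / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        return 0.0, zhat, float(norm), np.zeros(3)
    zhat = position / b
    m_r = float(moment @ zhat)
    return b, zhat, m_r, moment - m_r * zhat


def _angular_terms(degrees: np.ndarray, cosg: np.ndarray):
    """Legendre P_n(cos γ) and P_n'(cos γ) for all requested degrees.

    Returns arrays of shape (n_degrees, n_points) built by upward recurrence.
    """
    nmax = int(degrees.max())
    P = np.empty((nmax + 1, cosg.size))
    dP = np.empty((nmax + 1, cosg.size))
    P[0] = 1.0
    dP[0] = 0.0
    if nmax >= 1:
        P[1] = cosg
        dP[1] = 1.0
    for k in range(2, nmax + 1):
        P[k] = ((2 * k - 1) * cosg * P[k - 1] - (k - 1) * P[k - 2]) / k
        dP[k] = dP[k - 2] + (2 * k - 1) * P[k - 1]
    return P[degrees], dP[degrees]


def _check_source_position(position: np.ndarray, shells: ShellModel) -> int:
    b = float(np.linalg.norm(position))
    if b >= shells.brain_radius:
        raise DomainError(
            f"dipole at radius {b*1e3:.2f} mm is outside the brain region "
            f"(boundary {shells.brain_radius*1e3:.2f} mm)"
        )
    return shells.shell_index(b)


def potential_layered_sphere(
    dipole: Dipole,
    electrodes: ElectrodeArray,
    shells: ShellModel,
    *,
    rtol: float = 1e-8,
    n_max: int = 200,
) -> np.ndarray:
    """Unreferenced scalp potentials (V) of a dipole in the layered sphere.

    The spherical-harmonic series is truncated adaptively: degrees are added
    in blocks until the latest block contributes less than ``rtol`` of the
    accumulated potential scale, up to ``n_max``.

    Raises
    ------
    DomainError
        If the dipole lies outside the brain shells.
    ConvergenceError
        If the series has not converged at ``n_max`` (reports the achieved
        relative residual).
    """
    s = _check_source_position(dipole.position, shells)
    b, zhat, m_r, tvec = _dipole_frame(dipole.position, dipole.moment)
    if dipole.strength == 0.0:
        return np.zeros(len(electrodes))

    ehat = electrodes.positions / np.linalg.norm(electrodes.positions, axis=1, keepdims=True)
    cosg = np.clip(ehat @ zhat, -1.0, 1.0)
    edt = ehat @ tvec

    V = np.zeros(len(electrodes))
    block = 25
    start = 1
    scale = 0.0
    while start <= n_max:
        degrees = np.arange(start, min(start + block, n_max + 1))
        An, Bn = _surface_coefficients(shells, degrees, np.array([b]), np.array([s]))
        Pn, dPn = _angular_terms(degrees, cosg)
        contrib = (An[0] * m_r) @ Pn + Bn[0] @ (dPn * edt)
        V += contrib
        scale = max(scale, float(np.abs(V).max()))
        resid = float(np.abs(contrib).max())
        if scale > 0 and resid <= rtol * scale:
            return V
        start += block
    raise ConvergenceError(
        f"series not converged at N_max={n_max}: relative residual "
        f"{resid / scale if scale else np.inf:.3e} > rtol={rtol:.1e}",
        residual=resid / scale if scale else np.inf,
    )


def forward_potentials(
    positions: np.ndarray,
    shells: ShellModel,
    electrodes: ElectrodeArray,
    *,
    rtol: float = 1e-8,
    n_max: int = 200,
) -> np.ndarray:
    """Unit-moment forward solutions for many source positions at once.

    Returns an (n_electrodes, n_positions, 3) array: entry ``[:, k, j]`` is
    the unreferenced potential pattern of a unit dipole along cartesian axis
    ``j`` at position ``k``.  The truncation degree is fixed from a geometric
    tail bound at the most superficial source.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radii_src = np.linalg.norm(positions, axis=1)
    src_shell = np.array([_check_source_position(p, shells) for p in positions])

    # geometric tail bound: terms decay like (b/r_scalp)^n
    q = float(radii_src.max() / shells.outer_radius)
    q = min(max(q, 0.1), 1 - 1e-6)
    n_trunc = int(np.ceil((np.log(rtol) + np.log1p(-q)) / np.log(q))) + 10
    n_trunc = int(np.clip(n_trunc, 20, n_max))
    degrees = np.arange(1, n_trunc + 1)

    An, Bn = _surface_coefficients(shells, degrees, radii_src, src_shell)

    ehat = electrodes.positions / np.linalg.norm(electrodes.positions, axis=1, keepdims=True)
    n_e, n_p = len(electrodes), positions.shape[0]
    out = np.empty((n_e, n_p, 3))
    for k in range(n_p):
        b, zhat, _, _ = _dipole_frame(positions[k], np.array([0.0, 0.0, 1.0]))
        if b == 0.0:
            zhat = np.array([0.0, 0.0, 1.0])
        cosg = np.clip(ehat @ zhat, -1.0, 1.0)
        Pn, dPn = _angular_terms(degrees, cosg)
        rad_pattern = An[k] @ Pn          # (n_e,) per unit radial moment
        tan_pattern = Bn[k] @ dPn         # (n_e,) angular derivative factor
        for j in range(3):
            e_j = np.zeros(3)
            e_j[j] = 1.0
            m_r = float(e_j @ zhat)
            tvec = e_j - m_r * zhat
            out[:, k, j] = m_r * rad_pattern + tan_pattern * (ehat @ tvec)
    return out


def compute_leadfield(
    space,
    electrodes: ElectrodeArray,
    shells: ShellModel,
    *,
    rtol: float = 1e-8,
    n_max: int = 200,
) -> Leadfield:
    """Average-referenced leadfield over the retained positions of a source
    space (or a raw (n, 3) position array)."""
    positions = getattr(space, "retained", space)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise DomainError("empty source space: no retained positions")
    bad = [
        k
        for k, p in enumerate(positions)
        if np.linalg.norm(p) >= shells.brain_radius
    ]
    if bad:
        raise DomainError(f"source positions outside the brain region at indices {bad}")
    pots = forward_potentials(positions, shells, electrodes, rtol=rtol, n_max=n_max)
    gain = pots.reshape(len(electrodes), -1)
    gain = apply_average_reference(gain)
    cond = dict(zip(shells.tissue_labels, map(float, shells.conductivities)))
    return Leadfield(
        gain=gain,
        source_positions=positions,
        electrode_labels=electrodes.labels,
        conductivities=cond,
        reference="average",
    )
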