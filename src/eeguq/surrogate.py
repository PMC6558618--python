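"""Polynomial-chaos surrogate of the leadfield over uncertain conductivities.

Each uncertain tissue conductivity is uniform on a literature interval and
rescaled affinely to ξ ∈ [-1, 1].  The vector-valued model output (all
flattened leadfield entries) is expanded in orthonormal Legendre
polynomials of total degree ≤ p:

    f(ξ) ≈ Σ_α c_α Ψ_α(ξ),   Ψ_α(ξ) = Π_i sqrt(2 α_i + 1) P_{α_i}(ξ_i),

with coefficients obtained by pseudo-spectral projection on a Smolyak
sparse Gauss-Legendre grid.  Orthonormality under the uniform probability
measure makes variance bookkeeping trivial: the output variance is
Σ_{α≠0} c_α² and the Sobol index of a variable subset is the normalised sum
of squared coefficients whose multi-index support equals that subset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from numpy.polynomial.legendre import leggauss

TISSUES = ("skin", "skull", "csf", "gm", "wm")

#: Uniform conductivity priors in S/m: (lower, upper, standard).
#: Literature intervals: skin/gm/wm roughly ±50% around the standard value,
#: skull from measured extremes, CSF a narrow 99% confidence band.
DEFAULT_PRIOR_SM = {
    "skin": (0.280, 0.870, 0.430),
    "skull": (0.0016, 0.0330, 0.0100),
    "csf": (1.7696, 1.8104, 1.7900),
    "gm": (0.220, 0.670, 0.330),
    "wm": (0.090, 0.290, 0.140),
}


@dataclass(frozen=True)
class ConductivityPrior:
    """Per-tissue uniform bounds and standard values (S/m)."""

    bounds: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_SM)
    )

    def __post_init__(self):
        for tissue, (lo, hi, std) in self.bounds.items():
            if not (lo <= std <= hi):
                raise ValueError(f"{tissue}: standard {std} outside [{lo}, {hi}]")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def lower(self, tissue: str) -> float:
        return self.bounds[tissue][0]

    def upper(self, tissue: str) -> float:
        return self.bounds[tissue][1]

    def standard(self, tissue: str) -> float:
        return self.bounds[tissue][2]

    def width(self, tissue: str) -> float:
        lo, hi, _ = self.bounds[tissue]
        return hi - lo

    def standard_set(self) -> dict[str, float]:
        return {t: self.standard(t) for t in self.bounds}

    def interval_array(self, tissues) -> np.ndarray:
        """(d, 2) lower/upper bounds for the given ordered tissues."""
        return np.array([[self.lower(t), self.upper(t)] for t in tissues])


def rescale(sigma, prior: ConductivityPrior, tissues) -> np.ndarray:
    """Map conductivities (S/m) to ξ ∈ [-1, 1]^d for the given tissues.

    ``sigma`` may be a mapping or an array ordered like ``tissues``; arrays
    may be batched (n, d).  Out-of-bounds values and zero-width (degenerate)
    priors are rejected.
    """
    tissues = list(tissues)
    if isinstance(sigma, dict):
        sig = np.array([sigma[t] for t in tissues], dtype=float)
    else:
        sig = np.asarray(sigma, dtype=float)
    lo_hi = prior.interval_array(tissues)
    lo, hi = lo_hi[:, 0], lo_hi[:, 1]
    for t, l, h in zip(tissues, lo, hi):
        if h <= l:
            raise ValueError(f"degenerate prior for {t}: lower == upper")
    vals = np.atleast_2d(sig)
    for j, t in enumerate(tissues):
        bad = (vals[:, j] < lo[j] - 1e-12) | (vals[:, j] > hi[j] + 1e-12)
        if np.any(bad):
            raise ValueError(
                f"conductivity for {t} outside prior bounds "
                f"[{lo[j]}, {hi[j]}]: {vals[bad, j][0]}"
            )
    xi = (sig - lo) * 2.0 / (hi - lo) - 1.0
    return np.clip(xi, -1.0, 1.0)


def unrescale(xi, prior: ConductivityPrior, tissues) -> np.ndarray:
    """Inverse of :func:`rescale` (round-trips to ~1e-14)."""
    tissues = list(tissues)
    xi = np.asarray(xi, dtype=float)
    lo_hi = prior.interval_array(tissues)
    lo, hi = lo_hi[:, 0], lo_hi[:, 1]
    return lo + (xi + 1.0) * (hi - lo) / 2.0


def sample_prior(
    prior: ConductivityPrior, tissues, n: int, seed
) -> np.ndarray:
    """(n, d) i.i.d. uniform conductivity draws (S/m) for ``tissues``.

    Zero-width tissues yield a constant column.  Identical seeds give
    identical samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    lo_hi = prior.interval_array(tissues)
    return rng.uniform(lo_hi[:, 0], lo_hi[:, 1], size=(n, len(tissues)))


# ---------------------------------------------------------------------------
# basis and quadrature
# ---------------------------------------------------------------------------


def total_degree_indices(d: int, p: int) -> np.ndarray:
    """All multi-indices α ∈ ℕ₀^d with |α|₁ ≤ p, graded-lexicographic.
    Count is C(d+p, p)."""
    idx = [
        alpha
        for total in range(p + 1)
        for alpha in itertools.product(range(total + 1), repeat=d)
        if sum(alpha) == total
    ]
    return np.array(idx, dtype=int).reshape(len(idx), d)


def _legendre_eval(nodes: np.ndarray, max_deg: int) -> np.ndarray:
    """(max_deg+1, M, d) table of 1-D orthonormal Legendre values."""
    x = np.asarray(nodes, dtype=float)
    P = np.empty((max_deg + 1,) + x.shape)
    P[0] = 1.0
    if max_deg >= 1:
        P[1] = x
    for k in range(2, max_deg + 1):
        P[k] = ((2 * k - 1) * x * P[k - 1] - (k - 1) * P[k - 2]) / k
    norm = np.sqrt(2 * np.arange(max_deg + 1) + 1.0)
    return P * norm.reshape((-1,) + (1,) * x.ndim)


def basis_matrix(nodes: np.ndarray, multi_indices: np.ndarray) -> np.ndarray:
    """(M, n_terms) matrix of Ψ_α evaluated at (M, d) nodes."""
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    max_deg = int(multi_indices.max()) if multi_indices.size else 0
    table = _legendre_eval(nodes, max_deg)  # (deg+1, M, d)
    M, d = nodes.shape
    out = np.ones((M, multi_indices.shape[0]))
    for j in range(d):
        out *= table[multi_indices[:, j], :, j].T
    return out


def gauss_legendre_rule(m: int) -> tuple[np.ndarray, np.ndarray]:
    """m-point Gauss-Legendre rule normalised to the uniform probability
    measure on [-1, 1] (weights sum to 1); exact to degree 2m-1."""
    x, w = leggauss(m)
    return x, w / 2.0


def sparse_grid_nodes(
    d: int, degree: int, level: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Smolyak sparse Gauss-Legendre quadrature in d dimensions.

    Uses linear growth (level l → l+1 points, 1-D exactness 2l+1) and the
    combination formula at Smolyak level L (default L = ``degree``), which
    integrates all monomials of total degree ≤ 2L+1 exactly — sufficient
    for aliasing-free degree-``degree`` projection.  Duplicate nodes from
    overlapping tensor grids are merged; weights sum to 1.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    L = degree if level is None else level
    points: dict[tuple, tuple[tuple, float]] = {}  # merge key -> (node, weight)
    lo = max(0, L - d + 1)
    for offsets in itertools.product(range(L + 1), repeat=d):
        s = sum(offsets)
        if not (lo <= s <= L):
            continue
        coef = (-1) ** (L - s) * math.comb(d - 1, L - s)
        rules = [gauss_legendre_rule(l + 1) for l in offsets]
        for combo in itertools.product(*[range(l + 1) for l in offsets]):
            node = tuple(float(rules[k][0][i]) for k, i in enumerate(combo))
            key = tuple(round(v, 13) + 0.0 for v in node)
            w = coef * math.prod(rules[k][1][i] for k, i in enumerate(combo))
            prev = points.get(key)
            points[key] = (node, w + (prev[1] if prev else 0.0))
    keys = sorted(points)
    nodes = np.array([points[k][0] for k in keys]).reshape(len(keys), d)
    weights = np.array([points[k][1] for k in keys])
    return nodes, weights


# ---------------------------------------------------------------------------
# the expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCEModel:
    """Orthonormal-Legendre chaos expansion of a vector-valued output.

    ``coefficients[a]`` is the output vector multiplying Ψ_{multi_indices[a]}.
    ``bounds`` holds the per-tissue rescaling intervals (S/m); ``meta`` may
    carry leadfield metadata (electrode labels, source positions, output
    shape) for reshaping evaluations.
    """

    tissues: tuple[str, ...]
    degree: int
    multi_indices: np.ndarray  # (n_terms, d)
    coefficients: np.ndarray  # (n_terms, n_out)
    bounds: np.ndarray  # (d, 2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "tissues", tuple(self.tissues))
        mi = np.asarray(self.multi_indices, dtype=int)
        co = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "multi_indices", mi)
        object.__setattr__(self, "coefficients", co)
        object.__setattr__(self, "bounds", np.asarray(self.bounds, dtype=float))
        if mi.shape[0] != co.shape[0]:
            raise ValueError("one coefficient vector per multi-index required")
        if mi.shape[1] != len(self.tissues):
            raise ValueError("multi-index dimension must match tissues")
        if not np.any(np.all(mi == 0, axis=1)):
            raise ValueError("the constant multi-index α=0 must be present")

    @property
    def dims(self) -> int:
        return self.multi_indices.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.coefficients.shape[1]

    def predict_xi(self, xi: np.ndarray) -> np.ndarray:
        """Evaluate at rescaled points ξ (n, d) → (n, n_out)."""
        Psi = basis_matrix(np.atleast_2d(xi), self.multi_indices)
        return Psi @ self.coefficients

    def predict(self, sigma, prior: ConductivityPrior) -> np.ndarray:
        """Evaluate at conductivities (S/m); no extrapolation outside the
        prior bounds."""
        xi = rescale(sigma, prior, self.tissues)
        out = self.predict_xi(np.atleast_2d(xi))
        return out[0] if np.asarray(xi).ndim == 1 else out

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("multi_indices", data=self.multi_indices)
            f.create_dataset("coefficients", data=self.coefficients)
            f.create_dataset("bounds", data=self.bounds)
            f.attrs["tissues"] = ",".join(self.tissues)
            f.attrs["degree"] = self.degree
            f.attrs["basis"] = "orthonormal-legendre-uniform"
            if "source_positions" in self.meta:
                f.create_dataset("source_positions", data=self.meta["source_positions"])
            if "electrode_labels" in self.meta:
                f.attrs["electrode_labels"] = ",".join(self.meta["electrode_labels"])

    @classmethod
    def from_hdf5(cls, path) -> "PCEModel":
        with h5py.File(path, "r") as f:
            meta = {}
            if "source_positions" in f:
                meta["source_positions"] = f["source_positions"][()]
            if "electrode_labels" in f.attrs:
                meta["electrode_labels"] = tuple(str(f.attrs["electrode_labels"]).split(","))
            return cls(
                tissues=tuple(str(f.attrs["tissues"]).split(",")),
                degree=int(f.attrs["degree"]),
                multi_indices=f["multi_indices"][()],
                coefficients=f["coefficients"][()],
                bounds=f["bounds"][()],
                meta=meta,
            )


def fit_pce(
    evaluations: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
    tissues,
    degree: int,
    bounds: np.ndarray,
    meta: dict | None = None,
) -> PCEModel:
    """Pseudo-spectral projection: c_α = Σ_k w_k f(ξ_k) Ψ_α(ξ_k).

    ``evaluations`` (M, n_out) must be row-aligned with ``nodes`` (M, d).
    All outputs share the node set and are fitted in one pass.
    """
    evals = np.atleast_2d(np.asarray(evaluations, dtype=float))
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    if evals.shape[0] != nodes.shape[0]:
        raise ValueError("evaluations must be row-aligned with nodes")
    bad = np.flatnonzero(~np.all(np.isfinite(evals), axis=1))
    if bad.size:
        raise ValueError(f"non-finite evaluations at node indices {bad.tolist()}")
    mi = total_degree_indices(nodes.shape[1], degree)
    Psi = basis_matrix(nodes, mi)  # (M, n_terms)
    coef = (Psi * np.asarray(weights)[:, None]).T @ evals
    return PCEModel(
        tissues=tuple(tissues),
        degree=degree,
        multi_indices=mi,
        coefficients=coef,
        bounds=np.asarray(bounds, dtype=float),
        meta=meta or {},
    )


def evaluate_pce(model: PCEModel, sigma, prior: ConductivityPrior) -> np.ndarray:
    """Functional alias of :meth:`PCEModel.predict`."""
    return model.predict(sigma, prior)


# ---------------------------------------------------------------------------
# Sobol indices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SobolTable:
    """Variance decomposition of a PCE output vector.

    ``indices[subset]`` holds S(subset) per output; subsets are tuples of
    tissue names.  Outputs with zero total variance are flagged in
    ``zero_variance`` and carry NaN indices.
    """

    subsets: tuple[tuple[str, ...], ...]
    indices: dict[tuple[str, ...], np.ndarray]
    conditional_variance: dict[tuple[str, ...], np.ndarray]
    total_variance: np.ndarray
    zero_variance: np.ndarray

    def sum_of_indices(self) -> np.ndarray:
        """Σ over the reported subsets, per output."""
        return np.sum([self.indices[s] for s in self.subsets], axis=0)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for s in self.subsets:
            for out_idx, val in enumerate(self.indices[s]):
                rows.append({"subset": "+".join(s), "output": out_idx, "S": val})
        return pd.DataFrame(rows)


def sobol_indices(model: PCEModel, max_order: int | None = None) -> SobolTable:
    """Sobol indices from PCE coefficients.

    The total variance per output is 𝕍 = Σ_{α≠0} c_α²; the conditional
    variance of a subset is the sum over multi-indices whose support equals
    exactly that subset, and S = 𝕍(subset)/𝕍.  With ``max_order=None`` all
    orders 1..d are reported and the indices sum to 1 for every output with
    nonzero variance.
    """
    d = model.dims
    if d < 1:
        raise ValueError("model must have at least one uncertain tissue")
    order = d if max_order is None else min(max_order, d)
    support = model.multi_indices > 0
    c2 = model.coefficients**2
    total = c2[np.any(support, axis=1)].sum(axis=0)
    # outputs whose variance is pure quadrature round-off (constant outputs,
    # degenerate priors) are flagged rather than divided by
    scale = c2.sum(axis=0)
    zero = total <= 1e-24 * scale

    subsets = [
        tuple(model.tissues[i] for i in combo)
        for k in range(1, order + 1)
        for combo in itertools.combinations(range(d), k)
    ]
    cond: dict[tuple[str, ...], np.ndarray] = {}
    idx: dict[tuple[str, ...], np.ndarray] = {}
    for k in range(1, order + 1):
        for combo in itertools.combinations(range(d), k):
            key = tuple(model.tissues[i] for i in combo)
            mask = np.ones(model.multi_indices.shape[0], dtype=bool)
            for j in range(d):
                mask &= support[:, j] if j in combo else ~support[:, j]
            v = c2[mask].sum(axis=0)
            cond[key] = v
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.where(zero, np.nan, v / np.where(zero, 1.0, total))
            idx[key] = s
    return SobolTable(
        subsets=tuple(subsets),
        indices=idx,
        conditional_variance=cond,
        total_variance=total,
        zero_variance=zero,
    )
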