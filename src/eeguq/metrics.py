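"""Topography and magnitude error metrics, and variability summaries.

RDM (relative difference measure) compares normalised topographies,
``RDM = ||u1/||u1|| - u2/||u2||||``, ranging from 0 (identical shape) to 2
(opposite shape); lnMAG = ln(||u1||/||u2||) compares magnitudes.  Both are
zero iff the vectors are positive scalar multiples of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surrogate import ConductivityPrior, PCEModel, sample_prior


def _as_nonzero(u, name: str) -> np.ndarray:
    v = np.asarray(u, dtype=float).ravel()
    if np.linalg.norm(v) == 0:
        raise ValueError(f"{name} must be nonzero")
    return v


def rdm(u1, u2) -> float:
    """Topography error in [0, 2]; symmetric and scale-invariant."""
    a = _as_nonzero(u1, "u1")
    b = _as_nonzero(u2, "u2")
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b)))


def lnmag(u1, u2) -> float:
    """Magnitude error ln(||u1||/||u2||); antisymmetric and additive."""
    a = _as_nonzero(u1, "u1")
    b = _as_nonzero(u2, "u2")
    return float(np.log(np.linalg.norm(a) / np.linalg.norm(b)))


def electrodewise_std(samples) -> np.ndarray:
    """Unbiased per-electrode standard deviation over sample topographies.

    ``samples``: (n_samples, n_electrodes) array or a sequence of vectors.
    """
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return arr.std(axis=0, ddof=1)


@dataclass(frozen=True)
class SurrogateValidation:
    """Summary of surrogate-vs-exact leadfield errors."""

    max_rdm: float
    mean_rdm: float
    max_abs_lnmag: float
    mean_abs_lnmag: float
    table: pd.DataFrame  # columns draw, source_index, direction, rdm, lnmag


def validate_surrogate(
    model: PCEModel,
    exact_forward,
    prior: ConductivityPrior,
    n_test: int = 10,
    seed: int = 0,
) -> SurrogateValidation:
    """Compare surrogate and exact leadfields at random prior draws.

    ``exact_forward(sigma_dict) -> (n_electrodes, 3*n_sources) gain`` must
    share the surrogate's geometry.  Each source position is compared as
    one topography: its three unit-moment columns stacked into a single
    vector (one RDM/lnMAG per source per draw), over ``n_test``
    conductivity sets drawn from the prior.
    """
    draws = sample_prior(prior, model.tissues, n_test, seed)
    rows = []
    for i, sig in enumerate(draws):
        sigma = dict(zip(model.tissues, sig))
        approx = model.predict(sigma, prior)
        exact = np.asarray(exact_forward(sigma), dtype=float)
        approx = approx.reshape(exact.shape)
        if approx.shape != exact.shape:
            raise ValueError("surrogate and exact forward disagree on geometry")
        for src in range(exact.shape[1] // 3):
            a = approx[:, 3 * src : 3 * src + 3].ravel()
            e = exact[:, 3 * src : 3 * src + 3].ravel()
            rows.append(
                {
                    "draw": i,
                    "source_index": src,
                    "direction": "xyz",
                    "rdm": rdm(a, e),
                    "lnmag": lnmag(a, e),
                }
            )
    table = pd.DataFrame(rows)
    return SurrogateValidation(
        max_rdm=float(table["rdm"].max()),
        mean_rdm=float(table["rdm"].mean()),
        max_abs_lnmag=float(table["lnmag"].abs().max()),
        mean_abs_lnmag=float(table["lnmag"].abs().mean()),
        table=table,
    )
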