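import numpy as np
import pytest

from eeguq.headmodel import ElectrodeArray, ShellModel
from eeguq.pipeline import MULTIVARIATE_TISSUES, build_surrogate, prepare_scenario
from eeguq.surrogate import ConductivityPrior


@pytest.fixture(scope="session")
def prior():
    return ConductivityPrior()


@pytest.fixture(scope="session")
def head5(prior):
    """Default five-shell head with standard conductivities."""
    return ShellModel(
        radii=np.array([0.070, 0.078, 0.080, 0.086, 0.092]),
        conductivities=np.array([prior.standard(t) for t in ("wm", "gm", "csf", "skull", "skin")]),
    )


@pytest.fixture(scope="session")
def elec12():
    """Twelve electrodes spread over the full scalp sphere."""
    rng = np.random.default_rng(42)
    pos = rng.normal(size=(12, 3))
    pos = 0.092 * pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return ElectrodeArray(tuple(f"E{i}" for i in range(12)), pos)


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario (noisy topography at SNR 7.5)."""
    return prepare_scenario(seed=1)


@pytest.fixture(scope="session")
def multi_model(scenario):
    """Degree-4 four-variate leadfield surrogate on the default scenario."""
    return build_surrogate(scenario, MULTIVARIATE_TISSUES, 4)


def homogeneous_sphere_series(dip_pos, moment, elec_pos, radius, sigma, n_terms=150):
    """Independent oracle: classical series for a dipole in a homogeneous
    conducting sphere with insulating exterior.

    Surface potential at angle γ from the dipole axis:
    V = 1/(4πσ) Σ_n (b^(n-1)/R^(n+1)) [ (2n+1) m_r P_n(cos γ)
        + ((2n+1)/n) P_n'(cos γ) (ê·t) ].
    """
    b = float(np.linalg.norm(dip_pos))
    if b < 1e-15:
        zhat = moment / np.linalg.norm(moment)
        m_r, tvec = float(np.linalg.norm(moment)), np.zeros(3)
    else:
        zhat = dip_pos / b
        m_r = float(moment @ zhat)
        tvec = moment - m_r * zhat
    e = elec_pos / np.linalg.norm(elec_pos, axis=1, keepdims=True)
    cos = np.clip(e @ zhat, -1, 1)
    edt = e @ tvec
    V = np.zeros(len(elec_pos))
    c0 = 1.0 / (4 * np.pi * sigma)
    P_prev = np.ones_like(cos)  # P_0
    P = cos.copy()  # P_1
    dP_prev = np.zeros_like(cos)
    dP = np.ones_like(cos)
    for n in range(1, n_terms + 1):
        bn1 = b ** (n - 1) if b > 0 else (1.0 if n == 1 else 0.0)
        f = c0 * bn1 / radius ** (n + 1)
        V += f * ((2 * n + 1) * m_r * P + ((2 * n + 1) / n) * dP * edt)
        P_next = ((2 * n + 1) * cos * P - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P
        P_prev, P = P, P_next
        dP_prev, dP = dP, dP_next
    return V


def saltelli_indices(f, d, n, rng, pairs=None):
    """Independent Monte Carlo Sobol oracle (Saltelli pick-freeze scheme).

    ``f`` maps an (n, d) array of uniform[-1,1] inputs to n outputs.
    Returns dicts of first-order (and closed second-order for the requested
    pairs) index estimates together with block-wise standard errors.
    """
    A = rng.uniform(-1, 1, size=(n, d))
    B = rng.uniform(-1, 1, size=(n, d))
    fA, fB = f(A), f(B)
    var = np.concatenate([fA, fB]).var(ddof=1)

    def pick_freeze(cols):
        AB = A.copy()
        AB[:, list(cols)] = B[:, list(cols)]
        prod = fB * (f(AB) - fA)
        blocks = np.array([p.mean() for p in np.split(prod, 10)]) / var
        return blocks.mean(), blocks.std(ddof=1) / np.sqrt(10)

    S1 = {i: pick_freeze([i]) for i in range(d)}
    S2 = {}
    for pair in pairs or []:
        closed, se = pick_freeze(pair)
        S2[pair] = (
            closed - S1[pair[0]][0] - S1[pair[1]][0],
            se + S1[pair[0]][1] + S1[pair[1]][1],
        )
    return S1, S2
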