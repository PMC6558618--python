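"""End-to-end uncertainty-quantification experiments.

Orchestrates the full analysis: build the default synthetic scenario,
reconstruct the reference source in two steps (coarse whole-brain scan,
then a fine cubic grid around the initial fit, both with standard
conductivities and the exact forward model), fit polynomial-chaos
surrogates of the fine-grid leadfield over the uncertain conductivities,
draw conductivity samples from the priors, and run fixed / rotating /
moving goal-function scans for every sample.  Summaries cover best-fit
conductivities, depth-vs-conductivity surfaces, and per-electrode Sobol
sensitivity reports.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .headmodel import (
    Dipole,
    ElectrodeArray,
    Leadfield,
    ShellModel,
    compute_leadfield,
)
from .metrics import electrodewise_std
from .scan import (
    OrientationFrame,
    build_orientation_frame,
    fit_moments,
    gof_profile,
    scan_moving,
)
from .sourcespace import (
    SourceSpace,
    build_cubic_grid,
    coarse_brain_space,
    mask_positions,
    require_nonempty,
)
from .surrogate import (
    ConductivityPrior,
    PCEModel,
    fit_pce,
    rescale,
    sample_prior,
    sobol_indices,
    sparse_grid_nodes,
    unrescale,
)
from .synthdata import (
    DEFAULT_SNR,
    SyntheticSEP,
    default_head,
    default_truth_dipole,
    generate_electrodes,
    generate_measurement,
)

#: Tissues of the multivariate experiment: CSF is dropped as a source of
#: uncertainty (its prior interval is too narrow to matter).
MULTIVARIATE_TISSUES = ("skin", "skull", "gm", "wm")
UNIVARIATE_TISSUES = ("skin", "skull", "csf", "gm", "wm")
DEFAULT_DEGREE = 4
DEFAULT_N_SAMPLES = 10_000

#: Desk-scale scenario defaults: 5^3 fine lattice, 8 mm coarse lattice.
DEFAULT_GRID_EXTENT = 0.012
DEFAULT_GRID_SPACING = 0.003
DEFAULT_COARSE_SPACING = 0.008


@dataclass
class Scenario:
    """Everything one experiment run needs, with the reference fit.

    Built by :func:`prepare_scenario`; holds the head geometry, prior,
    electrode cap, synthetic measurement, the fine source space centred on
    the initial reconstruction, the exact leadfield at standard
    conductivities, and the reference position/orientation frame used by
    fixed and rotating scans.  Surrogates are cached per uncertain set.
    """

    shells: ShellModel
    prior: ConductivityPrior
    electrodes: ElectrodeArray
    truth: Dipole
    measurement: SyntheticSEP
    fissure_direction: np.ndarray
    fine_space: SourceSpace
    leadfield_standard: Leadfield
    reference_index: int
    reference_position: np.ndarray
    reference_orientation: np.ndarray
    reference_moment: np.ndarray
    frame: OrientationFrame
    seed: int
    _surrogates: dict = field(default_factory=dict, repr=False)

    @property
    def source_positions(self) -> np.ndarray:
        return self.leadfield_standard.source_positions

    def scenario_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (
            self.shells.radii,
            self.shells.conductivities,
            self.electrodes.positions,
            self.truth.position,
            self.truth.moment,
            self.measurement.u_meas,
            self.source_positions,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:12]

    def exact_gain(self, sigma: dict[str, float]) -> np.ndarray:
        """Exact average-referenced fine-grid gain for a conductivity set."""
        shells = self.shells.with_conductivities(sigma)
        lf = compute_leadfield(self.source_positions, self.electrodes, shells)
        return lf.gain


def prepare_scenario(
    seed: int = 0,
    snr: float = DEFAULT_SNR,
    n_electrodes: int = 70,
    grid_extent: float = DEFAULT_GRID_EXTENT,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    coarse_spacing: float = DEFAULT_COARSE_SPACING,
    truth: Dipole | None = None,
) -> Scenario:
    """Build the default synthetic scenario and its reference reconstruction.

    The reference fit follows the two-step scheme: a moving scan over a
    coarse whole-brain lattice with standard conductivities gives the
    initial position; the fine cubic grid is centred there, masked to the
    brain shells, and scanned again to fix the reference position and
    orientation for the fixed/rotating variants.
    """
    ss = np.random.SeedSequence(seed)
    s_elec, s_meas = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    shells, prior, frame_cfg = default_head()
    electrodes = generate_electrodes(n_electrodes, seed=s_elec, radius=shells.outer_radius)
    fissure = np.asarray(frame_cfg["fissure_direction"], dtype=float)
    if truth is None:
        truth = default_truth_dipole(shells, fissure)
    measurement = generate_measurement(truth, shells, electrodes, snr=snr, seed=s_meas)

    coarse = require_nonempty(coarse_brain_space(shells, coarse_spacing))
    lf_coarse = compute_leadfield(coarse, electrodes, shells)
    initial = scan_moving(measurement.u_meas, lf_coarse, shells)

    grid = build_cubic_grid(initial.position, grid_extent, grid_spacing)
    fine = require_nonempty(mask_positions(grid, shells))
    lf_fine = compute_leadfield(fine, electrodes, shells)
    ref = scan_moving(measurement.u_meas, lf_fine, shells)
    ref_orientation = ref.moment / np.linalg.norm(ref.moment)
    frame = build_orientation_frame(ref_orientation, ref.position, fissure)
    return Scenario(
        shells=shells,
        prior=prior,
        electrodes=electrodes,
        truth=truth,
        measurement=measurement,
        fissure_direction=fissure,
        fine_space=fine,
        leadfield_standard=lf_fine,
        reference_index=ref.best_index,
        reference_position=ref.position,
        reference_orientation=ref_orientation,
        reference_moment=ref.moment,
        frame=frame,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# surrogate construction
# ---------------------------------------------------------------------------


def collocation_conductivities(
    prior: ConductivityPrior, tissues, degree: int = DEFAULT_DEGREE
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Sparse-grid nodes/weights plus the full conductivity sets (all five
    tissues, uncertain ones at the node values, others at standard)."""
    tissues = list(tissues)
    nodes, weights = sparse_grid_nodes(len(tissues), degree)
    sig = unrescale(nodes, prior, tissues)
    full = pd.DataFrame(
        {t: np.full(nodes.shape[0], prior.standard(t)) for t in prior.tissues}
    )
    for j, t in enumerate(tissues):
        full[t] = sig[:, j]
    return nodes, weights, full


def build_surrogate(
    scenario: Scenario, tissues, degree: int = DEFAULT_DEGREE
) -> PCEModel:
    """Degree-``degree`` PCE of all fine-grid leadfield entries over the
    given uncertain tissues; cached on the scenario."""
    key = (tuple(tissues), degree)
    if key in scenario._surrogates:
        return scenario._surrogates[key]
    nodes, weights, sigma_sets = collocation_conductivities(
        scenario.prior, tissues, degree
    )
    n_e = len(scenario.electrodes)
    evals = np.empty((nodes.shape[0], scenario.leadfield_standard.gain.size))
    for k in range(nodes.shape[0]):
        evals[k] = scenario.exact_gain(sigma_sets.iloc[k].to_dict()).ravel()
    model = fit_pce(
        evals,
        nodes,
        weights,
        tissues,
        degree,
        scenario.prior.interval_array(tissues),
        meta={
            "electrode_labels": scenario.electrodes.labels,
            "source_positions": scenario.source_positions,
            "gain_shape": (n_e, 3 * scenario.source_positions.shape[0]),
            "n_nodes": nodes.shape[0],
        },
    )
    scenario._surrogates[key] = model
    return model


def experiment_node_counts(
    prior: ConductivityPrior | None = None, degree: int = DEFAULT_DEGREE
) -> dict:
    """Distinct exact forward evaluations for the full experiment plan:
    five univariate expansions plus one four-variate expansion.

    Returns per-expansion node counts and the number of distinct
    conductivity sets over the union (nodes shared between expansions —
    e.g. the all-standard set — are counted once)."""
    prior = prior or ConductivityPrior()
    per = {}
    seen = set()
    plans = [((t,), f"uni_{t}") for t in UNIVARIATE_TISSUES]
    plans.append((MULTIVARIATE_TISSUES, "multi"))
    for tissues, name in plans:
        _, _, sigma_sets = collocation_conductivities(prior, tissues, degree)
        per[name] = len(sigma_sets)
        for row in sigma_sets.itertuples(index=False):
            seen.add(tuple(round(v, 10) for v in row))
    per["total_distinct"] = len(seen)
    return per


# ---------------------------------------------------------------------------
# sampling experiments
# ---------------------------------------------------------------------------


def _scan_samples(
    scenario: Scenario,
    gains: np.ndarray,
) -> pd.DataFrame:
    """Run the three scan variants on a stack of sample leadfield gains.

    ``gains``: (n_samples, n_electrodes, 3 * n_positions).
    """
    u = scenario.measurement.u_meas
    n_s, n_e, _ = gains.shape
    P = scenario.source_positions.shape[0]
    blocks = gains.reshape(n_s, n_e, P, 3).transpose(0, 2, 1, 3)  # (S, P, n_e, 3)

    # moving scan
    gofs = gof_profile(u, blocks)  # (S, P)
    best = np.argmax(gofs, axis=1)
    mov_gof = gofs[np.arange(n_s), best]
    mov_pos = scenario.source_positions[best]
    depth = scenario.shells.inner_skull_radius - np.linalg.norm(mov_pos, axis=1)
    best_blocks = blocks[np.arange(n_s), best]  # (S, n_e, 3)
    mov_moments = fit_moments(u, best_blocks)
    mov_strength = np.linalg.norm(mov_moments, axis=1)

    # rotating scan at the reference position
    ref_blocks = blocks[:, scenario.reference_index]  # (S, n_e, 3)
    rot_gof = gof_profile(u, ref_blocks)
    rot_moments = fit_moments(u, ref_blocks)
    rot_norm = np.linalg.norm(rot_moments, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mh = rot_moments / rot_norm[:, None]
    theta = np.degrees(np.arcsin(np.clip(mh @ scenario.frame.e2, -1, 1)))
    phi = np.degrees(np.arctan2(mh @ scenario.frame.e3, mh @ scenario.frame.e1))

    # fixed scan: reference position and orientation, free signed strength
    l_fix = ref_blocks @ scenario.reference_orientation  # (S, n_e)
    ll = np.einsum("ij,ij->i", l_fix, l_fix)
    lu = l_fix @ u
    with np.errstate(invalid="ignore", divide="ignore"):
        fixed_strength = np.where(ll > 0, lu / np.where(ll > 0, ll, 1.0), 0.0)
        fixed_gof = np.where(ll > 0, lu**2 / (np.where(ll > 0, ll, 1.0) * (u @ u)), 0.0)

    return pd.DataFrame(
        {
            "fixed_strength_nAm": fixed_strength * 1e9,
            "fixed_gof": fixed_gof,
            "rot_phi_deg": phi,
            "rot_theta_deg": theta,
            "rot_gof": rot_gof,
            "rot_strength_nAm": rot_norm * 1e9,
            "mov_best_index": best,
            "mov_x_mm": mov_pos[:, 0] * 1e3,
            "mov_y_mm": mov_pos[:, 1] * 1e3,
            "mov_z_mm": mov_pos[:, 2] * 1e3,
            "mov_depth_mm": depth * 1e3,
            "mov_strength_nAm": mov_strength * 1e9,
            "mov_gof": mov_gof,
        }
    )


def _run_experiment(
    scenario: Scenario,
    uncertain: tuple[str, ...],
    n: int,
    seed: int,
    degree: int = DEFAULT_DEGREE,
    chunk: int = 500,
) -> pd.DataFrame:
    """Shared driver for the univariate and multivariate experiments."""
    prior = scenario.prior
    active = tuple(t for t in uncertain if prior.width(t) > 0)
    samples = sample_prior(prior, active, n, seed) if active else np.empty((n, 0))

    table = pd.DataFrame(
        {f"sigma_{t}": np.full(n, prior.standard(t)) * 1e3 for t in prior.tissues}
    )
    for j, t in enumerate(active):
        table[f"sigma_{t}"] = samples[:, j] * 1e3  # mS/m

    if not active:
        gain = scenario.exact_gain(prior.standard_set())
        scans = _scan_samples(scenario, np.repeat(gain[None], n, axis=0))
    else:
        model = build_surrogate(scenario, active, degree)
        parts = []
        n_e = len(scenario.electrodes)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            xi = rescale(samples[sl], prior, active)
            gains = model.predict_xi(xi).reshape(sl.stop - sl.start, n_e, -1)
            parts.append(_scan_samples(scenario, gains))
        scans = pd.concat(parts, ignore_index=True)

    out = pd.concat([table, scans], axis=1)
    out.insert(0, "sample_id", np.arange(n))
    out.attrs.update(
        uncertain_set=active,
        n=n,
        seed=seed,
        scenario_hash=scenario.scenario_hash(),
    )
    return out


def run_univariate(
    tissue: str,
    scenario: Scenario,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    degree: int = DEFAULT_DEGREE,
) -> pd.DataFrame:
    """Vary one tissue conductivity over its prior, others at standard;
    scan every sampled leadfield with all three variants."""
    if tissue not in scenario.prior.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    return _run_experiment(scenario, (tissue,), n, seed, degree)


def run_multivariate(
    scenario: Scenario,
    n: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    degree: int = DEFAULT_DEGREE,
    tissues: tuple[str, ...] = MULTIVARIATE_TISSUES,
) -> pd.DataFrame:
    """Vary skin, skull, gray- and white-matter conductivities jointly
    (CSF excluded by default)."""
    return _run_experiment(scenario, tuple(tissues), n, seed, degree)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def best_fit(table: pd.DataFrame) -> tuple[float, dict[str, float], float]:
    """Maximal moving-scan GoF, its conductivity set (mS/m), and the GoF
    standard deviation over the table; ties keep the lowest sample_id."""
    if len(table) == 0:
        raise ValueError("empty experiment table")
    i = int(table["mov_gof"].idxmax())
    sig = {
        c.removeprefix("sigma_"): float(table.loc[i, c])
        for c in table.columns
        if c.startswith("sigma_")
    }
    sd = float(table["mov_gof"].std(ddof=1)) if len(table) > 1 else 0.0
    return float(table.loc[i, "mov_gof"]), sig, sd


@dataclass(frozen=True)
class DepthSurface:
    """Binned median source depth over two conductivities."""

    tissue_x: str
    tissue_y: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    median_depth_mm: np.ndarray  # (bins_y, bins_x), NaN where empty
    counts: np.ndarray

    def to_csv(self, path) -> None:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = [
            {
                f"{self.tissue_x}_mSm": xc[i],
                f"{self.tissue_y}_mSm": yc[j],
                "median_depth_mm": self.median_depth_mm[j, i],
                "count": int(self.counts[j, i]),
            }
            for j in range(len(yc))
            for i in range(len(xc))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def depth_surface(
    table: pd.DataFrame, tissue_x: str, tissue_y: str, bins: int = 10
) -> DepthSurface:
    """Median moving-scan depth binned over two uncertain conductivities."""
    for t in (tissue_x, tissue_y):
        if t not in table.attrs.get("uncertain_set", ()):
            raise ValueError(f"tissue {t!r} was not varied in this experiment")
    x = table[f"sigma_{tissue_x}"].to_numpy()
    y = table[f"sigma_{tissue_y}"].to_numpy()
    depth = table["mov_depth_mm"].to_numpy()
    x_edges = np.linspace(x.min(), x.max(), bins + 1)
    y_edges = np.linspace(y.min(), y.max(), bins + 1)
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, bins - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, bins - 1)
    med = np.full((bins, bins), np.nan)
    counts = np.zeros((bins, bins), dtype=int)
    for j in range(bins):
        for i in range(bins):
            sel = (ix == i) & (iy == j)
            counts[j, i] = sel.sum()
            if counts[j, i]:
                med[j, i] = float(np.median(depth[sel]))
    return DepthSurface(tissue_x, tissue_y, x_edges, y_edges, med, counts)


def sensitivity_report(
    model: PCEModel,
    scenario: Scenario,
    n_std_samples: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-electrode first- and second-order Sobol indices for the fixed
    reference dipole, plus the per-electrode standard deviation.

    The leadfield expansion is contracted with the reference source (its
    grid position and fitted moment), giving a chaos expansion of each
    electrode potential; Sobol indices come from its coefficients, the
    standard deviation from prior samples of the contracted expansion.
    Electrodes whose potential does not vary are flagged (NaN indices).
    """
    if model.dims < 2:
        raise ValueError("sensitivity report needs >= 2 uncertain tissues")
    n_e = len(scenario.electrodes)
    P = scenario.source_positions.shape[0]
    coef = model.coefficients.reshape(-1, n_e, P, 3)
    pot_coef = coef[:, :, scenario.reference_index, :] @ scenario.reference_moment
    pot_model = PCEModel(
        tissues=model.tissues,
        degree=model.degree,
        multi_indices=model.multi_indices,
        coefficients=pot_coef,
        bounds=model.bounds,
    )
    table = sobol_indices(pot_model, max_order=2)
    draws = sample_prior(scenario.prior, model.tissues, n_std_samples, seed)
    xi = rescale(draws, scenario.prior, model.tissues)
    std = electrodewise_std(pot_model.predict_xi(xi))

    volts = pot_model.predict(scenario.prior.standard_set(), scenario.prior)
    df = pd.DataFrame(
        {
            "electrode": scenario.electrodes.labels,
            "voltage_uV": volts * 1e6,
            "std_uV": std * 1e6,
            "zero_variance": table.zero_variance,
        }
    )
    for subset in table.subsets:
        df["S_" + "_".join(subset)] = table.indices[subset]
    s_cols = [c for c in df.columns if c.startswith("S_")]
    df["residual"] = 1.0 - df[s_cols].sum(axis=1)
    df.loc[df["zero_variance"], "residual"] = np.nan
    return df.sort_values("voltage_uV", ascending=False).reset_index(drop=True)
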