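"""Synthetic study inputs: default head, electrode cap, and noisy topography.

Generates everything the analysis consumes so the full pipeline runs
without any measured data: a five-shell head with standard literature
conductivities, a quasi-uniform ~70-channel electrode cap, a superficial
predominantly tangential ground-truth dipole, and a single-topography
measurement at a configurable signal-to-noise ratio (default 7.5, the
evoked-response power ratio the analysis conditions on).

The SNR of the source study is a temporal power ratio (component peak power
over prestimulus power).  A single synthetic topography has no time axis,
so SNR is reinterpreted spatially: noise variance is chosen as
``mean(signal²) / snr`` across channels, preserving the single number the
analysis conditions on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .headmodel import (
    DEFAULT_RADII_M,
    Dipole,
    ElectrodeArray,
    ShellModel,
    apply_average_reference,
    potential_layered_sphere,
)
from .scan import DEFAULT_FISSURE_DIRECTION
from .surrogate import ConductivityPrior

#: Default channel count: a 74-channel cap minus four excluded noisy channels.
DEFAULT_N_ELECTRODES = 70
DEFAULT_SNR = 7.5

#: Scenario defaults (package choices, not measured facts): truth dipole in
#: the gray-matter shell at 8 mm depth below the inner skull, predominantly
#: tangential with a small radial component, 10 nAm.
DEFAULT_TRUTH_DIRECTION = (0.30, 0.10, 0.95)
DEFAULT_TRUTH_DEPTH_M = 0.008
DEFAULT_TRUTH_RADIAL_ANGLE_DEG = 15.0
DEFAULT_TRUTH_STRENGTH_AM = 10e-9


def default_head() -> tuple[ShellModel, ConductivityPrior, dict]:
    """Five-shell head with standard conductivities, the default prior and
    the orientation-frame configuration (fissure direction +y)."""
    prior = ConductivityPrior()
    shells = ShellModel(
        radii=np.array(DEFAULT_RADII_M),
        conductivities=np.array([prior.standard(t) for t in ("wm", "gm", "csf", "skull", "skin")]),
    )
    return shells, prior, {"fissure_direction": np.array(DEFAULT_FISSURE_DIRECTION)}


def generate_electrodes(
    n: int = DEFAULT_N_ELECTRODES,
    cap_fraction: float = 0.55,
    seed: int = 0,
    radius: float = DEFAULT_RADII_M[-1],
) -> ElectrodeArray:
    """Quasi-uniform electrode cap on the upper sphere.

    Uses a Fibonacci (golden-angle) spiral over the spherical cap covering
    ``cap_fraction`` of the sphere area, projected to the scalp radius.  The
    seed only rotates the spiral azimuthally, keeping layouts deterministic.
    """
    if n < 4:
        raise ValueError("need at least 4 electrodes")
    if not (0 < cap_fraction <= 1):
        raise ValueError("cap_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = 1.0 - 2.0 * cap_fraction * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    ang = phase + golden * i
    pos = radius * np.column_stack([rho * np.cos(ang), rho * np.sin(ang), z])
    labels = tuple(f"E{k+1:02d}" for k in i)
    return ElectrodeArray(labels, pos)


@dataclass(frozen=True)
class SyntheticSEP:
    """A synthetic single-topography measurement with known ground truth."""

    u_meas: np.ndarray  # referenced potentials (V)
    truth: Dipole
    noise_sd: float
    snr_target: float
    snr_realized: float
    seed: int

    def to_csv(self, path, labels) -> None:
        import pandas as pd

        pd.DataFrame({"label": labels, "u_volts": self.u_meas}).to_csv(path, index=False)


def generate_measurement(
    truth: Dipole,
    shells: ShellModel,
    electrodes: ElectrodeArray,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
) -> SyntheticSEP:
    """Average-referenced forward of ``truth`` plus i.i.d. Gaussian noise.

    The per-channel noise variance is ``mean(u²)/snr`` so the realised
    spatial power ratio matches the target on average; ``snr=inf`` returns
    the noiseless forward exactly.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive (or inf)")
    u0 = apply_average_reference(potential_layered_sphere(truth, electrodes, shells))
    power = float(np.mean(u0**2))
    if power == 0.0:
        raise ValueError("silent source configuration: zero forward field")
    if np.isinf(snr):
        return SyntheticSEP(u0, truth, 0.0, snr, np.inf, seed)
    sd = np.sqrt(power / snr)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sd, size=u0.shape)
    realized = power / float(np.mean(eps**2))
    return SyntheticSEP(u0 + eps, truth, sd, snr, realized, seed)


def default_truth_dipole(
    shells: ShellModel,
    fissure_direction=DEFAULT_FISSURE_DIRECTION,
    depth: float = DEFAULT_TRUTH_DEPTH_M,
    radial_angle_deg: float = DEFAULT_TRUTH_RADIAL_ANGLE_DEG,
    strength: float = DEFAULT_TRUTH_STRENGTH_AM,
) -> Dipole:
    """Ground-truth dipole of the default scenario.

    Placed at ``depth`` below the inner skull along a fixed off-vertical
    direction inside the electrode cap; oriented mostly tangentially
    (toward the fissure direction) with a ``radial_angle_deg`` radial tilt.
    """
    direction = np.asarray(DEFAULT_TRUTH_DIRECTION, dtype=float)
    rhat = direction / np.linalg.norm(direction)
    r = shells.inner_skull_radius - depth
    position = r * rhat
    fis = np.asarray(fissure_direction, dtype=float)
    tang = fis - (fis @ rhat) * rhat
    tang /= np.linalg.norm(tang)
    a = np.radians(radial_angle_deg)
    orientation = np.cos(a) * tang + np.sin(a) * rhat
    return Dipole(position, strength * orientation)
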