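"""Candidate source grids: cubic lattices and tissue masking.

Implements the two-step source-space scheme used for goal-function scans:
a coarse lattice over the whole brain region fixes an initial estimate, then
a fine cubic grid centred on it is masked to the allowed brain tissues with
a safety margin below the brain/CSF interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .headmodel import ShellModel

REASON_OK = "ok"
REASON_OUTSIDE = "outside_brain"
REASON_CSF = "too_close_to_csf"

#: Default margin kept below the brain/CSF boundary (m).  Motivated by the
#: floor effect seen in moving scans when sources hit the interface.
DEFAULT_MIN_CSF_DISTANCE = 0.002


@dataclass(frozen=True)
class SourceSpace:
    """A set of candidate source positions with a validity mask.

    ``positions`` holds the full point set (lattice order when grid-born);
    ``mask_reasons`` flags each point ``ok``, ``outside_brain`` or
    ``too_close_to_csf``.  Scans operate on :attr:`retained` only.
    """

    positions: np.ndarray  # (n, 3) metres, full set
    mask_reasons: np.ndarray  # (n,) str
    grid_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        reasons = np.asarray(self.mask_reasons)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "mask_reasons", reasons)
        if pos.shape[0] != reasons.shape[0]:
            raise ValueError("mask_reasons must align with positions")
        if pos.shape[0] != np.unique(pos, axis=0).shape[0]:
            raise ValueError("positions must be unique")

    @property
    def ok_mask(self) -> np.ndarray:
        return self.mask_reasons == REASON_OK

    @property
    def retained(self) -> np.ndarray:
        """(n_ok, 3) positions flagged ``ok``."""
        return self.positions[self.ok_mask]

    @property
    def n_total(self) -> int:
        return self.positions.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.ok_mask.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "x_mm": self.positions[:, 0] * 1e3,
                "y_mm": self.positions[:, 1] * 1e3,
                "z_mm": self.positions[:, 2] * 1e3,
                "mask_reason": self.mask_reasons,
            }
        ).to_csv(path, index=False)


def build_cubic_grid(center, extent: float, spacing: float) -> SourceSpace:
    """Regular cubic lattice spanning ``extent`` per axis around ``center``.

    ``extent`` is the total span per axis (endpoints inclusive, i.e. the
    lattice covers center ± extent/2), so the node count is
    ``(extent/spacing + 1)**3``; ``extent`` must be an integer multiple of
    ``spacing``.  An extent of 0 yields the single center point.
    """
    center = np.asarray(center, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if extent < 0:
        raise ValueError("extent must be non-negative")
    k = extent / spacing
    if abs(k - round(k)) > 1e-9 * max(1.0, k):
        raise ValueError(
            f"extent ({extent}) must be an integer multiple of spacing ({spacing})"
        )
    k = int(round(k))
    axis = (np.arange(k + 1) - k / 2.0) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = center + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return SourceSpace(
        positions=pts,
        mask_reasons=np.full(pts.shape[0], REASON_OK, dtype=object),
        grid_meta={"center": center, "extent": float(extent), "spacing": float(spacing)},
    )


def mask_positions(
    space: SourceSpace,
    shells: ShellModel,
    allowed_tissues=("gm", "wm"),
    min_csf_distance: float = DEFAULT_MIN_CSF_DISTANCE,
) -> SourceSpace:
    """Mask lattice positions to the allowed brain tissues.

    A position is retained when its radius falls in a shell whose label is
    in ``allowed_tissues`` AND it lies at least ``min_csf_distance`` below
    the outer boundary of the allowed region (the brain/CSF interface for
    the default labels).  Removals are recorded with reason codes.
    """
    allowed = set(allowed_tissues)
    if not allowed.issubset(set(shells.tissue_labels)):
        missing = allowed - set(shells.tissue_labels)
        raise ValueError(f"shells lack the allowed tissue labels {sorted(missing)}")
    boundary = max(
        r for r, t in zip(shells.radii, shells.tissue_labels) if t in allowed
    )
    radii = np.linalg.norm(space.positions, axis=1)
    reasons = np.full(space.n_total, REASON_OK, dtype=object)
    for i, r in enumerate(radii):
        if r > shells.outer_radius or shells.tissue_at(r) not in allowed:
            reasons[i] = REASON_OUTSIDE
        elif boundary - r < min_csf_distance:
            reasons[i] = REASON_CSF
    return SourceSpace(space.positions, reasons, dict(space.grid_meta))


def coarse_brain_space(
    shells: ShellModel,
    spacing: float,
    allowed_tissues=("gm", "wm"),
    min_csf_distance: float = DEFAULT_MIN_CSF_DISTANCE,
) -> SourceSpace:
    """Lattice over the bounding cube of the brain region, masked to the
    allowed tissues; the whole-brain first step of the two-step scheme."""
    r_brain = shells.brain_radius
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > r_brain:
        raise ValueError(
            f"spacing {spacing} exceeds the brain radius {r_brain}"
        )
    k = int(np.floor(r_brain / spacing))
    grid = build_cubic_grid(np.zeros(3), extent=2 * k * spacing, spacing=spacing)
    return mask_positions(grid, shells, allowed_tissues, min_csf_distance)


def require_nonempty(space: SourceSpace) -> SourceSpace:
    """Refuse an all-masked space with a clear error (scan entry guard)."""
    if space.n_retained == 0:
        raise DomainError("source space has no retained positions (all masked)")
    return space
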