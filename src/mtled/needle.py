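"""Kinematic needle-tissue interaction model with two parameters.

Needle insertion is modeled without any contact or cutting mechanics: the
problem is posed as Dirichlet-type, driven by prescribed motion of a small set
of nodes, which is what makes the computed displacement field only weakly
sensitive to the tissue's material properties.

Two phases:

* **indentation** — the surface nodes under the needle tip move with the tip
  (full prescribed displacement) while the maximum principal Green strain near
  the entry point is monitored;
* **penetration** — once that strain exceeds the puncture strain ``eps_p``,
  nodes within a sleeve around the needle shaft are driven by the fraction
  ``C_D`` (deformation coefficient) of the needle displacement accumulated
  since they were captured.

Both parameters are image-identifiable: ``C_D = U2/U1`` where U1 is the
insertion depth and U2 the maximum surface deflection along the shaft.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import Grid

__all__ = [
    "NeedleSpec", "KinematicParams", "InsertionMeasurement", "PhaseState",
    "NeedleDriver", "NeedleModelError",
    "estimate_cd", "select_contact_nodes", "indentation_update",
    "check_puncture", "update_driven_set", "penetration_update",
]


class NeedleModelError(ValueError):
    pass


@dataclass
class NeedleSpec:
    """Needle geometry and insertion schedule.

    ``axis`` points in the direction of motion (into the tissue); depth is the
    distance traveled by the tip from the entry point, mm.
    """

    entry_point: np.ndarray
    axis: np.ndarray
    diameter: float = 1.6
    max_depth: float = 15.0
    tip_half_angle_deg: float = 15.0  # symmetric conical tip descriptor

    def __post_init__(self):
        self.entry_point = np.asarray(self.entry_point, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(self.axis)
        if nrm == 0:
            raise NeedleModelError("needle axis must be a nonzero vector")
        self.axis = self.axis / nrm
        if self.diameter <= 0:
            raise NeedleModelError("needle diameter must be positive")
        if self.max_depth < 0:
            raise NeedleModelError("insertion depth must be non-negative")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class KinematicParams:
    """The model's two physical parameters plus geometric capture radii (mm).

    ``fade_steps`` is the number of solver pseudo-time steps over which a
    captured node's displacement blends from its free value into the pure
    kinematic rule C_D * (depth - activation).  The blend is a numerical
    regularization of the capture transient only: every settled state
    satisfies the pure rule exactly, so the final prescription is purely
    geometric and identical across material models.
    """

    eps_p: float = 1e-5
    cd: float = 0.4
    capture_radius: float | None = None   # default: needle radius + local spacing
    monitor_radius: float | None = None   # default: 2 x needle radius
    fade_steps: int = 400                 # solver steps to blend a capture in

    def __post_init__(self):
        if self.eps_p < 0:
            raise NeedleModelError("puncture strain must be non-negative")
        if not 0.0 <= self.cd <= 1.0:
            raise NeedleModelError("deformation coefficient must lie in [0, 1]")


@dataclass
class InsertionMeasurement:
    """Image-derived observables: insertion depth U1, surface deflection U2 (mm)."""

    U1: float
    U2: float


def estimate_cd(meas: InsertionMeasurement) -> float:
    """Deformation coefficient C_D = U2/U1, clipped to [0, 1]."""
    if meas.U1 <= 0:
        raise NeedleModelError("insertion depth U1 must be positive")
    return float(np.clip(meas.U2 / meas.U1, 0.0, 1.0))


@dataclass
class PhaseState:
    """Phase machine of one insertion: indentation -> penetration, once."""

    phase: str = "indentation"
    contact_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    driven_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    activation_depths: np.ndarray = field(default_factory=lambda: np.empty(0))
    capture_offsets: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    capture_steps: np.ndarray = field(default_factory=lambda: np.empty(0))
    puncture_depth: float = float("nan")
    transitions: int = 0

    def to_penetration(self, depth: float, axis=None, step: float = 0.0) -> None:
        if self.phase != "indentation":
            raise NeedleModelError("phase already switched to penetration")
        self.phase = "penetration"
        self.puncture_depth = depth
        self.transitions += 1
        # continuity across the switch: contact nodes are captured immediately
        # with their indentation displacement (depth * axis) as the offset
        self.driven_ids = self.contact_nodes.copy()
        self.activation_depths = np.full(len(self.driven_ids), depth)
        self.capture_steps = np.full(len(self.driven_ids), float(step))
        if axis is None:
            self.capture_offsets = np.zeros((len(self.driven_ids), 3))
        else:
            self.capture_offsets = np.broadcast_to(
                depth * np.asarray(axis, dtype=float),
                (len(self.driven_ids), 3)).copy()


def select_contact_nodes(grid: Grid, spec: NeedleSpec) -> np.ndarray:
    """Surface nodes within the needle footprint at the entry point.

    Falls back to the single nearest top-surface node (with a warning) on
    grids coarser than the needle diameter.
    """
    top = grid.boundary_sets.get("top")
    if top is None or len(top) == 0:
        raise NeedleModelError("grid has no 'top' boundary set")
    d = np.linalg.norm(grid.nodes[top] - spec.entry_point, axis=1)
    inside = top[d <= spec.radius + 1e-12]
    if len(inside) == 0:
        nearest = top[int(np.argmin(d))]
        if d.min() > 3.0 * spec.radius:
            raise NeedleModelError(
                "no surface node within the needle footprint; refine the grid "
                f"(nearest node {d.min():.2f} mm away)")
        warnings.warn("single contact node (grid coarser than needle footprint)",
                      stacklevel=2)
        return np.array([nearest], dtype=np.int64)
    if len(inside) == 1:
        warnings.warn("only one node in the needle footprint", stacklevel=2)
    return np.sort(inside.astype(np.int64))


def indentation_update(phase: PhaseState, spec: NeedleSpec,
                       depth: float) -> tuple[np.ndarray, np.ndarray]:
    """Prescribed displacements during indentation: contact nodes move with the tip."""
    if phase.phase != "indentation":
        raise NeedleModelError("indentation_update called in penetration phase")
    vals = np.broadcast_to(depth * spec.axis, (len(phase.contact_nodes), 3)).copy()
    return phase.contact_nodes, vals


def check_puncture(max_strain: float, eps_p: float) -> bool:
    """Puncture iff the monitored strain strictly exceeds eps_p (tie: no puncture)."""
    return bool(max_strain > eps_p)


def monitored_cells(grid: Grid, spec: NeedleSpec, monitor_radius: float) -> np.ndarray:
    """Cells whose quadrature point lies near the entry point (strain monitor)."""
    d = np.linalg.norm(grid.quad_points - spec.entry_point, axis=1)
    ids = np.flatnonzero(d <= monitor_radius)
    if len(ids) == 0:
        raise NeedleModelError(
            f"no quadrature point within {monitor_radius} mm of the entry point")
    return ids


def update_driven_set(phase: PhaseState, grid: Grid, spec: NeedleSpec,
                      capture_radius: float, depth: float,
                      u: np.ndarray | None = None,
                      step: float = 0.0) -> PhaseState:
    """Capture nodes in the sleeve around the traversed shaft.

    A node is captured when its perpendicular distance to the needle axis is
    at most ``capture_radius`` and its axial position lies between the entry
    point and the current tip; its activation depth is the current depth.
    Nodes are never released, so the set grows monotonically.

    The node's displacement at capture is recorded as an offset that
    :func:`penetration_update` fades out over subsequent solver steps, so
    capture is continuous (no snap) while every settled state obeys the pure
    kinematic rule — which is therefore identical across material models,
    underpinning the displacement-independence property.
    """
    if phase.phase != "penetration":
        raise NeedleModelError("update_driven_set called before puncture")
    rel = grid.nodes - spec.entry_point
    s = rel @ spec.axis                    # axial coordinate along the shaft
    radial = np.linalg.norm(rel - s[:, None] * spec.axis, axis=1)
    near = np.flatnonzero((radial <= capture_radius) & (s >= -1e-9)
                          & (s <= depth + 1e-9))
    new = np.setdiff1d(near, phase.driven_ids, assume_unique=False)
    if len(near) == 0 and len(phase.driven_ids) == 0:
        warnings.warn("capture radius smaller than nodal spacing: empty driven set",
                      stacklevel=2)
    if len(new):
        off = (u[new].copy() if u is not None else np.zeros((len(new), 3)))
        phase.driven_ids = np.concatenate([phase.driven_ids, new])
        phase.activation_depths = np.concatenate(
            [phase.activation_depths, np.full(len(new), depth)])
        phase.capture_offsets = np.concatenate([phase.capture_offsets, off])
        phase.capture_steps = np.concatenate(
            [phase.capture_steps, np.full(len(new), float(step))])
    return phase


def penetration_update(phase: PhaseState, spec: NeedleSpec, cd: float,
                       depth: float, fade_steps: int = 0,
                       step: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Prescribed displacements during penetration.

    Each driven node is displaced along the axis by ``cd`` times the needle
    travel since its activation, u = C_D * (depth - activation) * axis, plus
    its capture offset faded out smoothly over ``fade_steps`` solver steps.
    Once the fade has elapsed the prescription is exactly the pure kinematic
    rule, so any settled state obeys it.
    """
    if phase.phase != "penetration":
        raise NeedleModelError("penetration_update called during indentation")
    travel = depth - phase.activation_depths
    if np.any(travel < -1e-12):
        raise NeedleModelError("needle retraction is not modeled")
    travel = np.clip(travel, 0.0, None)
    vals = cd * travel[:, None] * spec.axis
    if fade_steps > 0 and len(phase.capture_offsets):
        s = np.clip((step - phase.capture_steps) / fade_steps, 0.0, 1.0)
        w = (1.0 - s) ** 2 * (1.0 + 2.0 * s)  # smoothstep complement, C1
        vals = vals + w[:, None] * phase.capture_offsets
    return phase.driven_ids, vals


class NeedleDriver:
    """Depth-schedule driver wiring the phase machine into the explicit solver.

    Exposes ``targets(depth, u, strain_fn)`` for
    :func:`mtled.dynamics.run_quasi_static`; ``strain_fn`` evaluates the
    maximum principal Green strain over the monitored quadrature points.
    """

    def __init__(self, grid: Grid, spec: NeedleSpec, params: KinematicParams):
        self.grid = grid
        self.spec = spec
        self.params = params
        spacing = float(np.median(grid.nodal_spacing()))
        self.capture_radius = (params.capture_radius
                               if params.capture_radius is not None
                               else spec.radius + spacing)
        self.monitor_radius = (params.monitor_radius
                               if params.monitor_radius is not None
                               else max(2.0 * spec.radius, 1.5 * spacing))
        self.fade_steps = params.fade_steps
        self.phase = PhaseState(contact_nodes=select_contact_nodes(grid, spec))
        self._monitor = monitored_cells(grid, spec, self.monitor_radius)
        self._tick = 0.0

    @property
    def axis(self) -> np.ndarray:
        return self.spec.axis

    def pending_fade(self, step: float) -> bool:
        """True while any capture offset is still being blended out."""
        ph = self.phase
        if not len(ph.capture_steps) or self.fade_steps <= 0:
            return False
        active = ph.capture_steps + self.fade_steps > step
        if not active.any():
            return False
        return bool(np.abs(ph.capture_offsets[active]).max() > 1e-12)

    def targets(self, depth: float, u: np.ndarray, strain_fn, step=None):
        self._tick = float(step) if step is not None else self._tick + 1.0
        if self.phase.phase == "indentation":
            if depth > 0 and check_puncture(strain_fn(self._monitor),
                                            self.params.eps_p):
                self.phase.to_penetration(depth, axis=self.spec.axis,
                                          step=self._tick)
            else:
                return indentation_update(self.phase, self.spec, depth)
        update_driven_set(self.phase, self.grid, self.spec,
                          self.capture_radius, depth, u=u, step=self._tick)
        return penetration_update(self.phase, self.spec, self.params.cd, depth,
                                  fade_steps=self.fade_steps, step=self._tick)
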