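"""Simple prescribed-motion drivers for verification problems.

These complement :class:`mtled.needle.NeedleDriver`: the solver only sees the
``targets(depth, u, strain_fn)`` protocol, so patch tests and compression
studies reuse the same quasi-static machinery.  For these drivers ``depth``
is simply the load factor carried by the schedule (mm of prescribed travel,
or a dimensionless ramp factor for the affine driver).
"""

from __future__ import annotations

import numpy as np

__all__ = ["AffineBoundaryDriver", "FaceCompressionDriver"]


class AffineBoundaryDriver:
    """Drive a node set through the affine field u = load * A x (+ load * b).

    Used for patch tests: prescribing an affine displacement on the whole
    boundary must reproduce the homogeneous deformation in the interior.
    """

    def __init__(self, node_ids, node_coords, A, b=None, axis=(0.0, 0.0, -1.0)):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.coords = np.asarray(node_coords, dtype=float)[self.node_ids]
        self.A = np.asarray(A, dtype=float)
        self.b = np.zeros(3) if b is None else np.asarray(b, dtype=float)
        self.axis = np.asarray(axis, dtype=float)

    def targets(self, load, u, strain_fn, step=None):
        vals = load * (self.coords @ self.A.T + self.b)
        return self.node_ids, vals


class FaceCompressionDriver:
    """Drive one face rigidly along a direction by ``depth`` mm."""

    def __init__(self, node_ids, direction=(0.0, 0.0, -1.0)):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        d = np.asarray(direction, dtype=float)
        self.axis = d / np.linalg.norm(d)

    def targets(self, depth, u, strain_fn, step=None):
        vals = np.broadcast_to(depth * self.axis, (len(self.node_ids), 3)).copy()
        return self.node_ids, vals
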