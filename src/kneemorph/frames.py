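"""The knee reference coordinate system.

All morphometric measurements are axis projections in a frame anchored on
the femoral posterior condylar line (the line through the most posterior
points of the two femoral condyles, FMCP and FLCP):

* **z (proximodistal)** — the scanner table direction, taken as the mesh
  file's +z (patients are assumed correctly positioned, so only an axial
  rotation remains to be corrected); +z points proximal.
* **x (mediolateral)** — the condylar line projected into the axial plane,
  signed so that FLCP - FMCP defines +x (a right-knee convention; flip with
  ``lateral_positive=False`` for unmirrored left knees).
* **y (anteroposterior)** — ``z cross x``; +y points anterior.

The femur and tibia of one subject share a single frame built from the
femoral FMCP/FLCP.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ReferenceFrame", "FrameError", "build_reference_frame", "to_frame"]

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class FrameError(ValueError):
    """Degenerate frame construction or frame-state contract violation."""


@dataclasses.dataclass
class ReferenceFrame:
    """Right-handed orthonormal frame (origin + x/y/z axes, mm)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.x_axis = np.asarray(self.x_axis, dtype=np.float64)
        self.y_axis = np.asarray(self.y_axis, dtype=np.float64)
        self.z_axis = np.asarray(self.z_axis, dtype=np.float64)
        basis = self.basis
        if np.abs(basis.T @ basis - np.eye(3)).max() > 1e-8:
            raise FrameError("axes must be orthonormal")
        if not np.isclose(np.linalg.det(basis), 1.0, atol=1e-8):
            raise FrameError("axes must form a right-handed system")

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix with the axes as columns."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World -> frame coordinates (a rigid change of basis)."""
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.basis

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.basis.T + self.origin

    @classmethod
    def canonical(cls) -> "ReferenceFrame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


def build_reference_frame(
    fmcp: np.ndarray,
    flcp: np.ndarray,
    table_axis: np.ndarray = (0.0, 0.0, 1.0),
    lateral_positive: bool = True,
) -> ReferenceFrame:
    """Build the measurement frame from the two posterior condyle landmarks.

    ``z`` is the (normalised) table axis; ``x`` is the condylar direction
    FLCP - FMCP projected into the plane perpendicular to ``z`` (so the
    condylar line becomes parallel to the mediolateral axis after an axial
    rotation only); ``y = z cross x``.  Origin is the condylar midpoint.
    """
    fmcp = np.asarray(fmcp, dtype=np.float64)
    flcp = np.asarray(flcp, dtype=np.float64)
    if np.allclose(fmcp, flcp):
        raise FrameError("FMCP and FLCP coincide; cannot define the condylar line")
    z = np.asarray(table_axis, dtype=np.float64)
    z = z / np.linalg.norm(z)
    d = flcp - fmcp if lateral_positive else fmcp - flcp
    d_axial = d - (d @ z) * z
    norm = np.linalg.norm(d_axial)
    if norm < 1e-9:
        raise FrameError("condylar line is parallel to the table axis; frame degenerate")
    x = d_axial / norm
    y = np.cross(z, x)
    return ReferenceFrame(origin=0.5 * (fmcp + flcp), x_axis=x, y_axis=y, z_axis=z)


def to_frame(obj, frame: ReferenceFrame):
    """Express a landmark set or mesh in ``frame`` coordinates.

    Landmark sets carry a RAW/ALIGNED flag; aligning an already-ALIGNED set
    raises to prevent silent double transforms.  Meshes are transformed
    unconditionally (they carry no frame state).
    """
    coords = getattr(obj, "coordinates", None)
    if coords is not None:  # LandmarkSet-like
        if getattr(obj, "frame", "RAW") == "ALIGNED":
            raise FrameError("landmark set is already ALIGNED; refusing to re-align")
        new_coords = {k: frame.to_local(v) for k, v in coords.items()}
        return dataclasses.replace(obj, coordinates=new_coords, frame="ALIGNED")
    # TriangleMesh-like
    out = obj.copy()
    out.vertices = frame.to_local(obj.vertices)
    return out
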