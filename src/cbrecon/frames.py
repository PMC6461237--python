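"""Discrete Frenet frames and peptide-plane (CαO) frames for Cα traces.

A protein's Cα backbone is treated as a piecewise-linear polygon with
vertices at the Cα positions.  Two orthonormal right-handed framings are
built on it:

* the *discrete Frenet frame* ``(n, b, t)`` at each interior Cα, defined
  purely from three consecutive Cα positions — tangent ``t`` toward the
  next Cα, binormal ``b`` normal to the local plane, normal ``n = b × t``;
* the *CαO frame* ``(û, v̂, ŵ)`` centered at the carbonyl O of the virtual
  peptide plane spanned by Cα(i), Cα(i+1) and O(i).

From the Frenet frames the virtual backbone bond angle ``κ`` (between
consecutive tangents) and torsion angle ``τ`` (signed angle between
consecutive binormals) are derived, together with the stereographic map
``x + iy = tan(κ/2) e^{iτ}`` used to chart the backbone on a disk.

All per-residue arrays are 0-based and aligned with
``ChainTrace.residues``; validity masks mark where a quantity is defined
(chain interiors away from breaks and collinear degeneracies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structio import ChainTrace

logger = logging.getLogger(__name__)

#: vectors whose pre-normalization cross product is shorter than this are
#: treated as collinear and the frame is marked invalid (never a silent NaN)
COLLINEARITY_TOL = 1e-8

FRENET = "frenet"
CAO = "cao"


@dataclass(frozen=True)
class Frame:
    """A single orthonormal right-handed frame: origin plus axis rows."""

    origin: np.ndarray  # (3,)
    axes: np.ndarray    # (3, 3); rows are axis1, axis2, axis3

    def to_frame_coords(self, point: np.ndarray) -> np.ndarray:
        return self.axes @ (np.asarray(point, dtype=float) - self.origin)

    def to_world(self, local: np.ndarray) -> np.ndarray:
        return self.origin + self.axes.T @ np.asarray(local, dtype=float)


@dataclass
class FrameSet:
    """Per-residue frames with a validity mask.

    ``axes[i]`` holds rows ``(n, b, t)`` for Frenet frames or
    ``(û, v̂, ŵ)`` for CαO frames.  For Frenet framings the raw tangent
    vectors are kept as well, because the first tangent of a segment
    exists before the first full frame does.
    """

    origin: np.ndarray          # (N, 3)
    axes: np.ndarray            # (N, 3, 3)
    valid: np.ndarray           # (N,) bool
    kind: str
    tangents: Optional[np.ndarray] = None        # (N, 3), Frenet only
    tangent_valid: Optional[np.ndarray] = None   # (N,) bool

    def __len__(self) -> int:
        return len(self.valid)

    def frame(self, i: int) -> Frame:
        if not self.valid[i]:
            raise ValueError(f"no valid {self.kind} frame at residue index {i}")
        return Frame(origin=self.origin[i], axes=self.axes[i])


@dataclass
class BackboneAngles:
    """Virtual bond (κ ∈ [0, π]) and torsion (τ ∈ [−π, π)) angles.

    ``kappa[i]`` is the angle between tangents ``t_i`` and ``t_{i+1}``;
    ``tau[i]`` is the signed angle between binormals ``b_i`` and
    ``b_{i+1}``.  Separate masks mark where each is defined.
    """

    kappa: np.ndarray
    tau: np.ndarray
    kappa_valid: np.ndarray
    tau_valid: np.ndarray

    def __len__(self) -> int:
        return len(self.kappa)

    @property
    def valid(self) -> np.ndarray:
        """Residues where both κ and τ are defined."""
        return self.kappa_valid & self.tau_valid


@dataclass(frozen=True)
class SphericalDirection:
    """Direction on a frame-centered sphere.

    latitude
        measured from the frame's third axis (the north pole, κ = 0
        direction), in [0, π];
    longitude
        measured counterclockwise about the third axis, zero on the
        first-axis meridian, in [−π, π); fixed to 0 at the poles;
    radius
        optional distance in Å.
    """

    latitude: float
    longitude: float
    radius: Optional[float] = None

    def unit_vector(self) -> np.ndarray:
        """Direction in frame coordinates (axis1, axis2, axis3 components)."""
        sl = np.sin(self.latitude)
        return np.array([
            sl * np.cos(self.longitude),
            sl * np.sin(self.longitude),
            np.cos(self.latitude),
        ])


def _canonical_angle(a):
    """Map angle(s) to [−π, π)."""
    return np.mod(np.asarray(a, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def frenet_frames(trace: ChainTrace) -> FrameSet:
    """Discrete Frenet frames ``(n_i, b_i, t_i)`` at every interior Cα.

    ``t_i`` points from Cα(i) to Cα(i+1); ``b_i`` is the unit cross
    product of the incoming and outgoing tangents; ``n_i = b_i × t_i``.
    A frame is valid only where both adjacent tangents lie inside one
    unbroken segment and are not collinear.
    """
    n = len(trace)
    ca = trace.ca_array()
    tangents = np.full((n, 3), np.nan)
    t_valid = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if i in trace.break_after:
            continue
        d = ca[i + 1] - ca[i]
        norm = np.linalg.norm(d)
        if norm < COLLINEARITY_TOL:
            logger.warning("zero-length virtual bond at residue %d", i)
            continue
        tangents[i] = d / norm
        t_valid[i] = True

    axes = np.full((n, 3, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if not (t_valid[i - 1] and i < n - 1 and t_valid[i]):
            continue
        c = np.cross(tangents[i - 1], tangents[i])
        cn = np.linalg.norm(c)
        if cn < COLLINEARITY_TOL:
            logger.info("collinear tangents at residue %d; frame invalid", i)
            continue
        b = c / cn
        t = tangents[i]
        axes[i] = np.stack([np.cross(b, t), b, t])
        valid[i] = True

    return FrameSet(origin=ca.copy(), axes=axes, valid=valid, kind=FRENET,
                    tangents=tangents, tangent_valid=t_valid)


def backbone_angles(frames: FrameSet) -> BackboneAngles:
    """Backbone bond/torsion angles from a Frenet ``FrameSet``.

    κ_i = arccos(t_{i+1} · t_i), clamped; τ_i = sign(b_{i+1} · n_i) ·
    arccos(b_{i+1} · b_i), with sign(0) taken as +1 and τ canonicalized
    to [−π, π).
    """
    if frames.kind != FRENET:
        raise ValueError("backbone angles require Frenet frames")
    n = len(frames)
    t, tv = frames.tangents, frames.tangent_valid
    kappa = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    kv = np.zeros(n, dtype=bool)
    tauv = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if tv[i] and tv[i + 1]:
            kappa[i] = np.arccos(np.clip(np.dot(t[i], t[i + 1]), -1.0, 1.0))
            kv[i] = True
    for i in range(n - 1):
        if frames.valid[i] and frames.valid[i + 1]:
            b_i, b_ip1 = frames.axes[i, 1], frames.axes[i + 1, 1]
            n_i = frames.axes[i, 0]
            mag = np.arccos(np.clip(np.dot(b_i, b_ip1), -1.0, 1.0))
            sgn = -1.0 if np.dot(b_ip1, n_i) < 0.0 else 1.0
            tau[i] = float(_canonical_angle(sgn * mag))
            tauv[i] = True
    return BackboneAngles(kappa=kappa, tau=tau, kappa_valid=kv, tau_valid=tauv)


def cao_frames(trace: ChainTrace) -> FrameSet:
    """O-centered peptide-plane frames ``(û_i, v̂_i, ŵ_i)``.

    û_i runs along the Cα(i)→Cα(i+1) virtual bond, ŵ_i is the unit
    normal of the plane through Cα(i), Cα(i+1) and O(i), and
    v̂_i = ŵ_i × û_i completes the right-handed triplet.  The origin is
    the O(i) atom.  Invalid where O is missing, the pair straddles a
    chain break, or O lies on the Cα–Cα axis.
    """
    n = len(trace)
    ca = trace.ca_array()
    origin = np.full((n, 3), np.nan)
    axes = np.full((n, 3, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        o = trace.residues[i].o
        if o is None or i in trace.break_after:
            continue
        d = ca[i + 1] - ca[i]
        dn = np.linalg.norm(d)
        oo = np.asarray(o, dtype=float) - ca[i]
        on = np.linalg.norm(oo)
        if dn < COLLINEARITY_TOL or on < COLLINEARITY_TOL:
            continue
        u = d / dn
        w = np.cross(u, oo / on)
        wn = np.linalg.norm(w)
        if wn < COLLINEARITY_TOL:
            logger.info("O collinear with Ca-Ca axis at residue %d", i)
            continue
        w = w / wn
        axes[i] = np.stack([u, np.cross(w, u), w])
        origin[i] = o
        valid[i] = True
    return FrameSet(origin=origin, axes=axes, valid=valid, kind=CAO)


def frame_coordinates(frame: Frame, point: np.ndarray) -> SphericalDirection:
    """Spherical coordinates of ``point`` as seen by an observer in ``frame``.

    Latitude is measured from the third axis, longitude counterclockwise
    about it from the first-axis meridian; longitude is 0 at the poles.
    """
    local = frame.to_frame_coords(point)
    r = float(np.linalg.norm(local))
    if r < 1e-12:
        raise ValueError("point coincides with the frame origin")
    u = local / r
    lat = float(np.arccos(np.clip(u[2], -1.0, 1.0)))
    if np.hypot(u[0], u[1]) < 1e-12:
        lon = 0.0
    else:
        lon = float(_canonical_angle(np.arctan2(u[1], u[0])))
    return SphericalDirection(latitude=lat, longitude=lon, radius=r)


def place_point(frame: Frame, direction: SphericalDirection,
                radius: Optional[float] = None) -> np.ndarray:
    """Inverse of :func:`frame_coordinates`: world position of a direction."""
    r = radius if radius is not None else direction.radius
    if r is None or r <= 0:
        raise ValueError("a positive radius is required")
    return frame.to_world(r * direction.unit_vector())


def stereographic_project(kappa, tau=None) -> np.ndarray:
    """Stereographic map x + iy = tan(κ/2) e^{iτ} from the south pole.

    Accepts either a :class:`BackboneAngles` (projecting the jointly
    valid residues) or paired κ/τ arrays.  Returns an (M, 2) array of
    planar points.  κ = π (the projection pole) is an error.
    """
    if isinstance(kappa, BackboneAngles):
        if tau is not None:
            raise TypeError("pass either BackboneAngles or two arrays")
        m = kappa.valid
        k, t = kappa.kappa[m], kappa.tau[m]
    else:
        k = np.atleast_1d(np.asarray(kappa, dtype=float))
        t = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(k >= np.pi) or np.any(k < 0):
        raise ValueError("kappa must lie in [0, pi); the south pole maps to infinity")
    rho = np.tan(k / 2.0)
    return np.column_stack([rho * np.cos(t), rho * np.sin(t)])


def export_angles(angles: BackboneAngles, path) -> None:
    """Write backbone angles as TSV: residue index, κ, τ, validity flags."""
    with open(path, "w") as fh:
        fh.write("residue_index\tkappa\ttau\tkappa_valid\ttau_valid\n")
        for i in range(len(angles)):
            k = repr(float(angles.kappa[i])) if angles.kappa_valid[i] else "."
            t = repr(float(angles.tau[i])) if angles.tau_valid[i] else "."
            fh.write(f"{i}\t{k}\t{t}\t{int(angles.kappa_valid[i])}"
                     f"\t{int(angles.tau_valid[i])}\n")


def stereographic_unproject(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse stereographic map; exact on the open disk of definition."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rho = np.hypot(pts[:, 0], pts[:, 1])
    kappa = 2.0 * np.arctan(rho)
    tau = np.where(rho > 0, np.arctan2(pts[:, 1], pts[:, 0]), 0.0)
    return kappa, _canonical_angle(tau)
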