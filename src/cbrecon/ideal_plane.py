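"""Ideal peptide-plane completion: place C(i), N(i+1), H(i+1) from Cα/O.

The peptide unit Cα(i)–C(i)–O(i)–N(i+1)–H(i+1)–Cα(i+1) is treated as a
rigid planar group.  Once the O-centered CαO frame of residue i is known,
the missing heavy atoms (and the amide H) are dropped in at fixed
in-plane offsets derived from a named set of ideal bond lengths and
angles.  The default parameter set uses standard published ideal
peptide-plane values (Engh–Huber-type restraint targets).

Geometry is configuration, not code: parameter sets are plain key=value
files (see :meth:`IdealPlaneGeometry.from_file`) and every derived
in-plane coordinate is recomputed from them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict, replace
from functools import cached_property
from pathlib import Path
from typing import Optional

import numpy as np

from .structio import ChainTrace
from .frames import FrameSet, cao_frames, CAO

logger = logging.getLogger(__name__)


def _rot2(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


@dataclass(frozen=True)
class IdealPlaneGeometry:
    """Ideal trans-peptide-plane dimensions (Å, degrees).

    The 2D in-plane coordinates of C, N, H relative to the O-centered
    CαO frame are derived once from these values.  The sanity windows
    C–O ∈ [1.15, 1.35] Å and C–N ∈ [1.25, 1.45] Å are enforced.
    """

    name: str = "engh-huber-1991"
    ca_c: float = 1.525      # Cα(i)–C(i)
    c_o: float = 1.231       # C(i)=O(i)
    c_n: float = 1.329       # C(i)–N(i+1) peptide bond
    n_ca: float = 1.458      # N(i+1)–Cα(i+1)
    n_h: float = 1.00        # N(i+1)–H(i+1)
    ang_ca_c_n: float = 116.2
    ang_ca_c_o: float = 120.8
    ang_c_n_ca: float = 121.7
    ang_c_n_h: float = 119.2

    def __post_init__(self):
        if not (1.15 <= self.c_o <= 1.35):
            raise ValueError(f"C-O distance {self.c_o} outside sanity window [1.15, 1.35]")
        if not (1.25 <= self.c_n <= 1.45):
            raise ValueError(f"C-N distance {self.c_n} outside sanity window [1.25, 1.45]")

    @cached_property
    def plane_coordinates(self) -> dict[str, np.ndarray]:
        """In-plane (û, v̂) offsets of C, N, H from O, plus the reference
        Cα positions used in the derivation.

        The trans unit is laid out flat: Cα(i) at the 2D origin with C(i)
        along +x, N on the opposite side of the Cα–C axis from O, Cα(i+1)
        trans to Cα(i) across the peptide bond, H trans to O.  The CαO
        frame of that layout then converts atom positions into (û, v̂)
        offsets from O.
        """
        d = math.radians
        ca1 = np.zeros(2)
        c = np.array([self.ca_c, 0.0])
        back = np.array([-1.0, 0.0])                       # C → Cα(i)
        n = c + self.c_n * _rot2(back, -d(self.ang_ca_c_n))   # N above the axis
        o = c + self.c_o * _rot2(back, d(self.ang_ca_c_o))    # O below the axis
        n_to_c = (c - n) / np.linalg.norm(c - n)
        cands = [n + self.n_ca * _rot2(n_to_c, s * d(self.ang_c_n_ca))
                 for s in (+1.0, -1.0)]
        # trans omega: Cα(i+1) on the far side of the C–N bond from Cα(i)
        ca2 = max(cands, key=lambda p: np.linalg.norm(p - ca1))
        axis = n - c

        def side(p):
            rel = p - c
            return axis[0] * rel[1] - axis[1] * rel[0]

        h_cands = [n + self.n_h * _rot2(n_to_c, s * d(self.ang_c_n_h))
                   for s in (+1.0, -1.0)]
        # amide H trans to the carbonyl O across the C–N axis
        h = next(p for p in h_cands if side(p) * side(o) < 0)

        u = (ca2 - ca1) / np.linalg.norm(ca2 - ca1)
        oca = (o - ca1) / np.linalg.norm(o - ca1)
        wz = u[0] * oca[1] - u[1] * oca[0]          # z of û × (O−Cα)/|·|
        v = np.array([-u[1], u[0]]) * math.copysign(1.0, wz)
        out = {}
        for label, p in (("C", c), ("N", n), ("H", h),
                         ("CA1", ca1), ("CA2", ca2)):
            rel = p - o
            out[label] = np.array([float(rel @ u), float(rel @ v)])
        return out

    @property
    def ca_ca_distance(self) -> float:
        pc = self.plane_coordinates
        return float(np.linalg.norm(pc["CA2"] - pc["CA1"]))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# cbrecon ideal peptide plane parameter set\n")
            fh.write("# lengths in Angstrom, angles in degrees\n")
            for key, val in asdict(self).items():
                fh.write(f"{key} = {val}\n")

    @classmethod
    def from_file(cls, path) -> "IdealPlaneGeometry":
        """Load a parameter set from a `key = value` file; unknown keys error."""
        fields = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            fields[key] = val.strip() if key == "name" else float(val)
        return cls(**fields)


DEFAULT_GEOMETRY = IdealPlaneGeometry()


def place_plane_atoms(trace: ChainTrace,
                      geometry: IdealPlaneGeometry = DEFAULT_GEOMETRY,
                      frames: Optional[FrameSet] = None,
                      ) -> dict[int, dict[str, np.ndarray]]:
    """Place C(i), N(i+1), H(i+1) in each valid peptide plane of a trace.

    Returns a map residue position → {"C", "N", "H"} world coordinates;
    the N/H entries belong to residue i+1.  Each placed atom is
    frame_origin + a·û + b·v̂, hence exactly in the plane spanned by û, v̂
    through O.  Residues without a valid CαO frame are skipped with a log
    entry; cis-like residues keep the trans layout with a warning.
    """
    if frames is None:
        frames = cao_frames(trace)
    if frames.kind != CAO:
        raise ValueError("plane placement requires CaO frames")
    coords = geometry.plane_coordinates
    placed: dict[int, dict[str, np.ndarray]] = {}
    for i in range(len(trace)):
        if not frames.valid[i]:
            if i < len(trace) - 1 and i not in trace.break_after:
                logger.info("no valid CaO frame at residue %d; plane skipped", i)
            continue
        if i in trace.cis_like:
            logger.warning("cis-like peptide at residue %d: trans plane geometry used", i)
        origin = frames.origin[i]
        u, v = frames.axes[i, 0], frames.axes[i, 1]
        placed[i] = {label: origin + coords[label][0] * u + coords[label][1] * v
                     for label in ("C", "N", "H")}
    return placed
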