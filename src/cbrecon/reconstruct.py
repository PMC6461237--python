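"""Statistical-method driver: predict and place Cβ atoms along a trace.

For each eligible residue the backbone state (κ_i, κ_{i+1}, τ_i) and the
carbonyl-O longitude ψ_i select a library bin; the library returns a
predicted Cβ direction (θ, ϕ) on the Frenet sphere, and the atom is
placed at the fixed Cα–Cβ covalent radius (default 1.55 Å) along that
direction.  Optionally the ideal peptide plane is completed with C, N
and H atoms.  Batch reconstruction never throws on a bad residue: each
one carries exactly one provenance label, either a library match kind or
a skip reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .structio import ChainTrace
from .frames import (BackboneAngles, Frame, FrameSet, SphericalDirection,
                     backbone_angles, cao_frames, frame_coordinates,
                     frenet_frames, place_point)
from .ideal_plane import DEFAULT_GEOMETRY, IdealPlaneGeometry, place_plane_atoms
from .statlib import (BinKey, LibraryConfig, Provenance, StatLibrary,
                      bin_assign, query)

logger = logging.getLogger(__name__)

GLY_MODES = ("skip", "virtual")


@dataclass(frozen=True)
class ReconstructOptions:
    """Knobs for :func:`reconstruct_chain`.

    ``cb_radius``: Cα–Cβ bond length in Å (None → library config value);
    ``gly_mode``: 'skip' glycines (no Cβ) or place a 'virtual' pseudo-Cβ;
    ``complete_planes``: also place ideal-plane C/N/H atoms.
    """

    cb_radius: Optional[float] = None
    gly_mode: str = "skip"
    complete_planes: bool = False
    geometry: IdealPlaneGeometry = DEFAULT_GEOMETRY

    def __post_init__(self):
        if self.gly_mode not in GLY_MODES:
            raise ValueError(f"gly_mode must be one of {GLY_MODES}")


@dataclass
class ResidueRecord:
    """Outcome for one residue: a predicted Cβ or a skip reason."""

    index: int                      # 0-based position along the trace
    seq_index: int                  # 1-based label
    res_name: str
    cb: Optional[np.ndarray] = None
    direction: Optional[SphericalDirection] = None
    bin_key: Optional[BinKey] = None
    provenance: Union[Provenance, str] = "skipped:unprocessed"

    @property
    def predicted(self) -> bool:
        return self.cb is not None

    @property
    def provenance_kind(self) -> str:
        return (self.provenance.kind if isinstance(self.provenance, Provenance)
                else self.provenance)

    plane_atoms: Optional[dict] = None


@dataclass
class ReconstructionResult:
    """Per-residue predictions with provenance and the effective config."""

    records: list[ResidueRecord]
    config: dict

    def __len__(self) -> int:
        return len(self.records)

    @property
    def predicted_records(self) -> list[ResidueRecord]:
        return [r for r in self.records if r.predicted]

    def provenance_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.provenance_kind] = out.get(r.provenance_kind, 0) + 1
        return out

    def cb_array(self) -> np.ndarray:
        """(N, 3) predicted Cβ coordinates, NaN where not predicted."""
        arr = np.full((len(self.records), 3), np.nan)
        for r in self.records:
            if r.cb is not None:
                arr[r.index] = r.cb
        return arr


def predict_direction(trace: ChainTrace, lib: StatLibrary, i: int,
                      frames: Optional[FrameSet] = None,
                      angles: Optional[BackboneAngles] = None,
                      gly_mode: str = "skip",
                      ) -> tuple[Optional[SphericalDirection],
                                 Union[Provenance, str],
                                 Optional[BinKey]]:
    """Predict the Cβ direction of residue ``i`` (0-based) from the library.

    Returns (direction, provenance, bin_key); on a missing prerequisite the
    direction is None and the provenance is a ``skipped:<reason>`` string.
    """
    if frames is None:
        frames = frenet_frames(trace)
    if angles is None:
        angles = backbone_angles(frames)
    res = trace.residues[i]
    if res.res_name == "GLY" and gly_mode == "skip":
        return None, "skipped:glycine", None
    if not frames.valid[i]:
        return None, "skipped:no-frame", None
    if not (angles.kappa_valid[i] and i + 1 < len(trace)
            and angles.kappa_valid[i + 1] and angles.tau_valid[i]):
        return None, "skipped:no-angles", None
    if res.o is None:
        return None, "skipped:no-O", None
    fr = frames.frame(i)
    psi = frame_coordinates(fr, res.o).longitude
    key = bin_assign(angles.kappa[i], angles.kappa[i + 1], angles.tau[i],
                     psi, lib.config)
    direction, prov = query(lib, key, (res.res_name, trace.residues[i + 1].res_name))
    return direction, prov, key


def place_cbeta(frame: Frame, direction: SphericalDirection,
                radius: float = 1.55) -> np.ndarray:
    """World position of a Cβ at ``radius`` Å along ``direction`` in a
    Frenet frame: origin + r·(sinθ cosϕ·n + sinθ sinϕ·b + cosθ·t)."""
    if radius <= 0:
        raise ValueError("cb radius must be positive")
    return place_point(frame, direction, radius)


def reconstruct_chain(trace: ChainTrace, lib: StatLibrary,
                      options: ReconstructOptions = ReconstructOptions(),
                      ) -> ReconstructionResult:
    """Reconstruct every eligible Cβ of a trace from the library.

    Deterministic: identical inputs give identical records.  Terminal
    residues and residues adjacent to breaks are skipped (their frames or
    angles are undefined); glycines follow ``options.gly_mode``.
    """
    if not lib.bins:
        raise ValueError("statistical library is empty")
    radius = options.cb_radius if options.cb_radius is not None else lib.config.cb_radius
    frames = frenet_frames(trace)
    angles = backbone_angles(frames)
    records: list[ResidueRecord] = []
    for i, res in enumerate(trace.residues):
        rec = ResidueRecord(index=i, seq_index=res.seq_index, res_name=res.res_name)
        direction, prov, key = predict_direction(
            trace, lib, i, frames=frames, angles=angles, gly_mode=options.gly_mode)
        rec.provenance = prov
        rec.bin_key = key
        if direction is not None:
            rec.direction = direction
            rec.cb = place_cbeta(frames.frame(i), direction, radius)
        records.append(rec)

    if options.complete_planes:
        placed = place_plane_atoms(trace, geometry=options.geometry)
        for rec in records:
            if rec.index in placed:
                rec.plane_atoms = placed[rec.index]

    config = {
        "cb_radius": radius,
        "gly_mode": options.gly_mode,
        "complete_planes": options.complete_planes,
        "kappa_threshold": lib.config.kappa_threshold,
        "n_tau_sectors": lib.config.n_tau_sectors,
        "n_psi_segments": lib.config.n_psi_segments,
    }
    return ReconstructionResult(records=records, config=config)


def reconstruction_report(trace: ChainTrace, result: ReconstructionResult,
                          path_or_file, header: bool = True) -> None:
    """Write a per-residue TSV report: bin key, provenance, predicted
    (θ, ϕ) and — when the trace carries reference Cβ atoms — the angular
    deviation (radians) between true and predicted Cα→Cβ directions."""
    from .evaluate import angular_deviation  # local import to avoid a cycle
    own = not hasattr(path_or_file, "write")
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        if header:
            fh.write("seq_index\tres_name\tdkappa_set\ttau_sector\tpsi_segment\t"
                     "provenance\ttheta\tphi\tdeviation_rad\n")
        for rec in result.records:
            key = rec.bin_key
            kcols = (f"{key.dkappa_set}\t{key.tau_sector}\t{key.psi_segment}"
                     if key else ".\t.\t.")
            if rec.direction is not None:
                tp = f"{rec.direction.latitude:.6f}\t{rec.direction.longitude:.6f}"
            else:
                tp = ".\t."
            ref = trace.residues[rec.index]
            if rec.cb is not None and ref.cb is not None:
                dev = f"{angular_deviation(ref.cb - ref.ca, rec.cb - ref.ca):.6f}"
            else:
                dev = "."
            fh.write(f"{rec.seq_index}\t{rec.res_name}\t{kcols}\t"
                     f"{rec.provenance_kind}\t{tp}\t{dev}\n")
    finally:
        if own:
            fh.close()
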