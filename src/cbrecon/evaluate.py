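"""Assessment machinery for reconstructions.

Covers the quantities used to judge a Cβ reconstruction against a
reference trace: angular-deviation distributions of the Cα→Cβ and O→Cβ
vectors, the ∠Cβ(i)O(i)Cβ(i+1) angle probing the whole Cα–Cβ–peptide
plane complex, direction density maps on frame-centered spheres, and
back-mapping of sphere regions to the (κ, τ) chart for stereographic
plotting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .structio import ChainTrace
from .frames import (SphericalDirection, backbone_angles, cao_frames,
                     frame_coordinates, frenet_frames)
from .reconstruct import ReconstructionResult

VECTOR_KINDS = ("ca-cb", "o-cb")


def angular_deviation(v_ref: np.ndarray, v_pred: np.ndarray) -> float:
    """Angle in [0, π] between two (nonzero) vectors."""
    a = np.asarray(v_ref, dtype=float)
    b = np.asarray(v_pred, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angular deviation of a zero vector is undefined")
    # atan2 form: exact at 0 and pi, well-conditioned everywhere
    return float(np.arctan2(np.linalg.norm(np.cross(a, b)), np.dot(a, b)))


@dataclass
class DeviationSummary:
    """Per-residue angular deviations with histogram summary statistics.

    ``peak_location`` is the center of the maximal histogram bin
    (ties broken toward the smaller deviation).
    """

    deviations: np.ndarray
    indices: np.ndarray
    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_location: float
    median: float
    mean: float

    def to_dict(self) -> dict:
        return {"n": int(len(self.deviations)),
                "peak_rad": self.peak_location,
                "median_rad": self.median,
                "mean_rad": self.mean}


def _summarize(devs: np.ndarray, indices: np.ndarray,
               bin_width: float) -> DeviationSummary:
    top = max(float(devs.max()), bin_width)
    n_bins = int(math.ceil(top / bin_width - 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(devs, bins=edges)
    peak_bin = int(np.argmax(counts))  # argmax ties -> first -> smaller deviation
    return DeviationSummary(
        deviations=devs, indices=indices, bin_width=bin_width,
        bin_edges=edges, counts=counts,
        peak_location=float((peak_bin + 0.5) * bin_width),
        median=float(np.median(devs)), mean=float(np.mean(devs)))


def deviation_distribution(ref: ChainTrace, recon: ReconstructionResult,
                           vector_kind: str = "ca-cb",
                           bin_width: float = 0.01) -> DeviationSummary:
    """Distribution of angles between reference and predicted Cβ vectors.

    ``ca-cb`` compares the Cα(i)→Cβ(i) directions; ``o-cb`` the
    O(i)→Cβ(i) directions.  Requires at least one residue with both a
    reference Cβ and a prediction.
    """
    if vector_kind not in VECTOR_KINDS:
        raise ValueError(f"vector_kind must be one of {VECTOR_KINDS}")
    devs, idx = [], []
    for rec in recon.records:
        if rec.cb is None:
            continue
        res = ref.residues[rec.index]
        if res.cb is None:
            continue
        origin = res.ca if vector_kind == "ca-cb" else res.o
        if origin is None:
            continue
        devs.append(angular_deviation(res.cb - origin, rec.cb - origin))
        idx.append(rec.index)
    if not devs:
        raise ValueError("no residues with both reference and predicted Cbeta")
    return _summarize(np.asarray(devs), np.asarray(idx), bin_width)


def cbeta_o_cbeta_angle(trace: ChainTrace, i: int,
                        recon: Optional[ReconstructionResult] = None) -> float:
    """Angle at O(i) between the O→Cβ(i) and O→Cβ(i+1) directions.

    Cβ positions come from ``recon`` when given, else from the trace.
    Probes the fidelity of the whole Cα–Cβ–peptide-plane complex.
    """
    o = trace.residues[i].o
    if o is None:
        raise ValueError(f"missing O atom at residue {i}")
    if recon is not None:
        cb = recon.cb_array()
        cb_i = cb[i] if np.all(np.isfinite(cb[i])) else None
        cb_ip1 = cb[i + 1] if i + 1 < len(cb) and np.all(np.isfinite(cb[i + 1])) else None
    else:
        cb_i = trace.residues[i].cb
        cb_ip1 = trace.residues[i + 1].cb if i + 1 < len(trace) else None
    if cb_i is None or cb_ip1 is None:
        raise ValueError(f"missing Cbeta at residue {i} or {i + 1}")
    return angular_deviation(cb_i - o, cb_ip1 - o)


@dataclass
class SphereHistogram:
    """Equal-angle (latitude × longitude) direction histogram on a sphere."""

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    counts: np.ndarray  # (n_lat, n_lon) ints

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def cell_solid_angles(self) -> np.ndarray:
        """Solid angle of each cell, steradians (sums to 4π)."""
        dcos = -np.diff(np.cos(self.lat_edges))
        dlon = np.diff(self.lon_edges)
        return np.outer(dcos, dlon)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")


def sphere_density(directions: Iterable[SphericalDirection],
                   n_lat: int = 18, n_lon: int = 36) -> SphereHistogram:
    """Bin directions into an equal-angle grid; counts conserve input size."""
    dirs = list(directions)
    if not dirs:
        raise ValueError("no directions to bin")
    lat = np.array([d.latitude for d in dirs])
    lon = np.array([d.longitude for d in dirs])
    lat_edges = np.linspace(0.0, np.pi, n_lat + 1)
    lon_edges = np.linspace(-np.pi, np.pi, n_lon + 1)
    li = np.minimum((lat / (np.pi / n_lat)).astype(int), n_lat - 1)
    lj = np.minimum(((lon + np.pi) / (2 * np.pi / n_lon)).astype(int), n_lon - 1)
    counts = np.zeros((n_lat, n_lon), dtype=int)
    np.add.at(counts, (li, lj), 1)
    return SphereHistogram(lat_edges=lat_edges, lon_edges=lon_edges, counts=counts)


@dataclass(frozen=True)
class SphereRegion:
    """Latitude/longitude rectangle; a lon_min > lon_max range wraps."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, d: SphericalDirection) -> bool:
        if not (self.lat_min <= d.latitude <= self.lat_max):
            return False
        if self.lon_min <= self.lon_max:
            return self.lon_min <= d.longitude <= self.lon_max
        return d.longitude >= self.lon_min or d.longitude <= self.lon_max


BACKMAP_TARGETS = ("cb-in-frenet", "cb-next-in-cao")


def region_backmap(traces: Sequence[ChainTrace], region: SphereRegion,
                   target: str = "cb-next-in-cao") -> list[tuple[float, float]]:
    """Backbone (κ_i, τ_i) of residues whose chosen Cβ direction falls in a
    sphere region.

    ``cb-in-frenet``: Cβ(i) seen from the Frenet frame at i;
    ``cb-next-in-cao``: Cβ(i+1) seen from the O(i)-centered CαO frame —
    the view in which isolated off-distribution islands show up.  The
    returned points are ready for stereographic plotting.
    """
    if target not in BACKMAP_TARGETS:
        raise ValueError(f"target must be one of {BACKMAP_TARGETS}")
    points: list[tuple[float, float]] = []
    for trace in traces:
        fren = frenet_frames(trace)
        ang = backbone_angles(fren)
        cao = cao_frames(trace) if target == "cb-next-in-cao" else None
        for i in range(len(trace)):
            if not (ang.kappa_valid[i] and ang.tau_valid[i]):
                continue
            if target == "cb-in-frenet":
                if not fren.valid[i] or trace.residues[i].cb is None:
                    continue
                d = frame_coordinates(fren.frame(i), trace.residues[i].cb)
            else:
                if (not cao.valid[i] or i + 1 >= len(trace)
                        or trace.residues[i + 1].cb is None):
                    continue
                d = frame_coordinates(cao.frame(i), trace.residues[i + 1].cb)
            if region.contains(d):
                points.append((float(ang.kappa[i]), float(ang.tau[i])))
    return points


def evaluation_report(ref_traces: Sequence[ChainTrace],
                      recons: Sequence[ReconstructionResult],
                      json_path=None, tsv_path=None,
                      bin_width: float = 0.01) -> dict:
    """Pool deviations over several (trace, reconstruction) pairs and
    summarize per vector kind; optionally write JSON/TSV artifacts."""
    summary: dict = {}
    rows: list[tuple] = []
    for kind in VECTOR_KINDS:
        devs, idx = [], []
        for trace, recon in zip(ref_traces, recons):
            try:
                s = deviation_distribution(trace, recon, vector_kind=kind,
                                           bin_width=bin_width)
            except ValueError:
                continue
            devs.append(s.deviations)
            idx.append(s.indices)
            if kind == "ca-cb":
                rows.extend((trace.model_id, trace.chain_id, int(i), float(d))
                            for i, d in zip(s.indices, s.deviations))
        if not devs:
            continue
        pooled = _summarize(np.concatenate(devs), np.concatenate(idx), bin_width)
        summary[kind] = pooled.to_dict()
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("model\tchain\tresidue_index\tcacb_deviation_rad\n")
            for row in rows:
                fh.write(f"{row[0]}\t{row[1]}\t{row[2]}\t{row[3]:.6f}\n")
    return summary
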