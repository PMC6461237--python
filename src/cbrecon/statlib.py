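"""Binned circular-statistics library of Cβ directions.

The reconstruction method partitions reference observations by backbone
state: the torsion angle τ_i selects one of 60 equal sectors (Δτ = π/30),
the bond-angle pair (κ_i, κ_{i+1}) selects one of four sets split at the
helix/strand boundary κ = 1.2 rad, and the carbonyl-O longitude ψ_i (on
the Frenet sphere, where the O atoms form a narrow strip at latitude
≈ π/4) selects one of 90 equal segments (Δψ = π/45).  Within each
(Δκ, Δτ, Δψ) bin, Cβ directions (θ, ϕ) are tabulated per consecutive
residue-name pair (res_i, res_{i+1}): latitude θ is averaged linearly,
longitude ϕ circularly (resultant-vector mean).

Queries reproduce the reference selection cascade: a unique pair match
is used verbatim, multiple matches are averaged, a missing pair falls
back to the whole-bin aggregate, and an empty bin falls back to a
deterministic clockwise neighbor search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .structio import ChainTrace
from .frames import (BackboneAngles, FrameSet, SphericalDirection,
                     backbone_angles, frenet_frames, frame_coordinates,
                     _canonical_angle)

logger = logging.getLogger(__name__)

FORMAT_VERSION = "cbrecon-statlib v1"


class UndefinedMeanError(ValueError):
    """Raised when a circular mean is requested for an antipodally
    balanced angle set (resultant length ~ 0)."""


class BinKey(NamedTuple):
    """Library bin: Δκ set (1–4), τ sector (0–59), ψ segment (0–89)."""

    dkappa_set: int
    tau_sector: int
    psi_segment: int


@dataclass(frozen=True)
class LibraryConfig:
    """Partition parameters. Defaults follow the reference method:
    κ boundary 1.2 rad, 60 τ sectors, 90 ψ segments, Cα–Cβ radius 1.55 Å."""

    kappa_threshold: float = 1.2
    n_tau_sectors: int = 60
    n_psi_segments: int = 90
    cb_radius: float = 1.55


@dataclass(frozen=True)
class PairStats:
    """Circular statistics of Cβ directions for one (bin, residue-pair) cell.

    ``mean_latitude`` is the linear mean of θ; ``mean_longitude`` the
    circular mean of ϕ with resultant length ``resultant_R`` ∈ (0, 1].
    A single observation has R = 1 and means equal to itself.
    """

    count: int
    mean_latitude: float
    mean_longitude: float
    resultant_R: float


@dataclass(frozen=True)
class Provenance:
    """How a query was answered: 'exact-single', 'exact-averaged',
    'bin-average' or 'neighbor-fallback' (with the substituted key)."""

    kind: str
    requested_key: BinKey
    used_key: BinKey


def circular_mean(angles: Iterable[float]) -> tuple[float, float]:
    """Resultant-vector mean of angles (radians) and its length R.

    X = mean(cos), Y = mean(sin), R = sqrt(X² + Y²); the mean is
    atan2(Y, X) canonicalized to [−π, π).  Antipodally balanced sets
    (R < 1e-9) have no defined mean and raise :class:`UndefinedMeanError`.
    """
    arr = np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("circular mean of an empty set")
    x = float(np.mean(np.cos(arr)))
    y = float(np.mean(np.sin(arr)))
    r = math.hypot(x, y)
    if r < 1e-9:
        raise UndefinedMeanError(f"resultant length {r:.2e}: mean undefined")
    return float(_canonical_angle(math.atan2(y, x))), r


def bin_assign(kappa_i: float, kappa_ip1: float, tau_i: float, psi_i: float,
               config: LibraryConfig = LibraryConfig()) -> BinKey:
    """Assign a residue's backbone state to its library bin.

    The four Δκ sets split at ``config.kappa_threshold`` with the boundary
    on the ≥ (helix-like) side: set 1 both below, set 2 κ_i below / κ_{i+1}
    at-or-above, set 3 the reverse, set 4 both at-or-above.  τ and ψ bins
    are half-open [lo, hi) intervals anchored at −π; the upper boundary
    wraps into the last bin.
    """
    for name, val in (("kappa_i", kappa_i), ("kappa_ip1", kappa_ip1),
                      ("tau_i", tau_i), ("psi_i", psi_i)):
        if not math.isfinite(val):
            raise ValueError(f"non-finite angle {name}={val}")
    thr = config.kappa_threshold
    hi_i, hi_ip1 = kappa_i >= thr, kappa_ip1 >= thr
    dk = {(False, False): 1, (False, True): 2,
          (True, False): 3, (True, True): 4}[(hi_i, hi_ip1)]
    ts = min(int((tau_i + math.pi) / (2 * math.pi / config.n_tau_sectors)),
             config.n_tau_sectors - 1)
    ps = min(int((psi_i + math.pi) / (2 * math.pi / config.n_psi_segments)),
             config.n_psi_segments - 1)
    return BinKey(dk, max(ts, 0), max(ps, 0))


class _Accum:
    """Sufficient statistics for one (bin, pair) cell."""

    __slots__ = ("count", "sum_theta", "sum_cos", "sum_sin")

    def __init__(self):
        self.count = 0
        self.sum_theta = 0.0
        self.sum_cos = 0.0
        self.sum_sin = 0.0

    def add(self, theta: float, phi: float) -> None:
        self.count += 1
        self.sum_theta += theta
        self.sum_cos += math.cos(phi)
        self.sum_sin += math.sin(phi)

    def finalize(self) -> PairStats:
        x = self.sum_cos / self.count
        y = self.sum_sin / self.count
        r = math.hypot(x, y)
        if r < 1e-9:
            logger.warning("antipodally balanced longitudes in a cell; mean set to 0")
            mean_phi = 0.0
        else:
            mean_phi = float(_canonical_angle(math.atan2(y, x)))
        return PairStats(count=self.count,
                         mean_latitude=self.sum_theta / self.count,
                         mean_longitude=mean_phi,
                         resultant_R=r)


def _aggregate(pair_stats: dict[tuple[str, str], PairStats]) -> PairStats:
    """Whole-bin aggregate, derived canonically from the pair cells so that
    a freshly built and a reloaded library answer queries identically."""
    n = 0
    sum_theta = sum_cos = sum_sin = 0.0
    for _, ps in sorted(pair_stats.items()):
        n += ps.count
        sum_theta += ps.count * ps.mean_latitude
        sum_cos += ps.count * ps.resultant_R * math.cos(ps.mean_longitude)
        sum_sin += ps.count * ps.resultant_R * math.sin(ps.mean_longitude)
    x, y = sum_cos / n, sum_sin / n
    r = math.hypot(x, y)
    mean_phi = 0.0 if r < 1e-9 else float(_canonical_angle(math.atan2(y, x)))
    return PairStats(count=n, mean_latitude=sum_theta / n,
                     mean_longitude=mean_phi, resultant_R=r)


@dataclass
class StatLibrary:
    """The binned reference library.

    ``bins`` maps :class:`BinKey` → {(res_i, res_{i+1}) → PairStats}.
    Empty bins are absent.  Whole-bin aggregates are derived on demand.
    """

    config: LibraryConfig
    bins: dict[BinKey, dict[tuple[str, str], PairStats]]
    source_structures: int = 0
    n_observations: int = 0
    built: str = ""

    def bin_aggregate(self, key: BinKey) -> PairStats:
        return _aggregate(self.bins[key])

    def total_count(self) -> int:
        return sum(ps.count for cells in self.bins.values() for ps in cells.values())

    def save(self, path) -> None:
        """Persist as a versioned TSV: `#` header with config/provenance,
        one row per (bin, pair) cell, full float precision."""
        cfg = asdict(self.config)
        with open(path, "w") as fh:
            fh.write(f"# {FORMAT_VERSION}\n")
            for k, v in cfg.items():
                fh.write(f"# {k} = {v!r}\n")
            fh.write(f"# source_structures = {self.source_structures}\n")
            fh.write(f"# n_observations = {self.n_observations}\n")
            fh.write(f"# built = {self.built}\n")
            fh.write("dkappa_set\ttau_sector\tpsi_segment\tres_i\tres_ip1\t"
                     "count\tmean_theta\tmean_phi\tR\n")
            for key in sorted(self.bins):
                for pair in sorted(self.bins[key]):
                    ps = self.bins[key][pair]
                    fh.write(f"{key.dkappa_set}\t{key.tau_sector}\t{key.psi_segment}\t"
                             f"{pair[0]}\t{pair[1]}\t{ps.count}\t"
                             f"{float(ps.mean_latitude)!r}\t"
                             f"{float(ps.mean_longitude)!r}\t"
                             f"{float(ps.resultant_R)!r}\n")

    @classmethod
    def load(cls, path) -> "StatLibrary":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].lstrip("# ").strip() != FORMAT_VERSION:
            raise ValueError(f"not a {FORMAT_VERSION} file: {path}")
        meta: dict[str, str] = {}
        rows_start = 0
        for i, line in enumerate(lines[1:], start=1):
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            else:
                rows_start = i
                break
        cfg = LibraryConfig(
            kappa_threshold=float(meta["kappa_threshold"]),
            n_tau_sectors=int(meta["n_tau_sectors"]),
            n_psi_segments=int(meta["n_psi_segments"]),
            cb_radius=float(meta["cb_radius"]))
        bins: dict[BinKey, dict[tuple[str, str], PairStats]] = {}
        header = lines[rows_start].split("\t")
        if header[0] != "dkappa_set":
            raise ValueError("malformed library header row")
        for line in lines[rows_start + 1:]:
            if not line.strip():
                continue
            f = line.split("\t")
            key = BinKey(int(f[0]), int(f[1]), int(f[2]))
            bins.setdefault(key, {})[(f[3], f[4])] = PairStats(
                count=int(f[5]), mean_latitude=float(f[6]),
                mean_longitude=float(f[7]), resultant_R=float(f[8]))
        return cls(config=cfg, bins=bins,
                   source_structures=int(meta.get("source_structures", 0)),
                   n_observations=int(meta.get("n_observations", 0)),
                   built=meta.get("built", ""))


def eligible_observations(trace: ChainTrace,
                          config: LibraryConfig = LibraryConfig(),
                          frames: Optional[FrameSet] = None,
                          angles: Optional[BackboneAngles] = None):
    """Yield (i, key, pair, theta, phi) for every residue contributing a
    reference observation: valid Frenet frame at i, κ_i and κ_{i+1}, τ_i,
    O(i) for ψ_i, Cβ(i) for (θ, ϕ), and residue i+1's name.  Glycine at i
    contributes nothing (no Cβ)."""
    if frames is None:
        frames = frenet_frames(trace)
    if angles is None:
        angles = backbone_angles(frames)
    names = trace.res_names()
    for i in range(len(trace) - 1):
        res = trace.residues[i]
        if res.res_name == "GLY" or res.cb is None or res.o is None:
            continue
        if not (frames.valid[i] and angles.kappa_valid[i]
                and angles.kappa_valid[i + 1] and angles.tau_valid[i]):
            continue
        fr = frames.frame(i)
        psi = frame_coordinates(fr, res.o).longitude
        cb_dir = frame_coordinates(fr, res.cb)
        key = bin_assign(angles.kappa[i], angles.kappa[i + 1],
                         angles.tau[i], psi, config)
        yield i, key, (names[i], names[i + 1]), cb_dir.latitude, cb_dir.longitude


def build_library(traces: Iterable[ChainTrace],
                  config: LibraryConfig = LibraryConfig()) -> StatLibrary:
    """Build a :class:`StatLibrary` from reference traces carrying Cβ atoms."""
    acc: dict[BinKey, dict[tuple[str, str], _Accum]] = {}
    n_traces = 0
    n_obs = 0
    for trace in traces:
        n_traces += 1
        for _, key, pair, theta, phi in eligible_observations(trace, config):
            acc.setdefault(key, {}).setdefault(pair, _Accum()).add(theta, phi)
            n_obs += 1
    if n_obs == 0:
        raise ValueError("no eligible residues: library would be empty")
    bins = {key: {pair: a.finalize() for pair, a in cells.items()}
            for key, cells in acc.items()}
    return StatLibrary(config=config, bins=bins, source_structures=n_traces,
                       n_observations=n_obs,
                       built=datetime.now(timezone.utc).isoformat(timespec="seconds"))


def neighbor_fallback(lib: StatLibrary, key: BinKey) -> BinKey:
    """Deterministic substitute for an empty bin.

    Within the same (Δκ set, τ sector) the ψ ring is scanned clockwise
    (decreasing segment index, wrapping); if the whole ring is empty the
    τ sector steps clockwise (decreasing, wrapping) and its ψ ring is
    rescanned starting from the original ψ segment.  The Δκ set is never
    changed by the scan; if the entire set is empty, the same (τ, ψ)
    position in the bin-richest other set seeds a scan there (logged).
    """
    if not lib.bins:
        raise ValueError("statistical library is empty")
    n_tau = lib.config.n_tau_sectors
    n_psi = lib.config.n_psi_segments

    def scan(dk: int) -> Optional[BinKey]:
        for tau_off in range(n_tau):
            sector = (key.tau_sector - tau_off) % n_tau
            start = 1 if tau_off == 0 else 0
            for psi_off in range(start, n_psi):
                cand = BinKey(dk, sector, (key.psi_segment - psi_off) % n_psi)
                if cand in lib.bins:
                    return cand
        return None

    found = scan(key.dkappa_set)
    if found is not None:
        return found
    richness = {dk: sum(1 for k in lib.bins if k.dkappa_set == dk)
                for dk in (1, 2, 3, 4) if dk != key.dkappa_set}
    richest = max(richness, key=lambda dk: (richness[dk], -dk))
    logger.warning("dkappa set %d empty; falling back to set %d",
                   key.dkappa_set, richest)
    same_pos = BinKey(richest, key.tau_sector, key.psi_segment)
    if same_pos in lib.bins:
        return same_pos
    found = scan(richest)
    if found is None:
        raise ValueError("statistical library is empty")
    return found


def query(lib: StatLibrary, key: BinKey,
          pair: tuple[str, str]) -> tuple[SphericalDirection, Provenance]:
    """Look up the predicted Cβ direction for a backbone bin and residue pair.

    Selection cascade: unique pair match → that observation
    ('exact-single'); several → their circular average ('exact-averaged');
    pair absent but bin populated → whole-bin aggregate ('bin-average');
    bin empty → :func:`neighbor_fallback` then the same cascade in the
    substituted bin ('neighbor-fallback').
    """
    if not lib.bins:
        raise ValueError("statistical library is empty")
    used = key
    fallback = key not in lib.bins
    if fallback:
        used = neighbor_fallback(lib, key)
    cells = lib.bins[used]
    if pair in cells:
        ps = cells[pair]
        kind = "exact-single" if ps.count == 1 else "exact-averaged"
    else:
        ps = _aggregate(cells)
        kind = "bin-average"
    if fallback:
        kind = "neighbor-fallback"
    direction = SphericalDirection(latitude=ps.mean_latitude,
                                   longitude=ps.mean_longitude,
                                   radius=lib.config.cb_radius)
    return direction, Provenance(kind=kind, requested_key=key, used_key=used)
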