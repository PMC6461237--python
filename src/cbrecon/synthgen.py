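"""Synthetic Cα/O/Cβ chains with controlled backbone-angle programs.

Chains are built by inverting the Frenet-frame relations: a per-residue
(κ, τ) program is turned into Cα positions by frame propagation so that
measuring the generated chain reproduces the program exactly (the
module's defining round-trip contract).  Each chain is then decorated
with carbonyl O atoms (radius 2.40 Å, on the narrow latitude strip
ϑ ≈ π/4 the reference data show) and Cβ atoms (radius 1.55 Å) at
per-residue-pair planted mean directions in the local Frenet frame, with
small-angle von Mises–Fisher-style noise of circular dispersion σ.

Everything is a pure function of the :class:`GeneratorSpec` (including
its seed); chains carry no physics — they are geometric objects only.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .structio import ChainTrace, Residue, STANDARD_AA
from .frames import frenet_frames, frame_coordinates, SphericalDirection

NON_GLY_AA = sorted(STANDARD_AA - {"GLY"})

PRESETS = {
    "alpha": (1.45, 0.8),   # helix-like: kappa > 1.2
    "beta": (0.95, 2.9),    # strand-like: kappa < 1.2
}
PROGRAM_NAMES = ("alpha", "beta", "mixed", "coil")


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions for one synthetic data set.

    ``program`` is a preset name ('alpha', 'beta', 'mixed', 'coil') or an
    (n_residues, 2) array of per-residue (κ, τ); 'coil' samples κ from
    the annulus [1.0, π/2] and τ uniformly.  ``noise_sigma`` is the
    per-tangent-component circular dispersion (radians) applied to both O
    and Cβ directions.
    """

    n_chains: int = 50
    n_residues: int = 60
    program: Union[str, np.ndarray] = "alpha"
    gly_fraction: float = 0.0
    noise_sigma: float = 0.05
    o_lat_center: float = math.pi / 4
    ca_spacing: float = 3.8
    cb_radius: float = 1.55
    o_radius: float = 2.40
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1 or self.n_residues < 4:
            raise ValueError("need at least 1 chain of 4 residues")
        if self.noise_sigma < 0:
            raise ValueError("noise dispersion must be non-negative")
        if isinstance(self.program, str) and self.program not in PROGRAM_NAMES:
            raise ValueError(f"unknown program preset {self.program!r}")


def _rng(spec: GeneratorSpec, stream: int, chain: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), stream, chain])


def _resolve_program(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    if not isinstance(spec.program, str):
        prog = np.asarray(spec.program, dtype=float)
        if prog.shape != (n, 2):
            raise ValueError(f"explicit program must have shape ({n}, 2)")
        return prog
    if spec.program in PRESETS:
        k, t = PRESETS[spec.program]
        return np.tile([k, t], (n, 1))
    if spec.program == "mixed":
        half = n // 2
        out = np.empty((n, 2))
        out[:half] = PRESETS["alpha"]
        out[half:] = PRESETS["beta"]
        return out
    # coil: kappa from the populated annulus, tau uniform
    out = np.column_stack([rng.uniform(1.0, math.pi / 2, n),
                           rng.uniform(-math.pi, math.pi, n)])
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _sample_names(spec: GeneratorSpec, rng: np.random.Generator) -> list[str]:
    names = rng.choice(NON_GLY_AA, size=spec.n_residues)
    if spec.gly_fraction > 0:
        gly = rng.random(spec.n_residues) < spec.gly_fraction
        names = np.where(gly, "GLY", names)
    return [str(x) for x in names]


def generate_backbone(spec: GeneratorSpec) -> list[ChainTrace]:
    """Cα-only chains whose measured (κ, τ) reproduce the program.

    Frame propagation: t_{i+1} = cos κ_i · t_i + sin κ_i (cos τ_i · n_i −
    sin τ_i · b_i), the transfer that makes the Frenet-frame measurement of
    the chain return the input angles (the τ of the first bond is not
    measurable and is ignored).  Cα spacing is exact.  Each chain gets a
    random rigid placement; the same seed reproduces chains bit-identically.
    """
    traces = []
    for c in range(spec.n_chains):
        rng = _rng(spec, 0, c)
        prog = _resolve_program(spec, rng)
        kappa, tau = prog[:, 0], prog[:, 1]
        if np.any((kappa <= 0) | (kappa >= math.pi)):
            raise ValueError("kappa program values must lie strictly in (0, pi)")
        names = _sample_names(spec, rng)
        rot = _random_rotation(rng)
        offset = rng.uniform(-50, 50, 3)

        n = spec.n_residues
        t = np.empty((n - 1, 3))
        t[0] = rot @ np.array([0.0, 0.0, 1.0])
        x0 = rot @ np.array([1.0, 0.0, 0.0])
        t[1] = math.cos(kappa[0]) * t[0] + math.sin(kappa[0]) * x0
        for i in range(1, n - 2):
            b = np.cross(t[i - 1], t[i])
            b /= np.linalg.norm(b)
            nvec = np.cross(b, t[i])
            t[i + 1] = (math.cos(kappa[i]) * t[i]
                        + math.sin(kappa[i]) * (math.cos(tau[i]) * nvec
                                                - math.sin(tau[i]) * b))
        ca = np.empty((n, 3))
        ca[0] = offset
        for i in range(n - 1):
            ca[i + 1] = ca[i] + spec.ca_spacing * t[i]

        residues = [Residue(seq_index=i + 1, res_name=names[i], ca=ca[i],
                            auth_seq=i + 1) for i in range(n)]
        traces.append(ChainTrace(model_id=c + 1, chain_id="A", residues=residues))
    return traces


def pair_direction_means(spec: GeneratorSpec,
                         pair: tuple[str, str]) -> dict[str, float]:
    """Planted mean directions for a residue pair (deterministic in the
    seed and the pair, independent of chain or position).

    Cβ: latitude θ away from the poles, longitude ϕ uniform; O: latitude
    ϑ on the narrow strip around ``o_lat_center``, longitude ψ uniform.
    """
    h = zlib.crc32(f"{pair[0]}|{pair[1]}".encode()) & 0x7FFFFFFF
    r = np.random.default_rng([spec.seed % (2**31), 7, h])
    return {
        "theta": float(r.uniform(0.5, 2.6)),
        "phi": float(r.uniform(-math.pi, math.pi)),
        "o_lat": float(spec.o_lat_center + r.uniform(-0.08, 0.08)),
        "o_psi": float(r.uniform(-math.pi, math.pi)),
    }


def _perturb(u: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Small-angle vMF-style noise: tangent-plane Gaussian wrapped onto the
    sphere, scaled so that the circular standard deviation √(−2 ln R̄) of
    the perturbed directions equals ``sigma`` (per tangent component the
    Gaussian sd is σ/√2)."""
    if sigma == 0.0:
        return u
    sigma = sigma / math.sqrt(2.0)
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    g1, g2 = rng.normal(0.0, sigma, 2)
    a = math.hypot(g1, g2)
    if a < 1e-15:
        return u
    d = (g1 * e1 + g2 * e2) / a
    return math.cos(a) * u + math.sin(a) * d


def decorate(traces: Sequence[ChainTrace], spec: GeneratorSpec) -> list[ChainTrace]:
    """Add O and Cβ atoms (in place) at planted directions plus noise.

    O(i) sits at ``o_radius`` Å and Cβ(i) at ``cb_radius`` Å along the
    (pair-mean ⊕ noise) directions in the Frenet frame at i; residues
    without a valid frame (chain ends, breaks) stay undecorated, and
    glycine gets no Cβ.
    """
    for c, trace in enumerate(traces):
        rng = _rng(spec, 1, c)
        frames = frenet_frames(trace)
        for i, res in enumerate(trace.residues):
            if not frames.valid[i] or i + 1 >= len(trace):
                continue
            means = pair_direction_means(spec, (res.res_name,
                                                trace.residues[i + 1].res_name))
            fr = frames.frame(i)
            o_dir = SphericalDirection(means["o_lat"], means["o_psi"]).unit_vector()
            o_dir = _perturb(o_dir, spec.noise_sigma, rng)
            res.o = fr.origin + spec.o_radius * (fr.axes.T @ o_dir)
            if res.res_name != "GLY":
                cb_dir = SphericalDirection(means["theta"], means["phi"]).unit_vector()
                cb_dir = _perturb(cb_dir, spec.noise_sigma, rng)
                res.cb = fr.origin + spec.cb_radius * (fr.axes.T @ cb_dir)
    return list(traces)


def generate(spec: GeneratorSpec) -> list[ChainTrace]:
    """Full pipeline: backbone from the (κ, τ) program, then O/Cβ decoration."""
    return decorate(generate_backbone(spec), spec)


def truth_table(spec: GeneratorSpec,
                traces: Sequence[ChainTrace]) -> pd.DataFrame:
    """Planted mean directions for every residue pair present in ``traces``."""
    pairs = sorted({(t.residues[i].res_name, t.residues[i + 1].res_name)
                    for t in traces for i in range(len(t) - 1)})
    rows = [{"res_i": a, "res_ip1": b, **pair_direction_means(spec, (a, b))}
            for a, b in pairs]
    return pd.DataFrame(rows)


def make_benchmark(spec: GeneratorSpec, train_fraction: float = 0.8,
                   ) -> tuple[list[ChainTrace], list[ChainTrace], pd.DataFrame]:
    """Deterministic train/test split plus the planted-direction truth table.

    The first ``round(train_fraction · n_chains)`` chains train the
    library; the rest are held out.  Splitting by chain index is
    reproducible under a fixed seed and keeps the sets disjoint.
    """
    if spec.n_chains < 2:
        raise ValueError("a benchmark needs at least 2 chains")
    traces = generate(spec)
    n_train = int(round(train_fraction * spec.n_chains))
    n_train = min(max(n_train, 1), spec.n_chains - 1)
    train, test = traces[:n_train], traces[n_train:]
    return train, test, truth_table(spec, traces)
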