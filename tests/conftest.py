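"""Shared fixtures: hand-written PDB text and small synthetic chains."""

from __future__ import annotations

import numpy as np
import pytest

from cbrecon import ChainTrace, GeneratorSpec, Residue, decorate, generate_backbone


def pdb_atom_line(serial: int, name: str, res_name: str, chain: str, seq: int,
                  xyz, occ: float = 1.0, altloc: str = " ",
                  element: str = " C") -> str:
    """One fixed-width ATOM record."""
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {name_field}{altloc}{res_name:>3s} {chain}"
            f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def make_pdb(records: list[str]) -> str:
    return "\n".join(records + ["END"]) + "\n"


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written 3-residue chain with CA/O/CB, trans spacing ~3.8 A."""
    lines = []
    serial = 1
    for i, (name, ca) in enumerate([("ALA", (0.0, 0.0, 0.0)),
                                    ("LEU", (3.8, 0.0, 0.0)),
                                    ("SER", (5.9, 3.2, 0.0))], start=1):
        ca = np.array(ca)
        lines.append(pdb_atom_line(serial, "CA", name, "A", i, ca)); serial += 1
        lines.append(pdb_atom_line(serial, "O", name, "A", i, ca + (1.2, 1.8, 0.6),
                                   element=" O")); serial += 1
        lines.append(pdb_atom_line(serial, "CB", name, "A", i, ca + (0.5, -1.2, 0.8)))
        serial += 1
    path = tmp_path / "three.pdb"
    path.write_text(make_pdb(lines))
    return path


def manual_trace(ca_coords, names=None, o=None, cb=None, model_id=1) -> ChainTrace:
    """Build a ChainTrace directly from coordinate arrays."""
    ca_coords = np.asarray(ca_coords, dtype=float)
    n = len(ca_coords)
    names = names or ["ALA"] * n
    residues = [Residue(seq_index=i + 1, res_name=names[i], ca=ca_coords[i],
                        o=None if o is None or o[i] is None else np.asarray(o[i], float),
                        cb=None if cb is None or cb[i] is None else np.asarray(cb[i], float),
                        auth_seq=i + 1)
                for i in range(n)]
    return ChainTrace(model_id=model_id, chain_id="A", residues=residues)


def distinct_pair_chain(n_residues: int = 14, seed: int = 77, sigma: float = 0.05):
    """One decorated chain whose consecutive residue pairs are all distinct,
    so every library cell it populates has a unique occupant."""
    from cbrecon.synthgen import NON_GLY_AA

    spec = GeneratorSpec(n_chains=1, n_residues=n_residues, program="alpha",
                         noise_sigma=sigma, seed=seed)
    (trace,) = generate_backbone(spec)
    for i, res in enumerate(trace.residues):
        res.res_name = NON_GLY_AA[i % len(NON_GLY_AA)]
    decorate([trace], spec)
    return spec, trace


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-20, 20, 3)


def apply_motion(trace: ChainTrace, rot, shift) -> ChainTrace:
    moved = manual_trace([rot @ r.ca + shift for r in trace.residues],
                         names=trace.res_names(),
                         o=[None if r.o is None else rot @ r.o + shift
                            for r in trace.residues],
                         cb=[None if r.cb is None else rot @ r.cb + shift
                             for r in trace.residues],
                         model_id=trace.model_id)
    moved.break_after = set(trace.break_after)
    moved.cis_like = set(trace.cis_like)
    return moved
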