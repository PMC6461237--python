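"""Structure file IO: extract Cα/O/Cβ traces from PDB/mmCIF, write results.

The universal in-memory object is :class:`ChainTrace`: one per
(model, chain), holding ordered residues with their Cα position and the
optional carbonyl O and side-chain Cβ positions, plus chain-break flags.
Parsing and serialization are delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

try:
    import gemmi
except ImportError as exc:  # pragma: no cover
    raise ImportError("cbrecon requires gemmi for structure IO") from exc

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})

#: nonstandard residue-name aliases (configuration, not code): norleucine
#: behaves like leucine for pair keys, protonation variants collapse to HIS,
#: selenomethionine to MET.
DEFAULT_ALIASES = {
    "NLE": "LEU",
    "MSE": "MET",
    "HIP": "HIS", "HID": "HIS", "HIE": "HIS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS",
}

#: Cα(i)–Cα(i+1) distance window accepted as a continuous chain, Å.
#: Admits trans (~3.8 Å) and cis (~3.0 Å) virtual bonds, rejects gaps.
DEFAULT_MIN_CA_DIST = 2.5
DEFAULT_MAX_CA_DIST = 4.3
#: below this the virtual bond is additionally flagged cis-like
CIS_LIKE_MAX = 3.3


@dataclass
class Residue:
    """One residue of a trace.  ``seq_index`` is the 1-based position along
    the extracted trace; ``auth_seq``/``icode`` preserve the file numbering."""

    seq_index: int
    res_name: str
    ca: np.ndarray
    o: Optional[np.ndarray] = None
    cb: Optional[np.ndarray] = None
    auth_seq: int = 0
    icode: str = ""


@dataclass
class ChainTrace:
    """Per-chain Cα/O/Cβ trace with break bookkeeping.

    ``break_after`` holds 0-based positions ``i`` where chain continuity
    between residues ``i`` and ``i+1`` fails; ``cis_like`` marks short
    (~3.0 Å) virtual bonds that are continuous but cis-peptide-like.
    """

    model_id: int
    chain_id: str
    residues: list[Residue]
    break_after: set[int] = field(default_factory=set)
    cis_like: set[int] = field(default_factory=set)
    missing: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_array(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def atom_array(self, role: str) -> np.ndarray:
        """(N, 3) array for role 'CA', 'O' or 'CB'; NaN where absent."""
        out = np.full((len(self.residues), 3), np.nan)
        attr = role.lower()
        for i, r in enumerate(self.residues):
            v = getattr(r, attr)
            if v is not None:
                out[i] = v
        return out

    def res_names(self) -> list[str]:
        return [r.res_name for r in self.residues]


def _resolve_altlocs(residue: "gemmi.Residue") -> dict[str, "gemmi.Atom"]:
    """Pick one atom per name: highest occupancy, ties by altloc identifier."""
    by_name: dict[str, list] = {}
    seen: set[tuple[str, str]] = set()
    for atom in residue:
        alt = atom.altloc if atom.altloc and atom.altloc != "\x00" else ""
        key = (atom.name, alt)
        if key in seen:
            raise ValueError(
                f"duplicate atom record {atom.name!r} altloc {alt!r} "
                f"in residue {residue.name} {residue.seqid.num}")
        seen.add(key)
        by_name.setdefault(atom.name, []).append((-atom.occ, alt, atom))
    return {name: sorted(cands)[0][2] for name, cands in by_name.items()}


def read_traces(path, atom_requirements: Iterable[str] = ("CA", "O"),
                aliases: Optional[dict[str, str]] = None,
                min_d: float = DEFAULT_MIN_CA_DIST,
                max_d: float = DEFAULT_MAX_CA_DIST) -> list[ChainTrace]:
    """Read a (multi-model) PDB or mmCIF file into :class:`ChainTrace` objects.

    One trace per (model, chain).  Altloc conflicts resolve to the
    highest-occupancy conformer (ties: first altloc identifier).  Residues
    recognized as amino acids but lacking a required atom are recorded in
    ``trace.missing``; a residue without a Cα cannot be placed on the trace
    at all and the resulting gap is handled by break detection.
    """
    roles = {r.upper() for r in atom_requirements}
    if not roles <= {"CA", "O", "CB"}:
        raise ValueError(f"atom requirements must be within CA/O/CB, got {roles}")
    alias_map = DEFAULT_ALIASES if aliases is None else aliases
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"unreadable structure file {path}: {exc}") from exc

    traces: list[ChainTrace] = []
    any_ca = False
    for model in st:
        for chain in model:
            residues: list[Residue] = []
            missing: list[tuple[str, str]] = []
            for res in chain:
                name = res.name.strip().upper()
                name = alias_map.get(name, name)
                atoms = _resolve_altlocs(res)
                known_aa = name in STANDARD_AA
                if not known_aa and "CA" not in atoms:
                    continue  # water / ligand / nucleic acid
                label = f"{chain.name}:{res.seqid.num}{res.seqid.icode.strip()}"
                if "CA" not in atoms:
                    if "CA" in roles:
                        missing.append((label, "CA"))
                        logger.warning("residue %s lacks required CA; skipped", label)
                    continue
                coords = {}
                for role in ("CA", "O", "CB"):
                    if role in atoms:
                        p = atoms[role].pos
                        coords[role] = np.array([p.x, p.y, p.z])
                    elif role in roles and not (role == "CB" and name == "GLY"):
                        missing.append((label, role))
                if not np.all(np.isfinite(coords["CA"])):
                    raise ValueError(f"non-finite CA coordinates at {label}")
                any_ca = True
                residues.append(Residue(
                    seq_index=len(residues) + 1,
                    res_name=name,
                    ca=coords["CA"],
                    o=coords.get("O"),
                    cb=coords.get("CB"),
                    auth_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                ))
            if not residues:
                continue
            trace = ChainTrace(model_id=model.num, chain_id=chain.name,
                               residues=residues, missing=missing)
            if len(residues) >= 2:
                detect_breaks(trace, min_d=min_d, max_d=max_d)
            traces.append(trace)
    if not any_ca:
        raise ValueError(f"no residue with a CA atom in {path}")
    return traces


def detect_breaks(trace: ChainTrace, min_d: float = DEFAULT_MIN_CA_DIST,
                  max_d: float = DEFAULT_MAX_CA_DIST) -> ChainTrace:
    """Populate ``break_after``/``cis_like`` from consecutive Cα distances.

    Position ``i`` is a break iff |Cα(i+1) − Cα(i)| falls outside
    [min_d, max_d]; distances in [min_d, 3.3) are flagged cis-like but are
    not breaks.  Invariant under rigid motion (distances only).
    """
    if len(trace) < 2:
        raise ValueError("break detection needs at least two residues")
    ca = trace.ca_array()
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    trace.break_after = set(np.nonzero((d < min_d) | (d > max_d))[0].tolist())
    trace.cis_like = set(
        np.nonzero((d >= min_d) & (d < CIS_LIKE_MAX))[0].tolist()) - trace.break_after
    return trace


def _add_atom(res: "gemmi.Residue", name: str, element: str, xyz) -> None:
    a = gemmi.Atom()
    a.name = name
    a.element = gemmi.Element(element)
    a.pos = gemmi.Position(*(float(x) for x in xyz))
    a.occ = 1.0
    a.b_iso = 0.0
    res.add_atom(a)


def _trace_to_gemmi_chain(trace: ChainTrace, reconstructed=None) -> "gemmi.Chain":
    chain = gemmi.Chain(trace.chain_id or "A")
    g_residues = []
    for r in trace.residues:
        res = gemmi.Residue()
        res.name = r.res_name
        res.seqid = gemmi.SeqId(r.auth_seq or r.seq_index, r.icode or " ")
        _add_atom(res, "CA", "C", r.ca)
        if r.o is not None:
            _add_atom(res, "O", "O", r.o)
        g_residues.append(res)

    if reconstructed is not None:
        for rec in reconstructed.records:
            i = rec.index
            if i >= len(g_residues):
                raise ValueError("reconstructed indices exceed trace length")
            if rec.cb is not None:
                name = "CB" if trace.residues[i].res_name != "GLY" else "XB"
                _add_atom(g_residues[i], name, "C", rec.cb)
            if rec.plane_atoms is not None:
                _add_atom(g_residues[i], "C", "C", rec.plane_atoms["C"])
                if i + 1 < len(g_residues):
                    _add_atom(g_residues[i + 1], "N", "N", rec.plane_atoms["N"])
                    _add_atom(g_residues[i + 1], "H", "H", rec.plane_atoms["H"])
    else:
        for i, r in enumerate(trace.residues):
            if r.cb is not None:
                _add_atom(g_residues[i], "CB", "C", r.cb)

    for res in g_residues:
        chain.add_residue(res)
    return chain


def write_structure(trace: ChainTrace, reconstructed=None, path=None) -> None:
    """Write one trace (plus an optional reconstruction) as a PDB file.

    Input CA/O atoms are emitted as read; predicted CB (and, when plane
    completion ran, C/N/H) records are added.  Fixed-width PDB keeps three
    decimals, so a read-back round trip agrees to 1e-3 Å.
    """
    write_traces([trace], path, reconstructions=[reconstructed] if reconstructed else None)


def write_traces(traces: Sequence[ChainTrace], path,
                 reconstructions=None) -> None:
    """Write traces as a (multi-model) PDB file.

    Traces sharing a ``model_id`` land in the same MODEL block; chains keep
    their identifiers.
    """
    if reconstructions is not None and len(reconstructions) != len(traces):
        raise ValueError("one reconstruction (or None) per trace required")
    st = gemmi.Structure()
    st.name = "cbrecon"
    models: dict[int, "gemmi.Model"] = {}
    for k, trace in enumerate(traces):
        rec = reconstructions[k] if reconstructions is not None else None
        mid = trace.model_id or 1
        if mid not in models:
            models[mid] = gemmi.Model(mid)
        models[mid].add_chain(_trace_to_gemmi_chain(trace, rec))
    for mid in sorted(models):
        st.add_model(models[mid])
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except Exception as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc
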