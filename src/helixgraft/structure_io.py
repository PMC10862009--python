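"""Structures, ensembles and PDB input/output.

The in-memory model is deliberately small: a :class:`PolymerStructure` is an
ordered set of chains of residues of named heavy atoms (hydrogens are kept
if present, never required), and an :class:`Ensemble` is a stack of
coordinate frames sharing one topology — the natural container for a
multi-MODEL PDB trajectory.  Author residue numbering is preserved
everywhere and all residue ranges are inclusive on both ends, matching the
convention used for epitope segments such as Glut1 35–54.

PDB parsing and writing are delegated to gemmi; a light validation pass
runs first so that malformed coordinate fields are reported with their line
number instead of being silently coerced.
"""

from __future__ import annotations

import dataclasses
import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Residue",
    "PolymerStructure",
    "Ensemble",
    "SegmentSpec",
    "HelixgraftError",
    "PdbParseError",
    "TopologyMismatchError",
    "SegmentGapError",
    "read_pdb",
    "write_pdb",
    "extract_segment",
    "sequence_of",
    "ensemble_to_csv",
    "ensemble_from_csv",
]


class HelixgraftError(Exception):
    """Base class for all package errors."""


class PdbParseError(HelixgraftError):
    """A PDB record could not be parsed; message names the line number."""


class TopologyMismatchError(HelixgraftError):
    """MODEL blocks (or frames) disagree on atom count or identity."""


class SegmentGapError(HelixgraftError):
    """A requested residue range has missing residues."""

    def __init__(self, chain_id: str, missing: Sequence[int]):
        self.chain_id = chain_id
        self.missing = list(missing)
        super().__init__(
            f"chain {chain_id!r}: residues missing from range: {self.missing}"
        )


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common histidine tautomer names
    "HSD": "H", "HSE": "H", "HSP": "H",
}
ONE_TO_THREE = {v: k for k, v in list(THREE_TO_ONE.items())[:20]}

_WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "DOD"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    """One atom: PDB-convention name, element, coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.coords.copy(),
                          self.occupancy, self.b_factor)


@dataclass
class Residue:
    """One residue in author numbering with an ordered atom list."""

    chain_id: str
    res_seq: int
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name.upper(), "X")

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.res_seq, self.res_name,
                       [a.copy() for a in self.atoms])


class PolymerStructure:
    """Ordered chains of residues; the single-conformer container."""

    def __init__(self, chains: dict[str, list[Residue]] | None = None,
                 title: str = ""):
        self.chains: dict[str, list[Residue]] = chains if chains is not None else {}
        self.title = title
        for cid, residues in self.chains.items():
            seqs = [r.res_seq for r in residues]
            if any(b <= a for a, b in zip(seqs, seqs[1:])):
                raise ValueError(
                    f"chain {cid!r}: res_seq must be strictly increasing"
                )

    # -- iteration ---------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains.keys())

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is None:
            for residues in self.chains.values():
                yield from residues
        else:
            yield from self.chains[chain_id]

    def get_residue(self, chain_id: str, res_seq: int) -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.res_seq == res_seq:
                return r
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    # -- coordinates -------------------------------------------------------
    def coords(self) -> np.ndarray:
        """All atom coordinates, (n_atoms, 3), in chain/residue/atom order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coords for r in self.residues() for a in r.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise TopologyMismatchError(
                f"expected coordinates of shape ({self.n_atoms}, 3), "
                f"got {xyz.shape}"
            )
        k = 0
        for r in self.residues():
            for a in r.atoms:
                a.coords = xyz[k].copy()
                k += 1

    def with_coords(self, xyz: np.ndarray) -> "PolymerStructure":
        s = self.copy()
        s.set_coords(xyz)
        return s

    def copy(self) -> "PolymerStructure":
        return PolymerStructure(
            {cid: [r.copy() for r in residues]
             for cid, residues in self.chains.items()},
            title=self.title,
        )

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        """Map (chain_id, res_seq, atom_name) -> flat coordinate row."""
        idx = {}
        k = 0
        for r in self.residues():
            for a in r.atoms:
                idx[(r.chain_id, r.res_seq, a.name)] = k
                k += 1
        return idx


@dataclass
class Ensemble:
    """Coordinate frames over one topology, e.g. a trajectory replicate."""

    topology: PolymerStructure
    frames: list[np.ndarray]
    frame_spacing_ps: float = 10.0
    replicate_id: int = 0

    def __post_init__(self):
        if self.frame_spacing_ps <= 0:
            raise ValueError("frame_spacing_ps must be > 0")
        na = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (na, 3):
                raise TopologyMismatchError(
                    f"frame {i}: expected shape ({na}, 3), got {f.shape}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def structure_at(self, i: int) -> PolymerStructure:
        return self.topology.with_coords(self.frames[i])

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_spacing_ps


@dataclass(frozen=True)
class SegmentSpec:
    """Inclusive author-numbered residue range on one chain."""

    chain_id: str
    start_res: int
    end_res: int

    def __post_init__(self):
        if self.start_res > self.end_res:
            raise ValueError("start_res must be <= end_res")

    @property
    def n_residues(self) -> int:
        return self.end_res - self.start_res + 1

    def interior(self, exclude_terminal: int = 2) -> "SegmentSpec":
        """Shrink both ends, e.g. the paper-style 2-per-terminus exclusion."""
        s = self.start_res + exclude_terminal
        e = self.end_res - exclude_terminal
        if s > e:
            raise ValueError(
                f"segment {self} empty after excluding {exclude_terminal} "
                "residues per terminus"
            )
        return SegmentSpec(self.chain_id, s, e)

    @classmethod
    def parse(cls, text: str) -> "SegmentSpec":
        """Parse 'A:35-69' (chain:start-end)."""
        m = re.fullmatch(r"([^:]+):(-?\d+)-(-?\d+)", text.strip())
        if not m:
            raise ValueError(f"cannot parse segment spec {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))

    def __str__(self):
        return f"{self.chain_id}:{self.start_res}-{self.end_res}"


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PdbParseError(
                f"line {lineno}: truncated coordinate record"
            )
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi].strip()
            try:
                float(fld)
            except ValueError:
                raise PdbParseError(
                    f"line {lineno}: malformed {label} coordinate field "
                    f"{fld!r}"
                ) from None


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def _model_signature(model: gemmi.Model) -> list[tuple[str, int, str, str]]:
    sig = []
    for chain, res, atom in _iter_polymer_atoms(model):
        sig.append((chain.name, res.seqid.num, res.name, atom.name))
    return sig


def _iter_polymer_atoms(model: gemmi.Model):
    """Yield (chain, residue, atom) for non-HETATM, non-water residues,
    one conformer per atom name."""
    for chain in model:
        for res in chain:
            if res.het_flag == "H" or res.name in _WATER_NAMES:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name in by_name:
                yield chain, res, _select_altloc(by_name[name])


def read_pdb(path: str | os.PathLike) -> Ensemble:
    """Read a single- or multi-MODEL PDB file into an :class:`Ensemble`.

    One frame per MODEL block (a single frame if there are none); HETATM
    records and waters are skipped; for alternate locations the
    highest-occupancy conformer is kept.  MODEL blocks must be congruent.
    """
    with open(path) as fh:
        text = fh.read()
    if "ATOM" not in text:
        raise PdbParseError(f"{path}: no ATOM records found")
    _validate_pdb_lines(text)

    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PdbParseError(f"{path}: no models parsed")

    ref_sig = _model_signature(st[0])
    if not ref_sig:
        raise PdbParseError(f"{path}: no polymer ATOM records")

    # topology from the first model
    chains: dict[str, list[Residue]] = {}
    cur: Residue | None = None
    for chain, res, atom in _iter_polymer_atoms(st[0]):
        key = (chain.name, res.seqid.num, res.name)
        if cur is None or (cur.chain_id, cur.res_seq, cur.res_name) != key:
            cur = Residue(chain.name, res.seqid.num, res.name)
            chains.setdefault(chain.name, []).append(cur)
        cur.atoms.append(AtomRecord(
            atom.name,
            atom.element.name if atom.element else "",
            np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            atom.occ, atom.b_iso,
        ))
    topology = PolymerStructure(chains, title=st.name or "")

    frames = []
    for i, model in enumerate(st):
        sig = _model_signature(model)
        if sig != ref_sig:
            raise TopologyMismatchError(
                f"{path}: MODEL block {i + 1} is incongruent with MODEL 1"
            )
        xyz = np.array([
            [atom.pos.x, atom.pos.y, atom.pos.z]
            for _, _, atom in _iter_polymer_atoms(model)
        ])
        frames.append(xyz)

    return Ensemble(topology, frames)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(serial: int, atom: AtomRecord, res: Residue,
                      xyz: np.ndarray) -> str:
    name = atom.name
    # PDB column rule: 1-letter elements start at column 14
    if len(name) < 4 and (len(atom.element) == 1 or len(name) < 3):
        name = " " + name
    return (
        f"ATOM  {serial:5d} {name:<4s} {res.res_name:<3s} "
        f"{res.chain_id[:1]:1s}{res.res_seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(ens: Ensemble | PolymerStructure, path: str | os.PathLike) -> None:
    """Write standard PDB; multi-frame ensembles get MODEL/ENDMDL blocks,
    a single frame (or a bare structure) is written as a plain file."""
    if isinstance(ens, PolymerStructure):
        ens = Ensemble(ens, [ens.coords()])
    if ens.n_frames == 0:
        raise ValueError("cannot write an empty ensemble")

    topo = ens.topology
    lines: list[str] = []
    if topo.title:
        lines.append(f"TITLE     {topo.title[:70]}")
    multi = ens.n_frames > 1
    for fi, frame in enumerate(ens.frames):
        if multi:
            lines.append(f"MODEL     {fi + 1:4d}")
        serial = 0
        k = 0
        for cid, residues in topo.chains.items():
            for res in residues:
                for atom in res.atoms:
                    serial += 1
                    lines.append(_format_atom_line(serial, atom, res, frame[k]))
                    k += 1
            serial += 1
            last = residues[-1]
            lines.append(
                f"TER   {serial:5d}      {last.res_name:<3s} "
                f"{cid[:1]:1s}{last.res_seq:4d}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Segments & sequences
# ---------------------------------------------------------------------------

def extract_segment(s: PolymerStructure, spec: SegmentSpec) -> PolymerStructure:
    """Return the inclusive residue range as a new structure.

    Author numbering is preserved; missing residues in the range raise
    :class:`SegmentGapError` listing the absent res_seq values.
    """
    if spec.chain_id not in s.chains:
        raise SegmentGapError(spec.chain_id,
                              list(range(spec.start_res, spec.end_res + 1)))
    present = {r.res_seq: r for r in s.chains[spec.chain_id]}
    wanted = range(spec.start_res, spec.end_res + 1)
    missing = [i for i in wanted if i not in present]
    if missing:
        raise SegmentGapError(spec.chain_id, missing)
    residues = [present[i].copy() for i in wanted]
    return PolymerStructure({spec.chain_id: residues},
                            title=f"{s.title} {spec}".strip())


def sequence_of(s: PolymerStructure, chain_id: str) -> str:
    """One-letter sequence of a chain; unknown residue names map to 'X'."""
    if chain_id not in s.chains:
        raise KeyError(f"no chain {chain_id!r}")
    return "".join(r.one_letter for r in s.chains[chain_id])


# ---------------------------------------------------------------------------
# CSV serialization of ensembles
# ---------------------------------------------------------------------------

def ensemble_to_csv(ens: Ensemble, path: str | os.PathLike) -> None:
    """Long-format CSV: frame, chain, res_seq, res_name, atom_name, x, y, z."""
    rows = []
    for fi, frame in enumerate(ens.frames):
        k = 0
        for r in ens.topology.residues():
            for a in r.atoms:
                rows.append((fi, r.chain_id, r.res_seq, r.res_name, a.name,
                             a.element, *frame[k]))
                k += 1
    pd.DataFrame(rows, columns=["frame", "chain", "res_seq", "res_name",
                                "atom_name", "element", "x", "y", "z"]
                 ).to_csv(path, index=False, float_format="%.4f")


def ensemble_from_csv(path: str | os.PathLike,
                      frame_spacing_ps: float = 10.0) -> Ensemble:
    df = pd.read_csv(path)
    f0 = df[df["frame"] == df["frame"].min()]
    chains: dict[str, list[Residue]] = {}
    cur: Residue | None = None
    for row in f0.itertuples(index=False):
        key = (str(row.chain), int(row.res_seq), str(row.res_name))
        if cur is None or (cur.chain_id, cur.res_seq, cur.res_name) != key:
            cur = Residue(*key)
            chains.setdefault(str(row.chain), []).append(cur)
        cur.atoms.append(AtomRecord(str(row.atom_name), str(row.element),
                                    np.array([row.x, row.y, row.z])))
    topo = PolymerStructure(chains)
    frames = [g[["x", "y", "z"]].to_numpy(dtype=float)
              for _, g in df.groupby("frame", sort=True)]
    return Ensemble(topo, frames, frame_spacing_ps=frame_spacing_ps)
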