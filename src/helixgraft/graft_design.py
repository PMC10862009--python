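"""Chimeric antigen construction: loop excision, linker sizing, sequence
assembly with index maps, a crude rigid-placement initial model, and
alanine-truncation mutants.

The design operation mirrors loop grafting onto a display scaffold: a
donor segment (e.g. an epitope helix) replaces an excised scaffold loop,
with flexible linkers sized from the mismatch between the donor's
end-to-end span and the Cα–Cα gap between the residues flanking the
excised loop.  The initial 3D model is an explicitly crude rigid
placement with a clash check — a starting point for refinement, not a
prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import rotation_about_axis, rotation_aligning, unit
from .structure_io import (ONE_TO_THREE, AtomRecord, HelixgraftError,
                           PolymerStructure, Residue, SegmentSpec,
                           extract_segment, sequence_of)

__all__ = ["GeometryError", "ClashError", "GraftDesign", "GeometryReport",
           "anchor_gap", "helix_span_estimate", "recommend_linkers",
           "build_chimera", "build_initial_model", "mutate_to_alanine",
           "geometry_report"]

HELIX_RISE_PER_RES = 1.5      # Å per residue along an α-helix axis
LINKER_REACH_PER_RES = 3.5    # Å per extended linker residue
LINKER_SLACK = 4.0            # Å of reach asked for beyond the mismatch
LINKER_CAP = 10               # residues per side
CLASH_DISTANCE = 2.0          # Å heavy-atom floor
PLACEMENT_STANDOFFS = (4.0, 5.0, 6.0, 7.0, 8.0)   # Å outward displacements
                              # of the donor midpoint tried in order

ALA_KEEP_ATOMS = {"N", "CA", "C", "O", "CB", "H"}


class GeometryError(HelixgraftError):
    """Required anchor/terminal geometry is unavailable."""


class ClashError(HelixgraftError):
    """No clash-free placement found; carries the offending atom pairs."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"{a}-{b} {d:.2f} Å" for a, b, d in self.pairs[:5])
        super().__init__(
            f"{len(self.pairs)} heavy-atom pair(s) under "
            f"{CLASH_DISTANCE} Å: {shown}")


@dataclass(frozen=True)
class IndexMapEntry:
    chimera_pos: int               # 1-based position in the chimera
    source: str                    # scaffold | linker | donor
    source_res_seq: int | None     # author numbering, None for linkers


@dataclass
class GraftDesign:
    """A chimera: scaffold with one loop excised and a donor segment
    inserted between flexible linkers."""

    scaffold_id: str
    excised_loop: SegmentSpec
    donor_id: str
    donor_segment: SegmentSpec
    linker_n: str
    linker_c: str
    chimera_sequence: str
    index_map: list[IndexMapEntry] = field(default_factory=list)

    def positions_of(self, source: str) -> list[int]:
        return [e.chimera_pos for e in self.index_map if e.source == source]

    def donor_res_for(self, chimera_pos: int) -> int | None:
        for e in self.index_map:
            if e.chimera_pos == chimera_pos and e.source == "donor":
                return e.source_res_seq
        return None


@dataclass
class GeometryReport:
    anchor_gap: float
    donor_end_to_end: float
    helix_span_estimate: float
    recommended_linker_len: int


def anchor_gap(scaffold: PolymerStructure, loop: SegmentSpec) -> float:
    """Cα–Cα distance between the residues flanking the excised loop."""
    flank = []
    for rs in (loop.start_res - 1, loop.end_res + 1):
        r = scaffold.get_residue(loop.chain_id, rs)
        if r is None:
            raise GeometryError(
                f"flanking residue {loop.chain_id}:{rs} absent "
                f"(loop at chain terminus?)")
        ca = r.atom("CA")
        if ca is None:
            raise GeometryError(f"residue {loop.chain_id}:{rs} has no CA")
        flank.append(ca.coords)
    return float(np.linalg.norm(flank[1] - flank[0]))


def helix_span_estimate(n_res: int) -> float:
    """Axial length of an ideal α-helix of n residues: 1.5 Å rise per
    residue over n−1 steps."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    return HELIX_RISE_PER_RES * (n_res - 1)


def recommend_linkers(gap: float, donor_end_to_end: float) -> int:
    """Smallest per-side linker length n with 2·n·3.5 Å of extended reach
    covering the span mismatch plus 4 Å slack, capped at 10."""
    if gap < 0 or donor_end_to_end < 0:
        raise ValueError("distances must be >= 0")
    need = abs(donor_end_to_end - gap) + LINKER_SLACK
    n = max(0, math.ceil(need / (2 * LINKER_REACH_PER_RES)))
    if n > LINKER_CAP:
        warnings.warn(
            f"span mismatch requires {n} linker residues per side; "
            f"capping at {LINKER_CAP}", stacklevel=2)
        n = LINKER_CAP
    return n


def geometry_report(scaffold: PolymerStructure, loop: SegmentSpec,
                    donor: PolymerStructure,
                    donor_segment: SegmentSpec) -> GeometryReport:
    gap = anchor_gap(scaffold, loop)
    seg = extract_segment(donor, donor_segment)
    residues = list(seg.residues(donor_segment.chain_id))
    ca1 = residues[0].atom("CA")
    ca2 = residues[-1].atom("CA")
    if ca1 is None or ca2 is None:
        raise GeometryError("donor segment termini lack CA atoms")
    e2e = float(np.linalg.norm(ca2.coords - ca1.coords))
    return GeometryReport(
        anchor_gap=gap,
        donor_end_to_end=e2e,
        helix_span_estimate=helix_span_estimate(len(residues)),
        recommended_linker_len=recommend_linkers(gap, e2e),
    )


def build_chimera(scaffold: PolymerStructure, loop: SegmentSpec,
                  donor: PolymerStructure, donor_segment: SegmentSpec,
                  linker_n: str = "GGGGS", linker_c: str = "GGGGS",
                  scaffold_id: str = "scaffold",
                  donor_id: str = "donor") -> GraftDesign:
    """Assemble the chimera sequence and its position-by-position map back
    to scaffold/linker/donor sources."""
    for s in (linker_n, linker_c):
        bad = [c for c in s.upper() if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"invalid linker letters: {bad}")
    scaffold_res = list(scaffold.residues(loop.chain_id))
    loop_set = set(range(loop.start_res, loop.end_res + 1))
    if not loop_set <= {r.res_seq for r in scaffold_res}:
        missing = sorted(loop_set - {r.res_seq for r in scaffold_res})
        raise GeometryError(f"loop residues absent from scaffold: {missing}")
    donor_seg = extract_segment(donor, donor_segment)
    donor_res = list(donor_seg.residues(donor_segment.chain_id))

    entries: list[IndexMapEntry] = []
    seq_parts: list[str] = []
    pos = 0

    def push(letter: str, source: str, source_rs: int | None):
        nonlocal pos
        pos += 1
        seq_parts.append(letter)
        entries.append(IndexMapEntry(pos, source, source_rs))

    for r in scaffold_res:
        if r.res_seq < loop.start_res:
            push(r.one_letter, "scaffold", r.res_seq)
    for c in linker_n.upper():
        push(c, "linker", None)
    for r in donor_res:
        push(r.one_letter, "donor", r.res_seq)
    for c in linker_c.upper():
        push(c, "linker", None)
    for r in scaffold_res:
        if r.res_seq > loop.end_res:
            push(r.one_letter, "scaffold", r.res_seq)

    return GraftDesign(
        scaffold_id=scaffold_id, excised_loop=loop,
        donor_id=donor_id, donor_segment=donor_segment,
        linker_n=linker_n.upper(), linker_c=linker_c.upper(),
        chimera_sequence="".join(seq_parts), index_map=entries,
    )


# ---------------------------------------------------------------------------
# Initial model
# ---------------------------------------------------------------------------

def _clash_pairs(xyz_a: np.ndarray, labels_a, xyz_b: np.ndarray, labels_b,
                 floor: float = CLASH_DISTANCE):
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    ii, jj = np.where(d < floor)
    return [(labels_a[i], labels_b[j], float(d[i, j]))
            for i, j in zip(ii, jj)]


def _heavy_coords_labels(residues: list[Residue]):
    xyz, labels = [], []
    for r in residues:
        for a in r.heavy_atoms():
            xyz.append(a.coords)
            labels.append(f"{r.chain_id}:{r.res_seq}:{a.name}")
    return np.array(xyz), labels


def _linker_residues(sequence: str, p_start: np.ndarray, p_end: np.ndarray,
                     chain_id: str, bulge: np.ndarray,
                     avoid_xyz: np.ndarray,
                     start_res_xyz: np.ndarray | None = None,
                     end_res_xyz: np.ndarray | None = None) -> list[Residue]:
    """Crude linker layout: Cα beads on a quadratic Bézier arc from
    ``p_start`` to ``p_end``, bulging along ``bulge`` just enough that
    consecutive beads are not crowded and nothing comes within the clash
    floor of ``avoid_xyz``; approximate backbone geometry around each
    bead."""
    k = len(sequence)
    if k == 0:
        return []
    chord = p_end - p_start
    u = unit(bulge - np.dot(bulge, unit(chord)) * unit(chord)) \
        if np.linalg.norm(np.cross(bulge, chord)) > 1e-6 else None
    if u is None:
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(unit(chord), helper)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = unit(np.cross(chord, helper))
    v = unit(np.cross(unit(chord), u))
    ts = np.array([(j + 1) / (k + 1) for j in range(k)])

    def spiral(amp: float, winds: float, phase: float = 0.0) -> np.ndarray:
        """Slack-linker detour: a spiral around the chord whose envelope
        is pinned to zero at both anchors."""
        env = amp * np.sin(np.pi * ts)
        ang = 2 * np.pi * winds * ts + np.radians(phase)
        return (p_start + ts[:, None] * chord
                + env[:, None] * (np.cos(ang)[:, None] * u
                                  + np.sin(ang)[:, None] * v))

    def build(cas: np.ndarray) -> list[Residue]:
        out = []
        for j in range(k):
            ca = cas[j]
            nxt = cas[j + 1] if j + 1 < k else p_end
            prv = cas[j - 1] if j > 0 else p_start
            t = unit(nxt - prv)
            helper = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(t, helper)) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            nvec = unit(np.cross(t, helper))
            res = Residue(chain_id, j + 1,
                          ONE_TO_THREE[sequence[j].upper()])
            res.atoms = [
                AtomRecord("N", "N", ca - 0.75 * t + 0.55 * nvec),
                AtomRecord("CA", "C", ca),
                AtomRecord("C", "C", ca + 0.80 * t + 0.50 * nvec),
                AtomRecord("O", "O", ca + 0.90 * t + 1.65 * nvec),
            ]
            if res.res_name != "GLY":
                res.atoms.append(AtomRecord("CB", "C", ca - 1.00 * nvec
                                            - 0.45 * t))
            out.append(res)
        return out

    def clash_free(residues: list[Residue]) -> bool:
        coords = [np.array([a.coords for a in r.atoms]) for r in residues]

        def too_close(xyz_a, xyz_b):
            return np.linalg.norm(xyz_a[:, None] - xyz_b[None, :],
                                  axis=-1).min() < CLASH_DISTANCE

        for j in range(k):
            for j2 in range(j + 2, k):   # bonded neighbors exempt
                if too_close(coords[j], coords[j2]):
                    return False
            if avoid_xyz.size and too_close(coords[j], avoid_xyz):
                return False
            # the flanking residues are bonded to the first/last bead
            # only; every other bead must clear them too
            if (j > 0 and start_res_xyz is not None
                    and too_close(coords[j], start_res_xyz)):
                return False
            if (j < k - 1 and end_res_xyz is not None
                    and too_close(coords[j], end_res_xyz)):
                return False
        return True

    chosen = None
    for winds in (0.0, 0.5, 1.0, 1.5, 2.0, 2.5):
        for phase in (0.0, 90.0, 180.0, 270.0):
            for amp in np.arange(0.0, 10.01, 0.25):
                cand = build(spiral(amp, winds, phase))
                if clash_free(cand):
                    chosen = cand
                    break
            if chosen is not None:
                break
        if chosen is not None:
            break
    if chosen is None:
        chosen = build(spiral(4.0, 1.0))   # fall back to a plausible coil
    return chosen


def build_initial_model(design: GraftDesign, scaffold: PolymerStructure,
                        donor: PolymerStructure) -> PolymerStructure:
    """Crude clash-checked starting model of the chimera.

    Scaffold coordinates outside the excised loop are kept bit-exactly.
    The donor segment is copied as a rigid body: its termini axis is
    aligned with the anchor axis, its termini midpoint is set on the
    anchor midpoint displaced outward along the loop normal, and the
    rigid body is rotated about the anchor axis in 10° steps until a
    clash-free pose is found (first hit wins).  Linkers are laid out with
    crude extended geometry between each anchor and the nearer donor
    terminus.  Chimera residues are renumbered sequentially from 1 on
    chain 'A'; source numbering is recoverable through the index map.
    """
    loop = design.excised_loop
    identity_graft = (
        not design.linker_n and not design.linker_c
        and donor is scaffold
        and design.donor_segment == loop
    )
    scaffold_res = list(scaffold.residues(loop.chain_id))
    before = [r for r in scaffold_res if r.res_seq < loop.start_res]
    after = [r for r in scaffold_res if r.res_seq > loop.end_res]
    if identity_graft:
        kept = (before
                + [r for r in scaffold_res
                   if loop.start_res <= r.res_seq <= loop.end_res]
                + after)
        placed_donor = []
        linkers_n = linkers_c = []
    else:
        kept = before + after
        donor_seg = extract_segment(donor, design.donor_segment)
        donor_res = [r.copy()
                     for r in donor_seg.residues(design.donor_segment.chain_id)]
        for r in (before[-1] if before else None,
                  after[0] if after else None):
            if r is None or r.atom("CA") is None:
                raise GeometryError(
                    "anchor residues with CA are required on both sides "
                    "of the excised loop")
        a1 = before[-1].atom("CA").coords
        a2 = after[0].atom("CA").coords
        axis = unit(a2 - a1)
        mid = 0.5 * (a1 + a2)
        ca_all = np.array([r.atom("CA").coords for r in scaffold_res
                           if r.atom("CA") is not None])
        centroid = ca_all.mean(axis=0)
        normal = mid - centroid
        normal = normal - np.dot(normal, axis) * axis
        if np.linalg.norm(normal) < 1e-6:
            normal = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        normal = unit(normal)

        d1 = donor_res[0].atom("CA")
        d2 = donor_res[-1].atom("CA")
        if d1 is None or d2 is None:
            raise GeometryError("donor segment termini lack CA atoms")
        donor_xyz = np.array([a.coords for r in donor_res for a in r.atoms])
        dmid = 0.5 * (d1.coords + d2.coords)
        R0 = rotation_aligning(d2.coords - d1.coords, axis)
        base = (donor_xyz - dmid) @ R0.T

        kept_xyz, kept_labels = _heavy_coords_labels(kept)
        donor_labels = [f"donor:{r.res_seq}:{a.name}" for r in donor_res
                        for a in r.atoms if a.element.upper() != "H"]
        heavy_rows = [k for k, (r, a) in enumerate(
            [(r, a) for r in donor_res for a in r.atoms])
            if a.element.upper() != "H"]

        # placement search: outward standoffs in order, 10° rotations
        # about the anchor axis; the first clash-free pose wins
        chosen = None
        best_pairs = None
        for standoff in PLACEMENT_STANDOFFS:
            target_mid = mid + standoff * normal
            for step in range(36):
                R = rotation_about_axis(axis, 10.0 * step)
                cand = base @ R.T + target_mid
                pairs = _clash_pairs(cand[heavy_rows], donor_labels,
                                     kept_xyz, kept_labels)
                if not pairs:
                    chosen = cand
                    break
                if best_pairs is None or len(pairs) < len(best_pairs):
                    best_pairs = pairs
            if chosen is not None:
                break
        if chosen is None:
            raise ClashError(best_pairs)
        k = 0
        for r in donor_res:
            for a in r.atoms:
                a.coords = chosen[k].copy()
                k += 1
        placed_donor = donor_res
        side = unit(np.cross(normal, axis))

        def heavy_except(residues, skip):
            skip_ids = {id(r) for r in skip}
            return np.array([a.coords for r in residues
                             if id(r) not in skip_ids
                             for a in r.heavy_atoms()]).reshape(-1, 3)

        # bonded-neighbor residues of each linker are exempt from its
        # clearance search (they are covalently attached)
        def res_xyz(r):
            return np.array([a.coords for a in r.heavy_atoms()])

        avoid_n = np.vstack([
            heavy_except(kept, [before[-1]]),
            heavy_except(placed_donor, [placed_donor[0]])])
        linkers_n = _linker_residues(
            design.linker_n, a1,
            placed_donor[0].atom("CA").coords, loop.chain_id,
            bulge=side, avoid_xyz=avoid_n,
            start_res_xyz=res_xyz(before[-1]),
            end_res_xyz=res_xyz(placed_donor[0]))
        avoid_c = np.vstack([
            heavy_except(kept, [after[0]]),
            heavy_except(placed_donor, [placed_donor[-1]]),
            heavy_except(linkers_n, [])])
        linkers_c = _linker_residues(
            design.linker_c, placed_donor[-1].atom("CA").coords,
            a2, loop.chain_id, bulge=-side, avoid_xyz=avoid_c,
            start_res_xyz=res_xyz(placed_donor[-1]),
            end_res_xyz=res_xyz(after[0]))

    ordered = (before + linkers_n + placed_donor + linkers_c + after
               if not identity_graft else kept)
    out_res = []
    for newpos, r in enumerate(ordered, start=1):
        rr = r.copy()
        rr.chain_id = "A"
        rr.res_seq = newpos
        out_res.append(rr)
    model = PolymerStructure({"A": out_res},
                             title=f"initial model {design.scaffold_id}"
                                   f"+{design.donor_id}")
    if len(out_res) != len(design.chimera_sequence):
        raise GeometryError(
            f"model residue count {len(out_res)} does not match chimera "
            f"sequence length {len(design.chimera_sequence)}")
    return model


def mutate_to_alanine(s: PolymerStructure, positions: list[int],
                      chain_id: str | None = None) -> PolymerStructure:
    """Truncate the listed residues to alanine (side chain cut at CB).

    Backbone atoms are never touched; glycines gain no atoms and are left
    unchanged (with a warning).  Idempotent on alanines.
    """
    out = s.copy()
    cid = chain_id or out.chain_ids[0]
    present = {r.res_seq for r in out.residues(cid)}
    absent = [p for p in positions if p not in present]
    if absent:
        raise KeyError(f"positions not in chain {cid!r}: {absent}")
    for r in out.residues(cid):
        if r.res_seq not in positions:
            continue
        if r.res_name == "GLY":
            warnings.warn(
                f"residue {cid}:{r.res_seq} is glycine; alanine "
                "truncation leaves it unchanged", stacklevel=2)
            continue
        r.res_name = "ALA"
        r.atoms = [a for a in r.atoms if a.name in ALA_KEEP_ATOMS]
    return out
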