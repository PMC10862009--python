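"""Hydrogen-bond-based α-helix assignment and helicity statistics.

The assignment follows the Kabsch–Sander electrostatic model that
underlies DSSP: a backbone N-H···O=C hydrogen bond is scored as

    E = 27.888 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol, r in Å]

and counted as a bond when E < -0.5 kcal/mol.  A "4-turn" at residue i is
a bond from the C=O of i to the N-H of i+4; residues i+1..i+4 are labeled
α-helical (H) when 4-turns exist at both i and i+1.  Only the two-class
alphabet {H, C} is produced — every statistic of interest here is
"fraction of residues in α-helical conformation".

Amide hydrogens are placed geometrically (1.0 Å from N along the
preceding C=O direction) so structures without hydrogens — crystal
structures, stripped trajectories — are handled identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord, Ensemble, PolymerStructure, SegmentSpec

__all__ = [
    "KS_COUPLING",
    "KS_CUTOFF",
    "place_amide_hydrogens",
    "ensemble_with_amide_hydrogens",
    "add_amide_hydrogens",
    "ks_energy",
    "assign_helix",
    "SSAssignment",
    "helical_fraction",
    "HelicityReport",
]

KS_COUPLING = 27.888   # q1*q2*332, kcal·Å/mol
KS_CUTOFF = -0.5       # kcal/mol; bond iff E below this
KS_E_MIN = -9.9        # clamp floor, as in the original algorithm
_MIN_DIST = 0.5        # Å; closer pairs return +inf (overlapping atoms)
_NH_BOND = 1.0         # Å


def _backbone_arrays(topology: PolymerStructure, chain_id: str,
                     frames: np.ndarray):
    """Per-chain backbone coordinates (F, n_res, 3) per atom type, with a
    mask of residues that have a complete backbone."""
    residues = list(topology.residues(chain_id))
    idx = topology.atom_index()
    n = len(residues)
    F = frames.shape[0]
    out = {}
    ok = np.ones(n, dtype=bool)
    for name in ("N", "CA", "C", "O"):
        arr = np.full((F, n, 3), np.nan)
        for j, r in enumerate(residues):
            key = (chain_id, r.res_seq, name)
            if key in idx:
                arr[:, j] = frames[:, idx[key]]
            else:
                ok[j] = False
        out[name] = arr
    return residues, out, ok


def place_amide_hydrogens(frames: np.ndarray, topology: PolymerStructure,
                          chain_id: str | None = None):
    """Geometric amide-H positions for every frame.

    H_i = N_i + 1.0 Å * unit(C_{i-1} - O_{i-1}); prolines and chain-start
    residues get no hydrogen.  ``frames`` is (F, n_atoms, 3) (a single
    (n_atoms, 3) frame is promoted).  Returns ``(H, has_h)`` with H of
    shape (F, n_res, 3) and NaN where no hydrogen is placed.
    """
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    if chain_id is None:
        chain_id = topology.chain_ids[0]
    residues, bb, ok = _backbone_arrays(topology, chain_id, frames)
    n = len(residues)
    H = np.full((frames.shape[0], n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for j in range(1, n):
        if residues[j].res_name == "PRO":
            continue
        if not (ok[j - 1] and ok[j]):
            continue
        co = bb["C"][:, j - 1] - bb["O"][:, j - 1]
        norm = np.linalg.norm(co, axis=-1, keepdims=True)
        H[:, j] = bb["N"][:, j] + _NH_BOND * co / norm
        has_h[j] = True
    if single:
        return H[0], has_h
    return H, has_h


def ks_energy(r_on, r_ch, r_oh, r_cn):
    """Kabsch–Sander energy from the four heavy-atom/H distances (Å).

    Vectorized; returns kcal/mol, clamped below at -9.9, +inf when any
    distance is under 0.5 Å.
    """
    r_on, r_ch, r_oh, r_cn = (np.asarray(x, dtype=float)
                              for x in (r_on, r_ch, r_oh, r_cn))
    with np.errstate(divide="ignore"):
        e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    bad = ((r_on < _MIN_DIST) | (r_ch < _MIN_DIST)
           | (r_oh < _MIN_DIST) | (r_cn < _MIN_DIST))
    e = np.where(bad, np.inf, np.maximum(e, KS_E_MIN))
    return e if e.shape else float(e)


def ks_energy_pair(donor_res, acceptor_res, h_coords=None) -> float:
    """Energy of the bond donor N-H ··· acceptor C=O for two residues of a
    single-conformer structure.  ``h_coords`` overrides the donor H (it is
    placed geometrically by callers that have the chain context)."""
    n = donor_res.atom("N")
    h = donor_res.atom("H")
    c = acceptor_res.atom("C")
    o = acceptor_res.atom("O")
    if n is None or c is None or o is None or (h is None and h_coords is None):
        raise ValueError("missing backbone atoms for Kabsch-Sander energy")
    hx = h_coords if h_coords is not None else h.coords
    d = np.linalg.norm
    return ks_energy(d(o.coords - n.coords), d(c.coords - hx),
                     d(o.coords - hx), d(c.coords - n.coords))


def ensemble_with_amide_hydrogens(ens: Ensemble) -> Ensemble:
    """A copy of the ensemble with geometric amide hydrogens inserted
    (after N) in every eligible residue that lacks one, in all frames."""
    topo = ens.topology
    frames = np.stack(ens.frames)
    h_by_chain = {}
    for cid in topo.chain_ids:
        h_by_chain[cid] = place_amide_hydrogens(frames, topo, cid)

    new_topo = topo.copy()
    cols: list[tuple[str, int]] = []   # (kind, index) kind: atom col | H col
    flat = 0
    for cid in new_topo.chain_ids:
        H, has_h = h_by_chain[cid]
        for j, res in enumerate(new_topo.chains[cid]):
            insert_h = has_h[j] and res.atom("H") is None
            new_atoms = []
            for a in res.atoms:
                new_atoms.append(a)
                cols.append(("x", flat))
                flat += 1
                if insert_h and a.name == "N":
                    new_atoms.append(AtomRecord("H", "H", H[0, j]))
                    cols.append(("h", (cid, j)))
            res.atoms = new_atoms

    F = frames.shape[0]
    out = np.empty((F, len(cols), 3))
    for k, (kind, ref) in enumerate(cols):
        if kind == "x":
            out[:, k] = frames[:, ref]
        else:
            cid, j = ref
            out[:, k] = h_by_chain[cid][0][:, j]
    return Ensemble(new_topo, list(out),
                    frame_spacing_ps=ens.frame_spacing_ps,
                    replicate_id=ens.replicate_id)


def add_amide_hydrogens(s: PolymerStructure) -> PolymerStructure:
    """Structure-level convenience wrapper of
    :func:`ensemble_with_amide_hydrogens`."""
    return ensemble_with_amide_hydrogens(Ensemble(s, [s.coords()])).topology


@dataclass
class SSAssignment:
    """Per-frame, per-residue code in {H, C} for one chain."""

    chain_id: str
    res_seqs: list[int]
    codes: np.ndarray          # (F, n_res) of 'H'/'C'
    turn_energies: np.ndarray  # (F, n_res) energy of the 4-turn at i, +inf if none

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    def is_helix(self) -> np.ndarray:
        return self.codes == "H"


def assign_helix(ens: Ensemble | PolymerStructure,
                 chain_id: str | None = None) -> SSAssignment:
    """Assign α-helix (H) vs other (C) per residue per frame.

    Hydrogens are placed geometrically first; residues with missing
    backbone atoms are un-assignable and stay C.
    """
    if isinstance(ens, PolymerStructure):
        ens = Ensemble(ens, [ens.coords()])
    topo = ens.topology
    if chain_id is None:
        chain_id = topo.chain_ids[0]
    frames = np.stack(ens.frames)
    residues, bb, ok = _backbone_arrays(topo, chain_id, frames)
    n = len(residues)
    F = frames.shape[0]
    H, has_h = place_amide_hydrogens(frames, topo, chain_id)

    codes = np.full((F, n), "C", dtype="<U1")
    turn_e = np.full((F, n), np.inf)
    if n >= 5:
        # 4-turn at i: donor N-H of i+4, acceptor C=O of i
        acc = np.arange(0, n - 4)
        don = acc + 4
        usable = ok[acc] & ok[don] & has_h[don]
        if usable.any():
            a = acc[usable]
            d = don[usable]
            dist = lambda p, q: np.linalg.norm(p - q, axis=-1)
            e = ks_energy(
                dist(bb["O"][:, a], bb["N"][:, d]),
                dist(bb["C"][:, a], H[:, d]),
                dist(bb["O"][:, a], H[:, d]),
                dist(bb["C"][:, a], bb["N"][:, d]),
            )
            turn_e[:, a] = e
        turn = turn_e[:, : n - 4] < KS_CUTOFF          # (F, n-4)
        both = turn[:, :-1] & turn[:, 1:]              # turns at i and i+1
        helix = np.zeros((F, n), dtype=bool)
        for i in range(both.shape[1]):
            helix[:, i + 1:i + 5] |= both[:, i:i + 1]
        codes[helix] = "H"
    return SSAssignment(chain_id, [r.res_seq for r in residues],
                        codes, turn_e)


@dataclass
class HelicityReport:
    """Replicate-averaged helical fraction over a segment's interior."""

    segment: SegmentSpec
    exclude_terminal: int
    per_replicate_fraction: list[float]
    mean: float
    std: float
    # alternative per-residue-then-average reading, reported side by side
    per_replicate_fraction_residue_mean: list[float]
    per_residue_mean: dict[int, float] = field(default_factory=dict)

    def summary(self) -> str:
        pct = ", ".join(f"{f * 100:.1f}%" for f in self.per_replicate_fraction)
        return (
            f"helical fraction over {self.segment} "
            f"(interior, -{self.exclude_terminal}/terminus): "
            f"{self.mean * 100:.1f}% (±{self.std * 100:.1f}%) "
            f"[replicates: {pct}]"
        )


def helical_fraction(ensembles: list[Ensemble] | Ensemble,
                     segment: SegmentSpec,
                     exclude_terminal: int = 2,
                     stride: int = 1) -> HelicityReport:
    """The '% of residues in α-helical conformation' statistic.

    Per replicate the fraction is the occupancy average: H-labeled
    (frame, residue) pairs over frames x interior segment residues.
    Mean and std (sample, n-1) are taken across replicates.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if not ensembles:
        raise ValueError("at least one ensemble required")
    interior = segment.interior(exclude_terminal)

    fractions = []
    fractions_resmean = []
    per_residue_acc: dict[int, list[float]] = {}
    for ens in ensembles:
        sub = Ensemble(ens.topology, ens.frames[::stride],
                       frame_spacing_ps=ens.frame_spacing_ps * stride,
                       replicate_id=ens.replicate_id)
        ss = assign_helix(sub, chain_id=segment.chain_id)
        cols = [j for j, rs in enumerate(ss.res_seqs)
                if interior.start_res <= rs <= interior.end_res]
        if len(cols) != interior.n_residues:
            missing = sorted(set(range(interior.start_res,
                                       interior.end_res + 1))
                             - {ss.res_seqs[j] for j in cols})
            raise ValueError(f"segment residues missing in topology: {missing}")
        hel = ss.is_helix()[:, cols]
        fractions.append(float(hel.mean()))
        per_res = hel.mean(axis=0)
        fractions_resmean.append(float(per_res.mean()))
        for j, c in enumerate(cols):
            per_residue_acc.setdefault(ss.res_seqs[c], []).append(
                float(per_res[j]))

    arr = np.array(fractions)
    std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return HelicityReport(
        segment=segment,
        exclude_terminal=exclude_terminal,
        per_replicate_fraction=fractions,
        mean=float(arr.mean()),
        std=std,
        per_replicate_fraction_residue_mean=fractions_resmean,
        per_residue_mean={k: float(np.mean(v))
                          for k, v in per_residue_acc.items()},
    )
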