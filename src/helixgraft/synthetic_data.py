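"""Synthetic fixtures with known ground truth.

This module generates every input the analysis operators need, at desk
scale and with the answers known by construction:

* ideal-geometry α-helices and extended chains built from internal
  coordinates (NeRF), used as unambiguous positive/negative controls for
  the hydrogen-bond helix assignment;
* a deterministic two-helix hairpin scaffold with an excisable VVAG loop,
  the graft-construction test bed;
* a two-helix bundle with three planted aromatic anchors facing the
  partner helix, the planted-signal fixture for interaction-energy
  ranking and alanine-truncation experiments;
* replicate helix-fraying trajectories whose per-residue helix/coil
  states follow a two-state Zimm–Bragg chain sampled by Gibbs sweeps,
  with the propagation weight calibrated by bisection against the exact
  transfer-matrix equilibrium so the observable helicity hits a target;
* HDX-MS uptake tables generated from per-residue exchange kinetics
  with a planted, binder-protected epitope.

All generators are seed-deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import place_atom, rotation_about_axis, unit
from .structure_io import (
    ONE_TO_THREE,
    AtomRecord,
    Ensemble,
    PolymerStructure,
    Residue,
    SegmentSpec,
)

__all__ = [
    "FrayConfig",
    "HDXSimConfig",
    "build_backbone",
    "build_ideal_helix",
    "build_extended_chain",
    "build_toy_scaffold",
    "build_two_helix_bundle",
    "TOY_SCAFFOLD_LOOP",
    "zb_mean_helicity",
    "zb_expected_visible_fraction",
    "calibrate_propagation_weight",
    "dssp_visible",
    "simulate_fray",
    "FrayGroundTruth",
    "simulate_hdx",
]

# ideal backbone geometry (lengths Å, angles degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O, A_N_CA_CB = (
    111.2, 116.2, 121.7, 120.8, 110.4)
# improper torsion C-N-CA-CB giving L-chirality (matches CCD alanine)
T_CB = -120.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0

# gamma heavy atom used for the crude side-chain stub, by residue type
GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
}
_GAMMA_BOND = {"OG": 1.42, "OG1": 1.42, "SG": 1.82}


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

def build_backbone(sequence: str, phi, psi,
                   include_cb: bool = True,
                   side_chain_stubs: bool = False,
                   chain_id: str = "A",
                   start_res: int = 1):
    """Build polypeptide coordinates from per-residue (φ, ψ) torsions.

    ``phi``/``psi`` have shape ``(n,)`` for a single conformer or
    ``(F, n)`` for a batch of frames; ω is fixed at 180°.  Returns
    ``(topology, coords)`` where ``coords`` has shape
    ``(n_atoms, 3)`` or ``(F, n_atoms, 3)`` in topology atom order.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 1:
        raise ValueError("sequence must be non-empty")
    bad = [c for c in seq if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"invalid residue letters: {bad}")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    batched = phi.ndim == 2
    if phi.shape != psi.shape or phi.shape[-1] != n:
        raise ValueError("phi/psi must both have trailing length len(sequence)")
    lead = phi.shape[:-1]

    def bc(vec):  # broadcast a constant point over the leading dims
        return np.broadcast_to(np.asarray(vec, dtype=float),
                               lead + (3,)).copy()

    N = [bc([0.0, 0.0, 0.0])]
    CA = [bc([B_N_CA, 0.0, 0.0])]
    th = np.radians(180.0 - A_N_CA_C)
    C = [CA[0] + B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])]

    for i in range(1, n):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1],
                            B_C_N, A_CA_C_N, psi[..., i - 1]))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i],
                             B_N_CA, A_C_N_CA, 180.0))
        C.append(place_atom(C[i - 1], N[i], CA[i],
                            B_CA_C, A_N_CA_C, phi[..., i]))
    O = [place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi[..., i] + 180.0)
         for i in range(n)]
    CB = {}
    G = {}
    for i, letter in enumerate(seq):
        res_name = ONE_TO_THREE[letter]
        if include_cb and res_name != "GLY":
            CB[i] = place_atom(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, T_CB)
            gname = GAMMA_ATOM.get(res_name)
            if side_chain_stubs and gname is not None:
                gb = _GAMMA_BOND.get(gname, 1.52)
                # extend along CA->CB: a crude, deterministic stub
                G[i] = CB[i] + gb * unit(CB[i] - CA[i])

    chains: dict[str, list[Residue]] = {chain_id: []}
    coords = []
    for i, letter in enumerate(seq):
        res_name = ONE_TO_THREE[letter]
        res = Residue(chain_id, start_res + i, res_name)
        per_atom = [("N", "N", N[i]), ("CA", "C", CA[i]),
                    ("C", "C", C[i]), ("O", "O", O[i])]
        if i in CB:
            per_atom.append(("CB", "C", CB[i]))
        if i in G:
            gname = GAMMA_ATOM[res_name]
            per_atom.append((gname, gname[0], G[i]))
        for name, elem, xyz in per_atom:
            first = xyz[(0,) * len(lead)] if batched else xyz
            res.atoms.append(AtomRecord(name, elem, np.asarray(first)))
            coords.append(xyz)
        chains[chain_id].append(res)

    topo = PolymerStructure(chains)
    stacked = np.stack(coords, axis=-2)  # (..., n_atoms, 3)
    return topo, stacked


def build_ideal_helix(sequence: str, chain_id: str = "A",
                      start_res: int = 1,
                      side_chain_stubs: bool = False) -> PolymerStructure:
    """Canonical α-helix: 1.5 Å rise and ~100°/residue twist, Cα radius
    ~2.3 Å, from ideal bond geometry with φ=-57°, ψ=-47°."""
    n = len(sequence)
    phi = np.full(n, HELIX_PHI)
    psi = np.full(n, HELIX_PSI)
    topo, xyz = build_backbone(sequence, phi, psi, chain_id=chain_id,
                               start_res=start_res,
                               side_chain_stubs=side_chain_stubs)
    topo.set_coords(xyz)
    topo.title = f"ideal helix {sequence}"
    return topo


def build_extended_chain(sequence: str, chain_id: str = "A",
                         start_res: int = 1) -> PolymerStructure:
    """Fully extended chain (φ=ψ=180°): the zero-helicity control."""
    n = len(sequence)
    topo, xyz = build_backbone(sequence, np.full(n, 180.0), np.full(n, 180.0),
                               chain_id=chain_id, start_res=start_res)
    topo.set_coords(xyz)
    topo.title = f"extended chain {sequence}"
    return topo


# ---------------------------------------------------------------------------
# Toy scaffold & two-helix bundle
# ---------------------------------------------------------------------------

TOY_SCAFFOLD_SEQ_H1 = "AEELKKLAEELKKLAEE"   # residues 30-46
TOY_SCAFFOLD_SEQ_LOOP = "VVAG"               # residues 47-50 (excisable)
TOY_SCAFFOLD_SEQ_H2 = "LKKIAEELKKLAEELKK"   # residues 51-67
TOY_SCAFFOLD_LOOP = SegmentSpec("A", 47, 50)

# hand-tuned hairpin-turn torsions for the 4-residue loop; chosen so the
# two helices run antiparallel (axis dot ~ -0.89), the Cα anchor gap
# across the excised loop is ~10.27 Å and no heavy-atom pair comes
# closer than ~3.1 Å
_TOY_LOOP_TORSIONS = [(-41.0, -175.0), (-45.0, -121.0), (-93.0, 105.0),
                      (-114.0, 42.0)]


def build_toy_scaffold() -> PolymerStructure:
    """Deterministic 38-residue two-helix hairpin, numbered 30–67, with an
    excisable VVAG loop at 47–50 — a miniature stand-in for a loop-bearing
    display scaffold.  Regenerating it is bit-identical."""
    seq = TOY_SCAFFOLD_SEQ_H1 + TOY_SCAFFOLD_SEQ_LOOP + TOY_SCAFFOLD_SEQ_H2
    n = len(seq)
    phi = np.full(n, HELIX_PHI)
    psi = np.full(n, HELIX_PSI)
    off = len(TOY_SCAFFOLD_SEQ_H1)
    for k, (p, q) in enumerate(_TOY_LOOP_TORSIONS):
        phi[off + k] = p
        psi[off + k] = q
    topo, xyz = build_backbone(seq, phi, psi, start_res=30)
    topo.set_coords(xyz)
    topo.title = "toy two-helix scaffold"
    return topo


BUNDLE_HELIX_A = SegmentSpec("A", 1, 17)
BUNDLE_HELIX_B = SegmentSpec("A", 21, 53)
BUNDLE_ANCHORS = (4, 8, 11)   # Trp, Trp, Tyr facing helix B

# (atom name, partial charge it carries in the parameter table, energy the
# placement aims for): the positively charged ring atoms of Trp/Tyr are
# the contact tips
_BUNDLE_TIPS = {
    "TRP": (("CD1", 0.22, -3.5), ("CE2", 0.24, -3.5)),
    "TYR": (("CZ", 0.40, -7.0), ("CE1", 0.0, -1.0)),
}
_BUNDLE_TERMINAL_CLEAR = 12.5   # Å; keeps tips outside cutoff range of the
                                # (monopole-bearing) chain-terminal residues


def _bundle_b_atoms(res_b):
    """(q, eps, rmin/2, xyz, residue index) of helix-B heavy atoms plus
    geometric amide hydrogens — what the tips will actually interact
    with."""
    from .forcefield import default_params
    P = default_params()
    out = []
    for j, rb in enumerate(res_b):
        for a in rb.atoms:
            p = P.get(rb.res_name, a.name)
            out.append((p.partial_charge, p.lj_epsilon, p.lj_rmin_half,
                        a.coords, j))
        if j > 0:
            prev = res_b[j - 1]
            h = rb.atom("N").coords + unit(prev.atom("C").coords
                                           - prev.atom("O").coords)
            ph = P.get(rb.res_name, "H")
            out.append((ph.partial_charge, ph.lj_epsilon, ph.lj_rmin_half,
                        h, j))
    return out


def build_two_helix_bundle(separation: float = 21.0) -> PolymerStructure:
    """Two antiparallel ideal helices on one chain (A: 1–17, B: 21–53)
    with three aromatic anchors (Trp4, Trp8, Tyr11) planted on helix A.

    This is an abstract planted-signal fixture, not a packed coiled coil:
    the helices sit far enough apart that every backbone–backbone atom
    pair is beyond the 12 Å interaction cutoff, and the anchors' charged
    ring atoms (CD1/CE2 of Trp, CZ of Tyr) are placed as long reaching
    tips at favorable Coulomb distance from backbone carbonyls of helix
    B, each tip splitting its interaction over two carbonyls of distinct
    residues.  By construction the three anchors are then the dominant
    inter-helix contributors, and truncating them to alanine removes the
    tips and with them essentially the whole cross-helix energy — the
    computational analogue of a stabilizing-aromatics triple-alanine
    mutant.  Deterministic; regeneration is bit-identical.
    """
    seq_a = list("A" * 17)
    for pos, aa in zip(BUNDLE_ANCHORS, "WWY"):
        seq_a[pos - 1] = aa
    hel_a = build_ideal_helix("".join(seq_a), start_res=1,
                              side_chain_stubs=True)
    n_b = BUNDLE_HELIX_B.n_residues
    hel_b = build_ideal_helix("A" * n_b, start_res=21,
                              side_chain_stubs=True)

    res_a = list(hel_a.residues("A"))
    ca = np.array([r.atom("CA").coords for r in res_a])
    axis = unit(ca[-1] - ca[0])
    dirs = []
    for pos in BUNDLE_ANCHORS:
        r = res_a[pos - 1]
        v = r.atom("CB").coords - r.atom("CA").coords
        v = v - np.dot(v, axis) * axis
        dirs.append(unit(v))
    face = unit(np.mean(dirs, axis=0)
                - np.dot(np.mean(dirs, axis=0), axis) * axis)

    xyz_b = hel_b.coords()
    cent = xyz_b.mean(axis=0)
    flip = rotation_about_axis(face, 180.0)     # antiparallel
    xyz_b = (xyz_b - cent) @ flip.T + cent + separation * face
    rows_ca = [k for k, (r, a) in enumerate(
        [(r, a) for r in hel_b.residues("A") for a in r.atoms])
        if a.name == "CA"]
    delta = ca.mean(axis=0) - xyz_b[rows_ca].mean(axis=0)
    xyz_b = xyz_b + np.dot(delta, axis) * axis
    hel_b.set_coords(xyz_b)
    res_b = list(hel_b.residues("A"))

    atoms_b = _bundle_b_atoms(res_b)
    qb = np.array([t[0] for t in atoms_b])
    eb = np.array([t[1] for t in atoms_b])
    rb2 = np.array([t[2] for t in atoms_b])
    xb = np.array([t[3] for t in atoms_b])
    res_of_atom = np.array([t[4] for t in atoms_b])
    term_xyz = np.array([a.coords for r in (res_b[0], res_b[-1])
                         for a in r.atoms])
    ca_b = np.array([r.atom("CA").coords for r in res_b])
    axis_b = unit(ca_b[-1] - ca_b[0])
    cb0 = ca_b.mean(axis=0)

    def tip_energies(tips: np.ndarray, q: float) -> np.ndarray:
        # mirrors the pair-energy convention, including the 12 Å
        # atom-pair truncation, so placement targets the energies the
        # matrix will actually report
        d = np.linalg.norm(tips[:, None, :] - xb[None, :, :], axis=-1)
        coul = 332.0636 * q * qb[None, :] / d
        eps = np.sqrt(0.07 * eb)[None, :]
        rmin = (1.99 + rb2)[None, :]
        x6 = (rmin / d) ** 6
        e = coul + eps * (x6 * x6 - 2 * x6)
        return np.where(d <= 12.0, e, 0.0).sum(axis=1)

    n_res_b = len(res_b)

    def tip_residue_vector(tip: np.ndarray, q: float) -> np.ndarray:
        """Per-B-residue energy breakdown of one tip (12 Å truncation)."""
        d = np.linalg.norm(tip[None, :] - xb, axis=-1)
        coul = 332.0636 * q * qb / d
        eps = np.sqrt(0.07 * eb)
        rmin = 1.99 + rb2
        x6 = (rmin / d) ** 6
        e = np.where(d <= 12.0, coul + eps * (x6 * x6 - 2 * x6), 0.0)
        return np.bincount(res_of_atom, weights=e, minlength=n_res_b)

    used_res: set[int] = set()
    placed: list[np.ndarray] = []
    accum = np.zeros(n_res_b)       # running per-B-residue energy
    h_grid = np.arange(2.6, 6.01, 0.1)
    tilt_grid = [-30.0, -15.0, 0.0, 15.0, 30.0]
    # no helix-B residue may end up more stabilizing than this, so the
    # planted anchors stay the top-ranked contributors by a clear margin
    accum_floor = -5.5

    for pos in BUNDLE_ANCHORS:
        r = res_a[pos - 1]
        cb = r.atom("CB").coords
        for name, q, target in _BUNDLE_TIPS[r.res_name]:
            # candidate carbonyl pairs one helix turn apart, unused
            # residues only, far from both chain termini
            pairs = []
            for j in range(1, len(res_b) - 5):
                for k in (3, 4):
                    ja, jb = res_b[j].res_seq, res_b[j + k].res_seq
                    if ja in used_res or jb in used_res:
                        continue
                    mid = 0.5 * (res_b[j].atom("O").coords
                                 + res_b[j + k].atom("O").coords)
                    if np.min(np.linalg.norm(term_xyz - mid, axis=1)) \
                            < _BUNDLE_TERMINAL_CLEAR:
                        continue
                    pairs.append((float(np.linalg.norm(mid - cb)),
                                  j, k, mid))
            pairs.sort(key=lambda t: t[0])
            cands = []
            for _, j, k, mid in pairs[:6]:
                z0 = mid - cb0
                z0 = unit(z0 - np.dot(z0, axis_b) * axis_b)
                wv = unit(np.cross(axis_b, z0))
                for ta in tilt_grid:
                    for tb in tilt_grid:
                        z = rotation_about_axis(axis_b, ta) @ z0
                        z = rotation_about_axis(wv, tb) @ z
                        tips = mid[None, :] + h_grid[:, None] * z[None, :]
                        clear = np.min(np.linalg.norm(
                            tips[:, None, :] - xb[None, :, :], axis=-1),
                            axis=1)
                        if placed:
                            pc = np.min(np.linalg.norm(
                                tips[:, None, :]
                                - np.array(placed)[None, :, :], axis=-1),
                                axis=1)
                            clear = np.minimum(clear, pc)
                        ok = clear >= 3.0
                        if not ok.any():
                            continue
                        e = tip_energies(tips[ok], q)
                        score = np.abs(e - target)
                        i = int(np.argmin(score))
                        cands.append((float(score[i]), tips[ok][i], j, k))
            cands.sort(key=lambda t: t[0])
            chosen = None
            for score, tip, j, k in cands:
                vec = tip_residue_vector(tip, q)
                if np.min(accum + vec) >= accum_floor:
                    chosen = (tip, j, k, vec)
                    break
            if chosen is None:
                raise RuntimeError("bundle tip placement failed")
            tip, j, k, vec = chosen
            accum += vec
            used_res.update({res_b[j].res_seq, res_b[j + k].res_seq})
            placed.append(tip)
            r.atoms.append(AtomRecord(name, "C", tip))

    chains = {"A": [r.copy() for r in res_a] + [r.copy() for r in res_b]}
    return PolymerStructure(chains,
                            title="two-helix bundle, planted anchors")


# ---------------------------------------------------------------------------
# Zimm–Bragg helix-coil machinery
# ---------------------------------------------------------------------------

def _zb_transfer(s: float, sigma: float) -> np.ndarray:
    """Transfer matrix T[prev, cur] over states (0=coil, 1=helix):
    a helix site carries weight s, starting a new helix run costs σ."""
    return np.array([[1.0, s * sigma], [1.0, s]])


def _zb_forward_backward(n: int, s: float, sigma: float):
    T = _zb_transfer(s, sigma)
    v0 = np.array([1.0, s * sigma])
    fwd = np.empty((n, 2))
    fwd[0] = v0
    for i in range(1, n):
        fwd[i] = fwd[i - 1] @ T
        fwd[i] /= fwd[i].sum()  # rescale; only ratios matter
    bwd = np.empty((n, 2))
    bwd[n - 1] = 1.0
    for i in range(n - 2, -1, -1):
        bwd[i] = T @ bwd[i + 1]
        bwd[i] /= bwd[i].sum()
    return T, v0, fwd, bwd


def zb_mean_helicity(n: int, s: float, sigma: float) -> float:
    """Exact equilibrium ⟨fraction of helix sites⟩ of the n-site chain."""
    _, _, fwd, bwd = _zb_forward_backward(n, s, sigma)
    p = fwd * bwd
    p = p / p.sum(axis=1, keepdims=True)
    return float(np.mean(p[:, 1]))


def _zb_prob_run_all_h(a: int, b: int, n: int, s: float, sigma: float) -> float:
    """Exact P(states a..b inclusive are all helix), 0-based indices."""
    T = _zb_transfer(s, sigma)
    v = np.array([1.0, s * sigma])
    logz_scale = 0.0
    vc = v.copy()
    for i in range(1, n):
        vc = vc @ T
        m = vc.sum()
        vc /= m
        logz_scale += np.log(m)
    z_full = np.log(vc.sum()) + logz_scale

    # constrained pass: at sites a..b only the helix state is allowed
    mask = np.array([0.0, 1.0])
    vc = v * (mask if a == 0 else 1.0)
    logs = 0.0
    for i in range(1, n):
        vc = vc @ T
        if a <= i <= b:
            vc = vc * mask
        m = vc.sum()
        if m == 0.0:
            return 0.0
        vc /= m
        logs += np.log(m)
    z_con = np.log(vc.sum()) + logs
    return float(np.exp(z_con - z_full))


# How the latent states print through to the hydrogen-bond assignment:
# the C=O(i)···H-N(i+4) 4-turn forms in the coordinate realization iff
# latent states i+1..i+3 are all helix.  ψ_i rotates O_i and the whole
# downstream chain rigidly together about the CA_i-C_i axis, so state i
# itself does not matter; φ of i+4 never enters the H position.  Two
# consecutive turns then label i+1..i+4, so a latent helix run is visible
# exactly where a 4-long all-helix window [k, k+3] with 1 <= k <= n-5
# covers the residue.
TURN_SPAN = (1, 3)


def dssp_visible(states: np.ndarray) -> np.ndarray:
    """Map latent helix/coil states to the labels the hydrogen-bond
    assignment will produce on the σ=0 coordinate realization.

    A 4-turn at i needs states[i..i+3] all helix; residues i+1..i+4 are
    labeled H when turns exist at both i and i+1.  Works on (..., n).
    """
    x = np.asarray(states, dtype=bool)
    n = x.shape[-1]
    lo, hi = TURN_SPAN
    span = hi - lo + 1
    # turn[i] for i in 0..n-5 (needs i+4 <= n-1)
    n_turn = n - 4
    turn = np.ones(x.shape[:-1] + (n_turn,), dtype=bool)
    for k in range(lo, hi + 1):
        turn &= x[..., k:k + n_turn]
    out = np.zeros_like(x)
    for i in range(n_turn - 1):
        both = turn[..., i] & turn[..., i + 1]
        out[..., i + 1:i + 5] |= both[..., None]
    return out


def zb_expected_visible_fraction(n: int, s: float, sigma: float,
                                 exclude_terminal: int = 2) -> float:
    """Exact expectation of the hydrogen-bond-visible helicity over the
    interior residues, under the Zimm–Bragg equilibrium."""
    lo, hi = TURN_SPAN
    total = 0.0
    j_range = range(exclude_terminal, n - exclude_terminal)
    for j in j_range:
        # residue j is visible iff for some t in [j-4, j-1] (with both
        # turns valid) states [t+lo .. t+1+hi] are all H
        ts = [t for t in range(j - 4, j)
              if t >= 0 and (t + 1) + 4 <= n - 1]
        blocks = [(t + lo, t + 1 + hi) for t in ts]
        p_union = 0.0
        for k in range(1, len(blocks) + 1):
            for sub in combinations(range(len(blocks)), k):
                a = min(blocks[i][0] for i in sub)
                b = max(blocks[i][1] for i in sub)
                p_union += ((-1) ** (k + 1)) * _zb_prob_run_all_h(
                    a, b, n, s, sigma)
        total += p_union
    return total / len(list(j_range))


def calibrate_propagation_weight(n: int, sigma: float, target: float,
                                 exclude_terminal: int = 2,
                                 tol: float = 1e-4) -> float:
    """Bisection for the propagation weight s at which the expected
    visible helicity equals ``target``."""
    if not (0.0 < target < 1.0):
        raise ValueError(f"target helicity {target} outside (0, 1)")
    lo, hi = 1e-3, 1e4
    f_lo = zb_expected_visible_fraction(n, lo, sigma, exclude_terminal)
    f_hi = zb_expected_visible_fraction(n, hi, sigma, exclude_terminal)
    if not (f_lo < target < f_hi):
        raise ValueError(
            f"target helicity {target} unreachable on chain of length {n} "
            f"(attainable range ~[{f_lo:.3f}, {f_hi:.3f}])"
        )
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        f_mid = zb_expected_visible_fraction(n, mid, sigma, exclude_terminal)
        if abs(f_mid - target) < tol:
            return float(mid)
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# Fraying-trajectory simulator
# ---------------------------------------------------------------------------

DEFAULT_FRAY_SEQUENCE = "AEELKKIAESLQKIGEELAKRLEEM"


@dataclass
class FrayConfig:
    """Conditions for the replicate fraying simulation.

    Defaults mirror the analysis conventions used throughout the package:
    3 replicates, 10 ps frame spacing, interior counting with 2 residues
    excluded per terminus.
    """

    n_res: int = 25
    sequence: str | None = None
    n_frames: int = 2000
    n_replicates: int = 3
    target_helicity: float = 0.70
    nucleation_weight: float = 0.05   # Zimm–Bragg σ
    coordinate_noise_sigma: float = 0.05  # Å
    frame_spacing_ps: float = 10.0
    exclude_terminal: int = 2
    burn_in_sweeps: int = 300
    sweeps_per_frame: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.sequence is None:
            reps = -(-self.n_res // len(DEFAULT_FRAY_SEQUENCE))
            self.sequence = (DEFAULT_FRAY_SEQUENCE * reps)[: self.n_res]
        if len(self.sequence) != self.n_res:
            raise ValueError("sequence length must equal n_res")
        if not 0 < self.nucleation_weight <= 1:
            raise ValueError("nucleation_weight must be in (0, 1]")


@dataclass
class FrayGroundTruth:
    """Latent and assignment-visible helix states per replicate."""

    latent: list[np.ndarray]     # (n_frames, n_res) bool
    visible: list[np.ndarray]    # (n_frames, n_res) bool
    propagation_weight: float
    config: FrayConfig

    def latent_fraction(self, exclude_terminal: int | None = None) -> float:
        k = (self.config.exclude_terminal if exclude_terminal is None
             else exclude_terminal)
        return float(np.mean([x[:, k:x.shape[1] - k] for x in self.latent]))

    def visible_fraction(self, exclude_terminal: int | None = None) -> float:
        k = (self.config.exclude_terminal if exclude_terminal is None
             else exclude_terminal)
        return float(np.mean([x[:, k:x.shape[1] - k] for x in self.visible]))


def _gibbs_sweeps(x: np.ndarray, s: float, sigma: float, n_sweeps: int,
                  rng: np.random.Generator) -> None:
    """In-place checkerboard Gibbs sweeps of the Zimm–Bragg chain."""
    n = x.size
    T = _zb_transfer(s, sigma)
    v0 = np.array([1.0, s * sigma])
    idx_even = np.arange(0, n, 2)
    idx_odd = np.arange(1, n, 2)
    for _ in range(n_sweeps):
        for idx in (idx_even, idx_odd):
            left = np.empty((idx.size, 2))
            has_left = idx > 0
            left[~has_left] = v0
            left[has_left] = T[x[idx[has_left] - 1].astype(int)]
            right = np.ones((idx.size, 2))
            has_right = idx < n - 1
            nxt = x[idx[has_right] + 1].astype(int)
            right[has_right, 0] = T[0, nxt]
            right[has_right, 1] = T[1, nxt]
            w = left * right
            p_h = w[:, 1] / (w[:, 0] + w[:, 1])
            x[idx] = rng.random(idx.size) < p_h


def simulate_fray(cfg: FrayConfig) -> tuple[list[Ensemble], FrayGroundTruth]:
    """Generate replicate fraying trajectories with known ground truth.

    Latent per-residue helix/coil states evolve by Gibbs sweeps under the
    Zimm–Bragg measure with the propagation weight calibrated so the
    equilibrium hydrogen-bond-visible helicity matches
    ``cfg.target_helicity``.  Helical stretches receive ideal helix
    torsions, coil stretches broad non-helical torsions, coordinates are
    built by internal-coordinate chain construction and Gaussian noise is
    added.  Replicates differ only by a seed offset.
    """
    n = cfg.n_res
    s = calibrate_propagation_weight(n, cfg.nucleation_weight,
                                     cfg.target_helicity,
                                     cfg.exclude_terminal)
    ensembles: list[Ensemble] = []
    latents: list[np.ndarray] = []
    visibles: list[np.ndarray] = []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng(int(cfg.seed) + 1000 * rep)
        x = rng.random(n) < cfg.target_helicity
        _gibbs_sweeps(x, s, cfg.nucleation_weight, cfg.burn_in_sweeps, rng)
        states = np.empty((cfg.n_frames, n), dtype=bool)
        for f in range(cfg.n_frames):
            _gibbs_sweeps(x, s, cfg.nucleation_weight,
                          cfg.sweeps_per_frame, rng)
            states[f] = x
        phi = np.where(states, HELIX_PHI,
                       rng.uniform(-180.0, -100.0, states.shape))
        psi = np.where(states, HELIX_PSI,
                       rng.uniform(100.0, 180.0, states.shape))
        topo, xyz = build_backbone(cfg.sequence, phi, psi)
        if cfg.coordinate_noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, cfg.coordinate_noise_sigma,
                                   xyz.shape)
        topo.set_coords(xyz[0])
        ensembles.append(Ensemble(topo, list(xyz),
                                  frame_spacing_ps=cfg.frame_spacing_ps,
                                  replicate_id=rep))
        latents.append(states)
        visibles.append(dssp_visible(states))
    return ensembles, FrayGroundTruth(latents, visibles, s, cfg)


# ---------------------------------------------------------------------------
# HDX uptake simulator
# ---------------------------------------------------------------------------

DEFAULT_HDX_SEQUENCE = (
    "ATGNSLEIEELARFAVDEHNKKENALLEFVRVVKAKEQLVAGTLYYLTLEAKD"
    "GGKKKLYEAKVWVKPWENFKELQEFKPVGDA"
)  # 84 residues, a generic small-protein construct


@dataclass
class HDXSimConfig:
    """Conditions for the synthetic HDX-MS experiment."""

    sequence: str = DEFAULT_HDX_SEQUENCE
    peptide_length: int = 8
    peptide_step: int = 5
    epitope: tuple[int, int] = (40, 60)    # inclusive, construct numbering
    protection_fold_change: float = 10.0
    timepoints_s: tuple[float, ...] = (30.0, 120.0, 600.0, 3600.0)
    noise_sd: float = 0.01
    k_int_log_mu: float = 0.0    # ln of s^-1
    k_int_log_sd: float = 1.0
    pf_log_mu: float = np.log(50.0)
    pf_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.protection_fold_change < 1.0:
            raise ValueError("protection_fold_change must be >= 1")

    def peptides(self) -> list[tuple[int, int]]:
        n = len(self.sequence)
        out = []
        start = 1
        while start + self.peptide_length - 1 <= n:
            out.append((start, start + self.peptide_length - 1))
            start += self.peptide_step
        if out and out[-1][1] < n:
            out.append((n - self.peptide_length + 1, n))
        return out


def simulate_hdx(cfg: HDXSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an uptake table (apo + bound) with a planted epitope.

    Per-residue uptake follows u(t) = 1 - exp(-k_int t / PF); a peptide's
    uptake is the mean over its exchangeable amides (all residues after
    the first, minus prolines).  Binding multiplies PF by the protection
    fold-change on epitope residues only.  Returns ``(uptake, truth)``
    where ``truth`` marks, per peptide, whether it overlaps the planted
    epitope.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(cfg.sequence)
    k_int = np.exp(rng.normal(cfg.k_int_log_mu, cfg.k_int_log_sd, n))
    pf_apo = np.exp(rng.normal(cfg.pf_log_mu, cfg.pf_log_sd, n))
    epi_lo, epi_hi = cfg.epitope
    epi_mask = np.zeros(n, dtype=bool)
    epi_mask[epi_lo - 1:epi_hi] = True
    pf_bound = np.where(epi_mask, pf_apo * cfg.protection_fold_change,
                        pf_apo)

    rows = []
    truth_rows = []
    for start, end in cfg.peptides():
        pep_seq = cfg.sequence[start - 1:end]
        # exchangeable amides: every residue after the N-terminal one of
        # the peptide, excluding prolines
        amide_pos = [p for p in range(start + 1, end + 1)
                     if cfg.sequence[p - 1] != "P"]
        if not amide_pos:
            continue
        idx = np.array(amide_pos) - 1
        overlaps = bool(epi_mask[start - 1:end].any())
        truth_rows.append((start, end, pep_seq, overlaps))
        for cond, pf in (("apo", pf_apo), ("bound", pf_bound)):
            for t in cfg.timepoints_s:
                u = 1.0 - np.exp(-k_int[idx] * t / pf[idx])
                val = float(np.mean(u))
                if cfg.noise_sd > 0:
                    val += rng.normal(0.0, cfg.noise_sd)
                rows.append((start, end, pep_seq, cond, t,
                             float(np.clip(val, 0.0, 1.0))))
    uptake = pd.DataFrame(rows, columns=["start_res", "end_res", "sequence",
                                         "condition", "timepoint_s",
                                         "uptake"])
    truth = pd.DataFrame(truth_rows, columns=["start_res", "end_res",
                                              "sequence", "in_epitope"])
    return uptake, truth
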