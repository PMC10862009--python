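"""Residue-pair nonbonded interaction energies over trajectory frames.

The observable is the symmetric residue-pair matrix of frame-averaged
Coulomb + Lennard-Jones energies, the computational readout of which
contacts hold a grafted helix in place: covalently adjacent pairs hug the
diagonal, the i→i+4 backbone hydrogen bonds of a helix form a band next
to it, and the off-diagonal negative patches are the hydrophobic core.

Energies use plain truncation at 12 Å, a dielectric of 1 and
Lorentz–Berthelot-style combination (ε_ab = √(ε_a ε_b),
rmin_ab = rmin_half_a + rmin_half_b):

    E(r) = 332.0636 q_a q_b / r + ε_ab[(rmin_ab/r)^12 − 2 (rmin_ab/r)^6]

For sequence-adjacent residues the atom pairs one or two bonds across the
peptide bond are excluded (no 1-4 scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcefield import (ForceFieldParams, HYDROPHOBIC_RESIDUES,
                         ParameterizationError, default_params)
from .secondary_structure import (KS_CUTOFF, ensemble_with_amide_hydrogens,
                                  ks_energy, place_amide_hydrogens)
from .structure_io import (BACKBONE_ATOMS, Ensemble, PolymerStructure,
                           Residue, SegmentSpec)

__all__ = ["COULOMB_K", "pair_energy", "EnergyMatrix", "energy_matrix",
           "ContactMap", "hydrophobic_contacts", "interhelix_contributors",
           "cross_helix_energy"]

COULOMB_K = 332.0636   # kcal·Å/(mol·e²)
DEFAULT_CUTOFF = 12.0  # Å
CLASH_FLOOR = 2.0      # Å

# atom pairs 1-2/1-3 across the peptide bond C_i–N_{i+1}; first name in
# residue i, second in residue i+1
_PEPTIDE_EXCLUSIONS = {("C", "N"), ("CA", "N"), ("O", "N"),
                       ("C", "CA"), ("C", "H")}


def _atom_arrays(res: Residue, params: ForceFieldParams):
    """Names, charges and LJ parameters for the parameterized atoms of a
    residue (heavy atoms + amide H)."""
    names, q, eps, rmin2, xyz = [], [], [], [], []
    for a in res.atoms:
        if a.element.upper() == "H" and a.name != "H":
            continue  # nonpolar hydrogens are not modeled
        p = params.get(res.res_name, a.name)
        names.append(a.name)
        q.append(p.partial_charge)
        eps.append(p.lj_epsilon)
        rmin2.append(p.lj_rmin_half)
        xyz.append(a.coords)
    return (names, np.array(q), np.array(eps), np.array(rmin2),
            np.array(xyz))


def _exclusion_mask(res_i: Residue, res_j: Residue,
                    names_i: list[str], names_j: list[str]) -> np.ndarray:
    """Boolean (na, nb) mask of atom pairs excluded for peptide-bonded
    neighbors; all-False otherwise."""
    mask = np.zeros((len(names_i), len(names_j)), dtype=bool)
    if res_i.chain_id != res_j.chain_id:
        return mask
    if res_j.res_seq - res_i.res_seq == 1:
        pairs = _PEPTIDE_EXCLUSIONS
        first, second = names_i, names_j
    elif res_i.res_seq - res_j.res_seq == 1:
        pairs = {(b, a) for a, b in _PEPTIDE_EXCLUSIONS}
        first, second = names_i, names_j
    else:
        return mask
    for a, b in pairs:
        if a in first and b in second:
            mask[first.index(a), second.index(b)] = True
    return mask


def _energies_from_dist(d: np.ndarray, qi, qj, ei, ej, ri, rj,
                        cutoff: float, excl: np.ndarray):
    """Coulomb and LJ sums over atom-pair distance arrays (..., na, nb)."""
    within = (d <= cutoff) & ~excl
    with np.errstate(divide="ignore", invalid="ignore"):
        coul = COULOMB_K * qi[:, None] * qj[None, :] / d
        eps = np.sqrt(ei[:, None] * ej[None, :])
        rmin = ri[:, None] + rj[None, :]
        x6 = (rmin / d) ** 6
        lj = eps * (x6 * x6 - 2.0 * x6)
    coul = np.where(within, coul, 0.0)
    lj = np.where(within, lj, 0.0)
    return coul.sum(axis=(-2, -1)), lj.sum(axis=(-2, -1))


def pair_energy(res_i: Residue, res_j: Residue,
                params: ForceFieldParams | None = None,
                cutoff: float = DEFAULT_CUTOFF):
    """Nonbonded (coulomb, lj, total) in kcal/mol between two residues of
    one conformer.  Atom pairs beyond ``cutoff`` contribute nothing;
    peptide-bond 1-2/1-3 pairs of adjacent residues are excluded."""
    if params is None:
        params = default_params()
    if res_i.chain_id == res_j.chain_id and res_i.res_seq == res_j.res_seq:
        raise ValueError("pair energy of a residue with itself")
    names_i, qi, ei, ri, xi = _atom_arrays(res_i, params)
    names_j, qj, ej, rj, xj = _atom_arrays(res_j, params)
    d = np.linalg.norm(xi[:, None, :] - xj[None, :, :], axis=-1)
    excl = _exclusion_mask(res_i, res_j, names_i, names_j)
    coul, lj = _energies_from_dist(d, qi, qj, ei, ej, ri, rj, cutoff, excl)
    return float(coul), float(lj), float(coul + lj)


@dataclass
class EnergyMatrix:
    """Frame-averaged symmetric residue-pair energy matrix with band labels
    in {adjacent, hbond_band, core, other}; the self diagonal is NaN."""

    chain_id: str
    res_seqs: list[int]
    total: np.ndarray
    coulomb: np.ndarray
    lj: np.ndarray
    bands: np.ndarray         # dtype <U10
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        n = len(self.res_seqs)
        for a in range(n):
            for b in range(a + 1, n):
                rows.append((self.res_seqs[a], self.res_seqs[b],
                             self.coulomb[a, b], self.lj[a, b],
                             self.total[a, b], self.bands[a, b]))
        return pd.DataFrame(rows, columns=["res_i", "res_j", "coulomb",
                                           "lj", "total", "band"])

    def band_mean(self, band: str) -> float:
        sel = self.bands == band
        return float(self.total[sel].mean()) if sel.any() else float("nan")


def _resolve_residues(topo: PolymerStructure,
                      residues: SegmentSpec | list[int],
                      chain_id: str | None = None) -> list[Residue]:
    if isinstance(residues, SegmentSpec):
        cid = residues.chain_id
        wanted = list(range(residues.start_res, residues.end_res + 1))
    else:
        cid = chain_id or topo.chain_ids[0]
        wanted = list(residues)
    out = []
    for rs in wanted:
        r = topo.get_residue(cid, rs)
        if r is None:
            raise ValueError(f"residue {cid}:{rs} not in topology")
        out.append(r)
    return out


def _hbond_occupancy(frames: np.ndarray, topo: PolymerStructure,
                     chain_id: str, res_seqs: list[int]) -> np.ndarray:
    """Fraction of frames with a Kabsch–Sander H-bond (either direction)
    for each residue pair; (n, n) array."""
    chain_res = list(topo.residues(chain_id))
    seq_to_col = {r.res_seq: j for j, r in enumerate(chain_res)}
    idx = topo.atom_index()
    F = frames.shape[0]
    nch = len(chain_res)
    bb = {}
    for name in ("N", "C", "O"):
        arr = np.full((F, nch, 3), np.nan)
        for j, r in enumerate(chain_res):
            key = (chain_id, r.res_seq, name)
            if key in idx:
                arr[:, j] = frames[:, idx[key]]
        bb[name] = arr
    H, has_h = place_amide_hydrogens(frames, topo, chain_id)

    n = len(res_seqs)
    occ = np.zeros((n, n))
    dist = lambda p, q: np.linalg.norm(p - q, axis=-1)
    for a in range(n):
        for b in range(a + 1, n):
            ca, cb = seq_to_col[res_seqs[a]], seq_to_col[res_seqs[b]]
            bond = np.zeros(F, dtype=bool)
            for don, acc in ((cb, ca), (ca, cb)):
                if not has_h[don]:
                    continue
                e = ks_energy(dist(bb["O"][:, acc], bb["N"][:, don]),
                              dist(bb["C"][:, acc], H[:, don]),
                              dist(bb["O"][:, acc], H[:, don]),
                              dist(bb["C"][:, acc], bb["N"][:, don]))
                bond |= e < KS_CUTOFF
            occ[a, b] = occ[b, a] = bond.mean()
    return occ


def energy_matrix(ens: Ensemble | PolymerStructure,
                  residues: SegmentSpec | list[int],
                  params: ForceFieldParams | None = None,
                  stride: int = 1,
                  cutoff: float = DEFAULT_CUTOFF,
                  core_threshold: float = -1.0,
                  hbond_occupancy_min: float = 0.5) -> EnergyMatrix:
    """Frame-averaged residue-pair energy matrix with band classification.

    Bands: |i−j| = 1 → ``adjacent``; pairs with a Kabsch–Sander H-bond in
    ≥ ``hbond_occupancy_min`` of frames and |i−j| ∈ {3,4,5} →
    ``hbond_band``; both residues hydrophobic with frame-averaged total ≤
    ``core_threshold`` → ``core``; everything else ``other``.
    """
    if isinstance(ens, PolymerStructure):
        ens = Ensemble(ens, [ens.coords()])
    if params is None:
        params = default_params()
    # amide hydrogens carry +0.31 e; without them every residue would be
    # a net monopole, so they are placed geometrically when absent
    ens = ensemble_with_amide_hydrogens(ens)
    topo = ens.topology
    res_list = _resolve_residues(topo, residues)
    chain_id = res_list[0].chain_id
    res_seqs = [r.res_seq for r in res_list]
    n = len(res_list)

    frames = np.stack(ens.frames[::stride])
    F = frames.shape[0]
    idx = topo.atom_index()

    per_res = []
    for r in res_list:
        names, q, eps, rmin2, _ = _atom_arrays(r, params)
        rows = [idx[(r.chain_id, r.res_seq, nm)] for nm in names]
        per_res.append((names, q, eps, rmin2, np.array(rows)))

    total = np.full((n, n), np.nan)
    coulomb = np.full((n, n), np.nan)
    ljm = np.full((n, n), np.nan)
    for a in range(n):
        na_, qa, ea, ra, rows_a = per_res[a]
        xa = frames[:, rows_a]                      # (F, na, 3)
        for b in range(a + 1, n):
            nb_, qb, eb, rb, rows_b = per_res[b]
            xb = frames[:, rows_b]
            d = np.linalg.norm(xa[:, :, None, :] - xb[:, None, :, :],
                               axis=-1)             # (F, na, nb)
            excl = _exclusion_mask(res_list[a], res_list[b], na_, nb_)
            coul, lj = _energies_from_dist(d, qa, qb, ea, eb, ra, rb,
                                           cutoff, excl)
            coulomb[a, b] = coulomb[b, a] = coul.mean()
            ljm[a, b] = ljm[b, a] = lj.mean()
            total[a, b] = total[b, a] = coulomb[a, b] + ljm[a, b]

    occ = _hbond_occupancy(frames, topo, chain_id, res_seqs)
    bands = np.full((n, n), "other", dtype="<U10")
    seq_arr = np.array(res_seqs)
    sep = np.abs(seq_arr[:, None] - seq_arr[None, :])
    hydro = np.array([r.res_name in HYDROPHOBIC_RESIDUES for r in res_list])
    both_hydro = hydro[:, None] & hydro[None, :]
    with np.errstate(invalid="ignore"):
        bands[both_hydro & (total <= core_threshold)] = "core"
    bands[(occ >= hbond_occupancy_min) & np.isin(sep, (3, 4, 5))] = "hbond_band"
    bands[sep == 1] = "adjacent"
    for k in range(n):
        bands[k, k] = "self"
    return EnergyMatrix(chain_id, res_seqs, total, coulomb, ljm, bands, F)


@dataclass
class ContactMap:
    """Hydrophobic residue-pair contacts by minimum side-chain distance."""

    pairs: list[tuple[int, int, float]]   # (res_seq_a, res_seq_b, min dist Å)
    dmax: float

    def __len__(self):
        return len(self.pairs)


def _side_chain_coords(res: Residue) -> np.ndarray:
    side = [a.coords for a in res.heavy_atoms()
            if a.name not in BACKBONE_ATOMS]
    if not side:  # GLY falls back to CA
        ca = res.atom("CA")
        side = [ca.coords] if ca is not None else []
    return np.array(side)


def hydrophobic_contacts(frame: PolymerStructure,
                         group_a: SegmentSpec, group_b: SegmentSpec,
                         dmax: float = 4.5) -> ContactMap:
    """Residue pairs (a ∈ A, b ∈ B), both hydrophobic, whose minimum
    side-chain heavy-atom distance is ≤ ``dmax``."""
    res_a = _resolve_residues(frame, group_a)
    res_b = _resolve_residues(frame, group_b)
    pairs = []
    for ra in res_a:
        if ra.res_name not in HYDROPHOBIC_RESIDUES:
            continue
        xa = _side_chain_coords(ra)
        if xa.size == 0:
            continue
        for rb in res_b:
            if rb.res_name not in HYDROPHOBIC_RESIDUES:
                continue
            if (ra.chain_id, ra.res_seq) == (rb.chain_id, rb.res_seq):
                continue
            xb = _side_chain_coords(rb)
            if xb.size == 0:
                continue
            d = float(np.min(np.linalg.norm(
                xa[:, None, :] - xb[None, :, :], axis=-1)))
            if d <= dmax:
                pairs.append((ra.res_seq, rb.res_seq, d))
    return ContactMap(pairs, dmax)


def _cross_cells(M: EnergyMatrix, helix_a: SegmentSpec,
                 helix_b: SegmentSpec):
    in_a = [(helix_a.start_res <= rs <= helix_a.end_res)
            for rs in M.res_seqs]
    in_b = [(helix_b.start_res <= rs <= helix_b.end_res)
            for rs in M.res_seqs]
    if any(a and b for a, b in zip(in_a, in_b)):
        raise ValueError("helices overlap")
    return np.array(in_a), np.array(in_b)


def cross_helix_energy(M: EnergyMatrix, helix_a: SegmentSpec,
                       helix_b: SegmentSpec) -> float:
    """Sum of frame-averaged pair energies across the two helices."""
    in_a, in_b = _cross_cells(M, helix_a, helix_b)
    block = M.total[np.ix_(in_a, in_b)]
    return float(np.nansum(block))


def interhelix_contributors(M: EnergyMatrix, helix_a: SegmentSpec,
                            helix_b: SegmentSpec,
                            top_k: int = 5) -> list[tuple[int, float]]:
    """Residues ranked by their summed cross-helix pair energy, most
    negative (most stabilizing) first; ties break by residue index."""
    in_a, in_b = _cross_cells(M, helix_a, helix_b)
    seqs = np.array(M.res_seqs)
    scores = []
    for side_self, side_other in ((in_a, in_b), (in_b, in_a)):
        for k in np.where(side_self)[0]:
            s = float(np.nansum(M.total[k, side_other]))
            scores.append((int(seqs[k]), s))
    scores.sort(key=lambda t: (t[1], t[0]))
    return scores[:top_k]
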