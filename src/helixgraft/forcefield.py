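"""Simplified all-atom nonbonded parameters for the 20 amino acids.

A deliberately small, fully documented parameter set: partial charges (e)
and Lennard-Jones well depths/radii (kcal/mol, Å) for every standard
heavy atom plus the backbone amide hydrogen.  Charges use CHARMM-style
backbone values and seed values on polar side-chain atoms; whatever
residual remains after the polar assignments is placed on CB (CA for
glycine) so that every residue sums exactly to its formal charge.
Nonpolar hydrogens are not modeled, which is why the aliphatic carbons
carry slightly different effective charges than any parent force field —
bit-compatibility with CHARMM36m is explicitly not the contract; the
qualitative band structure of residue-pair energy matrices is.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ForceFieldParams", "AtomParams", "default_params",
           "ParameterizationError", "FORMAL_CHARGE", "HYDROPHOBIC_RESIDUES"]


class ParameterizationError(Exception):
    """An atom has no parameters in the table."""


@dataclass(frozen=True)
class AtomParams:
    partial_charge: float   # e
    lj_epsilon: float       # kcal/mol
    lj_rmin_half: float     # Å


FORMAL_CHARGE = {
    "ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0,
}

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR", "PRO"})

# backbone charges (CHARMM-style); PRO has no amide H
_BACKBONE_Q = {"N": -0.47, "H": 0.31, "CA": 0.07, "C": 0.51, "O": -0.51}
_BACKBONE_Q_PRO = {"N": -0.29, "CA": 0.02, "C": 0.51, "O": -0.51}

# seed charges for polar/charged side-chain atoms; everything not listed
# here (and not CB) is 0 before normalization
_SIDE_Q: dict[str, dict[str, float]] = {
    "SER": {"OG": -0.40, "CB": 0.40},
    "THR": {"OG1": -0.40, "CB": 0.40},
    "TYR": {"OH": -0.40, "CZ": 0.40},
    "CYS": {"SG": -0.23, "CB": 0.23},
    "MET": {"SD": -0.09, "CG": 0.045, "CE": 0.045},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": -0.32, "CB": 0.32},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": -0.32, "CG": 0.32},
    "ASP": {"CG": 0.62, "OD1": -0.76, "OD2": -0.76},
    "GLU": {"CD": 0.62, "OE1": -0.76, "OE2": -0.76},
    "LYS": {"NZ": 0.70, "CE": 0.30},
    "ARG": {"CZ": 0.64, "NE": -0.40, "NH1": 0.40, "NH2": 0.40, "CD": 0.20},
    "HIS": {"ND1": -0.36, "NE2": -0.36, "CE1": 0.25, "CG": 0.22,
            "CD2": 0.25},
    "TRP": {"NE1": -0.51, "CD1": 0.22, "CE2": 0.24},
}

_SIDE_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
            "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

_AROMATIC_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}

# LJ classes: (epsilon kcal/mol, rmin/2 Å)
_LJ = {
    "N": (0.20, 1.85),
    "O": (0.12, 1.70),
    "O_hydroxyl": (0.15, 1.77),
    "C_carbonyl": (0.11, 2.00),
    "C_aromatic": (0.07, 1.99),
    "C_aliphatic": (0.078, 2.05),
    "CA": (0.032, 2.275),
    "S": (0.45, 2.00),
    "H_amide": (0.046, 0.2245),
}

_HYDROXYL_O = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}
_CARBONYL_SIDE_C = {("ASN", "CG"), ("GLN", "CD"), ("ASP", "CG"),
                    ("GLU", "CD")}


def _lj_class(res: str, atom: str) -> tuple[float, float]:
    if atom == "H":
        return _LJ["H_amide"]
    if atom == "CA":
        return _LJ["CA"]
    el = atom[0]
    if el == "N":
        return _LJ["N"]
    if el == "S":
        return _LJ["S"]
    if el == "O":
        return _LJ["O_hydroxyl"] if (res, atom) in _HYDROXYL_O else _LJ["O"]
    # carbon
    if atom == "C" or (res, atom) in _CARBONYL_SIDE_C:
        return _LJ["C_carbonyl"]
    if atom in _AROMATIC_CARBONS.get(res, ()):
        return _LJ["C_aromatic"]
    return _LJ["C_aliphatic"]


class ForceFieldParams:
    """Lookup of per-(residue, atom) nonbonded parameters."""

    def __init__(self, table: dict[tuple[str, str], AtomParams]):
        self._table = table

    def get(self, res_name: str, atom_name: str) -> AtomParams:
        key = (res_name.upper(), atom_name.upper())
        try:
            return self._table[key]
        except KeyError:
            raise ParameterizationError(
                f"no parameters for atom {atom_name!r} of residue "
                f"{res_name!r}") from None

    def has(self, res_name: str, atom_name: str) -> bool:
        return (res_name.upper(), atom_name.upper()) in self._table

    def residue_charge(self, res_name: str) -> float:
        res = res_name.upper()
        return sum(p.partial_charge for (r, _), p in self._table.items()
                   if r == res)


def _build_default() -> ForceFieldParams:
    table: dict[tuple[str, str], AtomParams] = {}
    for res, side_atoms in _SIDE_ATOMS.items():
        backbone = _BACKBONE_Q_PRO if res == "PRO" else _BACKBONE_Q
        q = dict(backbone)
        for a in side_atoms:
            q[a] = _SIDE_Q.get(res, {}).get(a, 0.0)
        # place the residual on CB (CA for GLY) so the residue sums
        # exactly to its formal charge
        target = FORMAL_CHARGE.get(res, 0.0)
        residual = target - sum(q.values())
        sink = "CB" if res != "GLY" else "CA"
        q[sink] += residual
        for a, charge in q.items():
            eps, rmin2 = _lj_class(res, a)
            table[(res, a)] = AtomParams(round(charge, 6), eps, rmin2)
    return ForceFieldParams(table)


_DEFAULT: ForceFieldParams | None = None


def default_params() -> ForceFieldParams:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _build_default()
    return _DEFAULT
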