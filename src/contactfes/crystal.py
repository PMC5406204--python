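"""Crystal symmetry expansion, supercell construction and residue-level
crystal-contact maps.

Symmetry operators act in fractional coordinates; coordinates are carried
in Å and converted through the standard crystallographic
orthogonalization (a along x, b in the xy-plane).  Two residues of
different symmetry images are in contact when the minimal distance
between any of their atoms is under the criterion (4 Å by default) — the
same criterion used to flag interactions that stabilize conformations in
the lattice but are absent in solution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, ConsistencyError
from .structio import Atom, Structure, SymmetryOperator, _cell_matrices

__all__ = [
    "SymmetryOperator",
    "CrystalContact",
    "CrystalContactMap",
    "SPACE_GROUP_OPERATORS",
    "spacegroup_operators",
    "fractional_orthogonal",
    "expand_symmetry",
    "build_supercell",
    "crystal_contact_map",
    "annotate_contacts",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"


def _ops(*triplets):
    out = []
    for rot, trans in triplets:
        out.append(SymmetryOperator.from_arrays(np.array(rot, float),
                                                np.array(trans, float)))
    return out


#: operators for the small built-in table of common space groups
SPACE_GROUP_OPERATORS = {
    "P1": _ops(([[1, 0, 0], [0, 1, 0], [0, 0, 1]], [0, 0, 0])),
    "P21": _ops(
        ([[1, 0, 0], [0, 1, 0], [0, 0, 1]], [0, 0, 0]),
        ([[-1, 0, 0], [0, 1, 0], [0, 0, -1]], [0, 0.5, 0]),
    ),
    "P212121": _ops(
        ([[1, 0, 0], [0, 1, 0], [0, 0, 1]], [0, 0, 0]),
        ([[-1, 0, 0], [0, -1, 0], [0, 0, 1]], [0.5, 0, 0.5]),
        ([[-1, 0, 0], [0, 1, 0], [0, 0, -1]], [0, 0.5, 0.5]),
        ([[1, 0, 0], [0, -1, 0], [0, 0, -1]], [0.5, 0.5, 0]),
    ),
}


def spacegroup_operators(name: str) -> list:
    key = name.replace(" ", "").upper().replace("₁", "1")
    if key not in SPACE_GROUP_OPERATORS:
        raise ConfigurationError(
            f"space group {name!r} not in built-in table "
            f"{sorted(SPACE_GROUP_OPERATORS)}"
        )
    return list(SPACE_GROUP_OPERATORS[key])


def fractional_orthogonal(cell, direction: str = "to_frac") -> np.ndarray:
    """Transform matrix between fractional and orthogonal (Å) coordinates.

    ``to_orth`` maps fractional → Å (the orthogonalization matrix),
    ``to_frac`` its inverse.  Convention: a along x, b in the xy-plane.
    """
    try:
        o_mat, f_mat = _cell_matrices(cell)
    except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
        raise ConfigurationError(f"degenerate cell {cell!r}")
    if not np.all(np.isfinite(o_mat)):
        raise ConfigurationError(f"degenerate cell {cell!r}")
    if direction == "to_orth":
        return o_mat
    if direction == "to_frac":
        return f_mat
    raise ValueError("direction must be 'to_frac' or 'to_orth'")


def _image_coords(coords_frac: np.ndarray, op: SymmetryOperator,
                  shift: np.ndarray, o_mat: np.ndarray) -> np.ndarray:
    return (op.apply_frac(coords_frac) + shift) @ o_mat.T


def expand_symmetry(asu: Structure, operators: Sequence[SymmetryOperator] | None = None,
                    lattice_range: Sequence = ((0, 0, 0),)) -> Structure:
    """One copy of the asymmetric unit per (operator, lattice shift).

    Chain ids are remapped uniquely across copies; the identity copy (the
    input ASU, identity operator at zero shift) is included once.
    """
    if asu.cell is None:
        raise ConfigurationError("symmetry expansion requires a unit cell")
    operators = list(operators if operators is not None
                     else (asu.symmetry_ops or []))
    if not operators:
        raise ConfigurationError("no symmetry operators supplied")
    o_mat = fractional_orthogonal(asu.cell, "to_orth")
    f_mat = fractional_orthogonal(asu.cell, "to_frac")
    coords_frac = asu.coords @ f_mat.T

    atoms = []
    copy = 0
    for shift in lattice_range:
        shift = np.asarray(shift, float)
        for op in operators:
            new_coords = _image_coords(coords_frac, op, shift, o_mat)
            cid = _CHAIN_IDS[copy % len(_CHAIN_IDS)]
            for a, pos in zip(asu.atoms, new_coords):
                atoms.append(replace(a, chain_id=cid, position=pos.copy()))
            copy += 1
    return Structure(atoms, cell=asu.cell, label=f"{asu.label}|expanded")


def build_supercell(asu: Structure, operators=None,
                    na: int = 1, nb: int = 1, nc: int = 1) -> Structure:
    """Expand over an na × nb × nc block of unit cells; the returned cell is
    scaled to (na·a, nb·b, nc·c)."""
    if min(na, nb, nc) < 1:
        raise ValueError("cell multiplicities must be positive")
    shifts = [np.array(s, float) for s in product(range(na), range(nb), range(nc))]
    out = expand_symmetry(asu, operators, shifts)
    a, b, c, al, be, ga = asu.cell
    out.cell = (na * a, nb * b, nc * c, al, be, ga)
    return out


@dataclass(frozen=True)
class CrystalContact:
    asu_residue: tuple          # (chain, resnum, icode)
    neighbor_residue: tuple
    operator_id: int            # index into the operator list
    lattice_shift: tuple        # integer triple
    min_distance: float         # Å


@dataclass
class CrystalContactMap:
    contacts: list
    criterion: float = 4.0

    def __len__(self) -> int:
        return len(self.contacts)

    def merged_pairs(self) -> set:
        """Residue-pair view merged over all symmetry neighbors."""
        return {(c.asu_residue, c.neighbor_residue) for c in self.contacts}

    def to_records(self) -> list:
        return [
            (c.asu_residue, c.neighbor_residue, c.operator_id,
             c.lattice_shift, c.min_distance)
            for c in self.contacts
        ]

    def write(self, path) -> None:
        lines = ["#! FIELDS asu_res neighbor_res operator shift min_distance"]
        for c in self.contacts:
            asu = f"{c.asu_residue[0]}:{c.asu_residue[1]}{c.asu_residue[2]}"
            nb = f"{c.neighbor_residue[0]}:{c.neighbor_residue[1]}{c.neighbor_residue[2]}"
            sh = ",".join(str(int(s)) for s in c.lattice_shift)
            lines.append(f"{asu} {nb} {c.operator_id} {sh} {c.min_distance:.3f}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def crystal_contact_map(asu: Structure, operators=None,
                        criterion: float = 4.0,
                        margin: float = 2.0,
                        max_shift: int = 1) -> CrystalContactMap:
    """Residue pairs of the ASU in contact with its symmetry images.

    Every non-identity image — including lattice-shifted copies generated
    by the identity operator — within the neighborhood is scanned; residue
    pairs whose minimal inter-atomic distance is under ``criterion``
    (default 4 Å) are reported per (operator, shift).  Images whose
    bounding box stays farther than ``criterion + margin`` from the ASU's
    are skipped (a performance guard, not a change of criterion).
    """
    if asu.cell is None:
        raise ConfigurationError("contact map requires a unit cell")
    operators = list(operators if operators is not None
                     else (asu.symmetry_ops or []))
    if not operators:
        raise ConfigurationError("no symmetry operators supplied")
    o_mat = fractional_orthogonal(asu.cell, "to_orth")
    f_mat = fractional_orthogonal(asu.cell, "to_frac")
    coords = asu.coords
    coords_frac = coords @ f_mat.T
    res_keys = asu.residues()
    res_indices = {k: np.array(asu.residue_atom_indices(*k)) for k in res_keys}
    asu_lo, asu_hi = coords.min(axis=0), coords.max(axis=0)
    reach = criterion + margin

    contacts = []
    shifts = range(-max_shift, max_shift + 1)
    for sa, sb, sc in product(shifts, shifts, shifts):
        shift = np.array([sa, sb, sc], float)
        for op_id, op in enumerate(operators):
            if op.is_identity() and sa == sb == sc == 0:
                continue
            img = _image_coords(coords_frac, op, shift, o_mat)
            if np.any(img.min(axis=0) > asu_hi + reach) or \
                    np.any(img.max(axis=0) < asu_lo - reach):
                continue
            # residue-level scan
            for ka in res_keys:
                ia = res_indices[ka]
                ca = coords[ia]
                for kb in res_keys:
                    ib = res_indices[kb]
                    cb = img[ib]
                    # cheap box test first
                    if np.any(cb.min(axis=0) > ca.max(axis=0) + criterion) or \
                            np.any(cb.max(axis=0) < ca.min(axis=0) - criterion):
                        continue
                    d = cdist(ca, cb).min()
                    if d < criterion:
                        contacts.append(CrystalContact(
                            asu_residue=ka, neighbor_residue=kb,
                            operator_id=op_id,
                            lattice_shift=(sa, sb, sc),
                            min_distance=float(d),
                        ))
    return CrystalContactMap(contacts, criterion=criterion)


def annotate_contacts(cmap: CrystalContactMap,
                      annotations: dict) -> list:
    """Tag contacts with the residue-range labels they intersect.

    ``annotations`` maps a label (e.g. ``"L16 loop"``) to one or more
    inclusive residue-number ranges ``(lo, hi)``.  Every contact row is
    retained; a row's tags list all labels whose range contains either the
    ASU or the neighbor residue number.  Overlapping labels all apply.
    """
    norm = {}
    for label, ranges in annotations.items():
        if ranges and isinstance(ranges[0], (int, float)):
            ranges = [ranges]
        norm[label] = [(int(lo), int(hi)) for lo, hi in ranges]

    report = []
    for c in cmap.contacts:
        tags = []
        for label, ranges in norm.items():
            for lo, hi in ranges:
                if lo <= c.asu_residue[1] <= hi or \
                        lo <= c.neighbor_residue[1] <= hi:
                    tags.append(label)
                    break
        report.append({"contact": c, "tags": sorted(tags)})
    return report
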