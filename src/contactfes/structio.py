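"""Structure and trajectory I/O, atom selection, superposition, distances.

The interchange format is a deliberately small subset of the PDB text
format: ATOM/HETATM, CRYST1, REMARK 290 SMTRY, MODEL/ENDMDL.  Multi-model
PDB files carry trajectories; model order defines time with a declared
stride.  Coordinates are Å, author residue numbering is preserved
verbatim, and insertion codes are carried through.

Alternate locations: atoms with altloc 'A' or blank are kept, all others
dropped (single-conformer convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    ConsistencyError,
    DegenerateFitError,
    FormatError,
    ResidueLookupError,
    SelectionError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "SymmetryOperator",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select_atoms",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "min_residue_distance",
]

# Atom names eligible for contact-map CVs: Cα, Cβ and backbone carbonyl O.
CV_ELIGIBLE_NAMES = ("CA", "CB", "O")
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class SymmetryOperator:
    """Crystallographic symmetry operation in fractional-coordinate convention."""

    rotation: tuple  # 3x3 nested tuple
    translation: tuple  # length-3 tuple, fractional

    @property
    def rot(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def trans(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @classmethod
    def from_arrays(cls, rotation, translation) -> "SymmetryOperator":
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return cls(tuple(tuple(row) for row in r), tuple(t))

    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls.from_arrays(np.eye(3), np.zeros(3))

    def apply_frac(self, frac: np.ndarray) -> np.ndarray:
        """Apply to an (N,3) array of fractional coordinates."""
        return frac @ self.rot.T + self.trans

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.rot, np.eye(3), atol=tol)
            and np.allclose(self.trans, 0.0, atol=tol)
        )


@dataclass
class Atom:
    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    insertion_code: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial} {self.name}")
        if self.b_factor < 0:
            raise ValueError("b_factor must be >= 0")

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def atom_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code, self.name)


@dataclass
class Structure:
    """An ordered collection of atoms with optional cell and symmetry operators."""

    atoms: list
    cell: tuple | None = None  # (a, b, c, alpha, beta, gamma) Å / degrees
    symmetry_ops: list | None = None
    label: str = ""

    def __post_init__(self):
        if self.cell is not None:
            a, b, c, al, be, ga = self.cell
            if min(a, b, c) <= 0:
                raise ValueError("cell lengths must be positive")
            if not all(0.0 < ang < 180.0 for ang in (al, be, ga)):
                raise ValueError("cell angles must lie in (0, 180) degrees")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ConsistencyError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, cell=self.cell, symmetry_ops=self.symmetry_ops,
                         label=label if label is not None else self.label)

    def atom_index(self, chain_id: str, residue_number: int, name: str,
                   insertion_code: str = "") -> int:
        key = (chain_id, residue_number, insertion_code, name)
        idx = self._atom_lookup().get(key)
        if idx is None:
            raise ResidueLookupError(
                f"atom {name} of residue {chain_id}{residue_number}{insertion_code} "
                "not found"
            )
        return idx

    def residue_atom_indices(self, chain_id: str, residue_number: int,
                             insertion_code: str = "") -> list:
        out = [i for i, a in enumerate(self.atoms)
               if a.residue_key == (chain_id, residue_number, insertion_code)]
        if not out:
            raise ResidueLookupError(
                f"residue {chain_id}{residue_number}{insertion_code} not found"
            )
        return out

    def residues(self) -> list:
        """Ordered unique residue keys (chain, resnum, icode)."""
        seen, out = set(), []
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                out.append(a.residue_key)
        return out

    def _atom_lookup(self) -> dict:
        cache = getattr(self, "_lookup_cache", None)
        if cache is None or cache[0] != len(self.atoms):
            table = {}
            for i, a in enumerate(self.atoms):
                table.setdefault(a.atom_key, i)
            cache = (len(self.atoms), table)
            object.__setattr__(self, "_lookup_cache", cache)
        return cache[1]

    def validate_unique(self) -> None:
        keys = [a.atom_key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ConsistencyError(f"duplicate atom identity {dup}")


@dataclass
class Trajectory:
    """Frames congruent with a template Structure; times strictly increasing (ps)."""

    template: Structure
    frames: list  # list of (N,3) float arrays
    times: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.template.atoms)
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ConsistencyError(
                    f"frame {k} has shape {f.shape}, template has {n} atoms"
                )
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise ConsistencyError("times length does not match frame count")
            if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def structure(self, i: int) -> Structure:
        return self.template.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _cell_matrices(cell):
    """Orthogonalization matrix O (frac->orth) and its inverse for a cell."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    cos_al, cos_be, cos_ga = np.cos([al, be, ga])
    sin_ga = np.sin(ga)
    v = np.sqrt(
        1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
    )
    o = np.array([
        [a, b * cos_ga, c * cos_be],
        [0.0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
        [0.0, 0.0, c * v / sin_ga],
    ])
    return o, np.linalg.inv(o)


def _parse_atom_line(line: str, lineno: int) -> Atom | None:
    try:
        altloc = line[16].strip() if len(line) > 16 else ""
        if altloc not in ("", "A"):
            return None
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(line[22:26])
        icode = line[26].strip() if len(line) > 26 else ""
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_s = line[54:60].strip() if len(line) > 54 else ""
        b_s = line[60:66].strip() if len(line) > 60 else ""
        occ = float(occ_s) if occ_s else 1.0
        bf = float(b_s) if b_s else 0.0
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparsable ATOM/HETATM record at line {lineno}: {exc}")
    return Atom(serial=serial, name=name, residue_name=resname,
                residue_number=resnum, chain_id=chain, insertion_code=icode,
                position=np.array([x, y, z]), occupancy=occ, b_factor=bf)


def _parse_pdb_text(text: str, label: str = ""):
    """Parse the PDB subset; returns (models, cell, symmetry_ops).

    models is a list of atom lists (one per MODEL, or a single list when the
    file has no MODEL records).
    """
    cell = None
    smtry_rows: dict = {}
    models: list = []
    current: list = []
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            if atom is not None:
                current.append(atom)
        elif rec == "CRYST1":
            try:
                cell = (float(line[6:15]), float(line[15:24]), float(line[24:33]),
                        float(line[33:40]), float(line[40:47]), float(line[47:54]))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"unparsable CRYST1 record at line {lineno}: {exc}")
        elif rec == "REMARK" and line[7:10].strip() == "290" and "SMTRY" in line:
            parts = line.split()
            # REMARK 290 SMTRYn opid r1 r2 r3 t
            try:
                row = int(parts[2][-1])
                opid = int(parts[3])
                vals = [float(v) for v in parts[4:8]]
            except (ValueError, IndexError) as exc:
                raise FormatError(f"unparsable SMTRY record at line {lineno}: {exc}")
            smtry_rows.setdefault(opid, {})[row] = vals
        elif rec == "MODEL ":
            saw_model = True
            if current:
                models.append(current)
                current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
    if current or not models:
        models.append(current)

    ops = None
    if smtry_rows:
        ops = []
        if cell is not None:
            o_mat, f_mat = _cell_matrices(cell)
        else:
            o_mat = f_mat = np.eye(3)
        for opid in sorted(smtry_rows):
            rows = smtry_rows[opid]
            if set(rows) != {1, 2, 3}:
                raise FormatError(f"incomplete SMTRY block for operator {opid}")
            r_orth = np.array([rows[k][:3] for k in (1, 2, 3)])
            t_orth = np.array([rows[k][3] for k in (1, 2, 3)])
            # SMTRY records are in orthogonal Å; store fractional convention.
            r_frac = f_mat @ r_orth @ o_mat
            t_frac = f_mat @ t_orth
            ops.append(SymmetryOperator.from_arrays(r_frac, t_frac))
    return models, cell, ops, saw_model


def read_structure(path, model_index: int | None = None) -> Structure:
    """Read one model from a PDB file.

    ``model_index`` counts models from 0; ``None`` means the first model.
    Raises :class:`FormatError` for files with no ATOM records and
    :class:`IndexError` for an out-of-range model index.
    """
    with open(path) as fh:
        text = fh.read()
    models, cell, ops, _ = _parse_pdb_text(text, label=str(path))
    idx = 0 if model_index is None else model_index
    if idx >= len(models) or idx < -len(models):
        raise IndexError(
            f"model index {idx} out of range: file has {len(models)} model(s)"
        )
    atoms = models[idx]
    if not atoms:
        raise FormatError(f"no ATOM records found in {path}")
    return Structure(atoms, cell=cell, symmetry_ops=ops, label=str(path))


def read_trajectory(path, template: Structure | None = None,
                    dt: float = 1.0, t0: float = 0.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory; model order defines time.

    ``dt`` is the declared stride in ps between successive models.
    """
    with open(path) as fh:
        text = fh.read()
    models, cell, ops, _ = _parse_pdb_text(text, label=str(path))
    models = [m for m in models if m]
    if not models:
        raise FormatError(f"no ATOM records found in {path}")
    if template is None:
        template = Structure(models[0], cell=cell, symmetry_ops=ops, label=str(path))
    n = len(template.atoms)
    frames = []
    for k, m in enumerate(models):
        if len(m) != n:
            raise ConsistencyError(
                f"model {k} has {len(m)} atoms, template has {n}"
            )
        frames.append(np.array([a.position for a in m]))
    times = t0 + dt * np.arange(len(frames))
    return Trajectory(template, frames, times)


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}"
    "          {element:>2s}"
)


def _format_atom(a: Atom) -> str:
    if np.any(np.abs(a.position) >= 10000.0):
        raise ValueError(
            f"coordinate magnitude >= 10000 Å not representable in PDB fixed "
            f"width (atom {a.serial} {a.name})"
        )
    name = a.name if len(a.name) >= 4 else " " + a.name
    element = "".join(ch for ch in a.name if ch.isalpha())[:1]
    return _ATOM_FMT.format(
        serial=a.serial % 100000, name=name, altloc=" ",
        resname=a.residue_name, chain=(a.chain_id or " ")[:1],
        resnum=a.residue_number, icode=a.insertion_code or " ",
        x=a.position[0], y=a.position[1], z=a.position[2],
        occ=a.occupancy, bf=a.b_factor, element=element,
    )


def _header_lines(structure: Structure) -> list:
    lines = []
    if structure.symmetry_ops:
        if structure.cell is not None:
            o_mat, f_mat = _cell_matrices(structure.cell)
        else:
            o_mat = f_mat = np.eye(3)
        for opid, op in enumerate(structure.symmetry_ops, start=1):
            r_orth = o_mat @ op.rot @ f_mat
            t_orth = o_mat @ op.trans
            for row in range(3):
                lines.append(
                    f"REMARK 290   SMTRY{row + 1} {opid:3d}"
                    f"{r_orth[row, 0]:10.6f}{r_orth[row, 1]:10.6f}"
                    f"{r_orth[row, 2]:10.6f}{t_orth[row]:15.5f}"
                )
    if structure.cell is not None:
        a, b, c, al, be, ga = structure.cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1"
        )
    return lines


def write_structure(structure: Structure, path) -> None:
    """Write a Structure to PDB text. Read-back reproduces identities and
    coordinates to 3 decimals (PDB fixed width)."""
    lines = _header_lines(structure)
    for a in structure.atoms:
        lines.append(_format_atom(a))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_trajectory(trajectory: Trajectory, path) -> None:
    lines = _header_lines(trajectory.template)
    for k, frame in enumerate(trajectory.frames):
        lines.append(f"MODEL     {k + 1:>4d}")
        for a, pos in zip(trajectory.template.atoms, frame):
            lines.append(_format_atom(replace(a, position=pos)))
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def _parse_residue_ranges(tokens: Sequence[str]) -> list:
    ranges = []
    for tok in tokens:
        if "-" in tok[1:]:  # allow negative start numbers
            lo_s, _, hi_s = tok.rpartition("-")
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise SelectionError(f"bad residue range {tok!r}")
            if lo > hi:
                raise SelectionError(f"empty residue range {tok!r}")
            ranges.append((lo, hi))
        else:
            try:
                v = int(tok)
            except ValueError:
                raise SelectionError(f"bad residue number {tok!r}")
            ranges.append((v, v))
    return ranges


def _clause_mask(structure: Structure, clause: str) -> np.ndarray:
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty selection clause")
    kw = tokens[0].lower()
    atoms = structure.atoms
    if kw == "name":
        if len(tokens) < 2:
            raise SelectionError("'name' needs at least one atom name")
        names = set(tokens[1:])
        return np.array([a.name in names for a in atoms])
    if kw == "chain":
        if len(tokens) < 2:
            raise SelectionError("'chain' needs at least one chain id")
        chains = set(tokens[1:])
        return np.array([a.chain_id in chains for a in atoms])
    if kw in ("resid", "resnum"):
        if len(tokens) < 2:
            raise SelectionError(f"'{kw}' needs residue numbers or ranges")
        ranges = _parse_residue_ranges(tokens[1:])
        return np.array([
            any(lo <= a.residue_number <= hi for lo, hi in ranges) for a in atoms
        ])
    if kw == "backbone" and len(tokens) == 1:
        return np.array([a.name in BACKBONE_NAMES for a in atoms])
    if kw in ("calpha", "ca") and len(tokens) == 1:
        return np.array([a.name == "CA" for a in atoms])
    if kw == "all" and len(tokens) == 1:
        return np.ones(len(atoms), dtype=bool)
    raise SelectionError(f"cannot parse selection clause {clause!r}")


def select_atoms(structure: Structure, selector: str) -> np.ndarray:
    """Evaluate a selection expression; returns ordered atom indices.

    Grammar: clauses joined by ``and`` / ``or``; a clause may be prefixed
    with ``not``.  Clauses: ``name N1 N2 ...``, ``chain C ...``,
    ``resid 5 7 10-20``, ``backbone``, ``calpha`` (alias ``ca``), ``all``.
    ``and`` binds tighter than ``or``.
    """
    if not isinstance(selector, str) or not selector.strip():
        raise SelectionError("selector must be a non-empty string")
    n = len(structure.atoms)
    if n == 0:
        return np.array([], dtype=int)

    def eval_clause(text: str) -> np.ndarray:
        text = text.strip()
        negate = False
        while text.lower().startswith("not "):
            negate = not negate
            text = text[4:].strip()
        mask = _clause_mask(structure, text)
        return ~mask if negate else mask

    or_parts = selector.split(" or ")
    total = np.zeros(n, dtype=bool)
    for part in or_parts:
        and_parts = part.split(" and ")
        mask = np.ones(n, dtype=bool)
        for clause in and_parts:
            mask &= eval_clause(clause)
        total |= mask
    return np.flatnonzero(total)


# ---------------------------------------------------------------------------
# Superposition and distances
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_indices: Iterable[int] | None = None):
    """Least-squares rigid superposition (Kabsch, proper rotation).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over
    ``fit_indices``; rmsd is over the fit atoms after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ConsistencyError("mobile and reference shapes differ")
    idx = (np.arange(len(mobile)) if fit_indices is None
           else np.asarray(list(fit_indices), dtype=int))
    if len(idx) < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    m = mobile[idx]
    r = reference[idx]
    mc = m - m.mean(axis=0)
    rc = r - r.mean(axis=0)
    # collinear (or coincident) fit sets have covariance rank < 2
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    h = mc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = r.mean(axis=0) - m.mean(axis=0) @ rot.T
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation).T + translation


def rmsd_series(trajectory: Trajectory, reference: Structure,
                fit_indices, measure_indices=None) -> np.ndarray:
    """Per-frame RMSD to a reference after superposing each frame on
    ``fit_indices``; measured over ``measure_indices`` (defaults to the fit
    set), which lets the flexible tails be excluded from the report."""
    ref = reference.coords
    fit = np.asarray(list(fit_indices), dtype=int)
    meas = fit if measure_indices is None else np.asarray(list(measure_indices), int)
    out = np.empty(len(trajectory.frames))
    for k, frame in enumerate(trajectory.frames):
        rot, trans, _ = superpose(frame, ref, fit)
        fitted = apply_transform(frame, rot, trans)
        out[k] = np.sqrt(np.mean(np.sum((fitted[meas] - ref[meas]) ** 2, axis=1)))
    return out


def min_residue_distance(structure: Structure, residue_a, residue_b,
                         atom_filter: str | None = None) -> float:
    """Minimum pairwise atom distance between two residues, in Å.

    Residues are addressed as ``(chain_id, residue_number)`` or
    ``(chain_id, residue_number, insertion_code)``.  ``atom_filter`` is a
    selection expression restricting which atoms of each residue count.
    """
    def _indices(res):
        chain, num = res[0], res[1]
        icode = res[2] if len(res) > 2 else ""
        return structure.residue_atom_indices(chain, num, icode)

    ia = np.array(_indices(residue_a))
    ib = np.array(_indices(residue_b))
    if atom_filter is not None:
        allowed = set(select_atoms(structure, atom_filter).tolist())
        ia = np.array([i for i in ia if i in allowed])
        ib = np.array([i for i in ib if i in allowed])
        if len(ia) == 0 or len(ib) == 0:
            raise ResidueLookupError(
                f"atom filter {atom_filter!r} leaves no atoms in one residue"
            )
    coords = structure.coords
    return float(cdist(coords[ia], coords[ib]).min())
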