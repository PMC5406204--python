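"""Contact-map collective variables.

Two CVs measure distance in contact-map space from an inactive and an
active reference conformation of the activation loop.  For a contact
``γ`` between two atoms at distance ``r`` the degree of formation is the
sigmoidal switch

    D_γ(R) = W_γ · (1 − (r/r0)^n) / (1 − (r/r0)^m),   n = 6, m = 10,

with W_γ = 1 for regular contacts and 3 for salt bridges, and r0 the
contact distance in the reference conformation the contact is specific
for.  The CV against a reference R_ref is

    CV(R) = (1/N) Σ_{γ∈Γ} (D_γ(R) − D_γ(R_ref))²,

normalized by N = Σ_γ W_γ² so that CV ∈ [0, 1): CV = 0 at the reference
itself, and large when every contact's formation degree differs maximally.
CV1 uses the inactive reference, CV2 the active one; both sum over the
full contact set Γ.

The contact set is selected from two reference ensembles: candidate pairs
are Cα/Cβ/backbone-O atoms within a distance cutoff in either reference
structure; pairs must appear in at least ``min_presence`` members of one
ensemble and fewer of the other (state-specific), pairs common to both
ensembles are discarded.  Salt-bridge pairs are supplied explicitly and
weighted 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConsistencyError, ResidueLookupError
from .structio import CV_ELIGIBLE_NAMES, Structure, Trajectory

__all__ = [
    "ContactSpec",
    "ContactSet",
    "CVRecord",
    "switching_value",
    "switching_derivative",
    "build_contact_set",
    "cv_pair",
    "cv_gradient",
    "cv_trajectory",
    "write_contacts",
    "read_contacts",
    "write_colvar",
    "read_colvar",
]

DEFAULT_N = 6
DEFAULT_M = 10
#: relative distance from r = r0 below which the series expansion is used
_SINGULARITY_TOL = 1e-6


@dataclass(frozen=True)
class ContactSpec:
    """One weighted atom-pair contact.

    Atoms are identified by ``(chain_id, residue_number, atom_name)``;
    ``r0`` is the contact distance (Å) in the reference conformation the
    contact is specific for; ``specificity`` is ``"inactive"`` or
    ``"active"``.
    """

    atom_a: tuple
    atom_b: tuple
    r0: float
    weight: float = 1.0
    specificity: str = "inactive"

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise ValueError("contact atoms must differ")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.specificity not in ("inactive", "active"):
            raise ValueError("specificity must be 'inactive' or 'active'")


def _switch_core(x: np.ndarray, n: int, m: int):
    """(1 - x^n)/(1 - x^m) with the removable singularity at x=1 handled
    by a first-order series; returns (value, d/dx)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    val = np.empty_like(x)
    der = np.empty_like(x)
    near = np.abs(x - 1.0) < _SINGULARITY_TOL
    far = ~near
    xf = x[far]
    num = 1.0 - xf**n
    den = 1.0 - xf**m
    val[far] = num / den
    der[far] = (-n * xf ** (n - 1) * den + m * xf ** (m - 1) * num) / den**2
    if np.any(near):
        t = x[near] - 1.0
        r = n / m
        val[near] = r * (1.0 + 0.5 * (n - m) * t)
        der[near] = r * 0.5 * (n - m)
    if scalar:
        return val[0], der[0]
    return val, der


def switching_value(r, r0: float, weight: float = 1.0,
                    n: int = DEFAULT_N, m: int = DEFAULT_M):
    """Degree of contact formation D(r); continuous for all r ≥ 0.

    Tends to ``weight`` as r → 0, to n/m·weight at r = r0 and to 0 as
    r → ∞.  Strictly decreasing in r for n < m.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if not n < m:
        raise ValueError("requires n < m")
    val, _ = _switch_core(np.asarray(r, float) / r0, n, m)
    return weight * val


def switching_derivative(r, r0: float, weight: float = 1.0,
                         n: int = DEFAULT_N, m: int = DEFAULT_M):
    """dD/dr of :func:`switching_value`."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    _, der = _switch_core(np.asarray(r, float) / r0, n, m)
    return weight * der / r0


@dataclass
class ContactSet:
    """The contact set Γ with its normalization and reference switch values."""

    contacts: list
    n_exponent: int = DEFAULT_N
    m_exponent: int = DEFAULT_M
    normalization: float = 0.0
    d_ref_inactive: np.ndarray | None = None
    d_ref_active: np.ndarray | None = None

    def __post_init__(self):
        if not self.n_exponent < self.m_exponent:
            raise ValueError("requires n_exponent < m_exponent")

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.contacts])

    @property
    def r0(self) -> np.ndarray:
        return np.array([c.r0 for c in self.contacts])

    def resolve_indices(self, structure: Structure):
        """Atom indices (idx_a, idx_b) of every contact in ``structure``."""
        ia, ib = [], []
        for c in self.contacts:
            try:
                ia.append(structure.atom_index(c.atom_a[0], c.atom_a[1], c.atom_a[2]))
                ib.append(structure.atom_index(c.atom_b[0], c.atom_b[1], c.atom_b[2]))
            except ResidueLookupError:
                raise ResidueLookupError(
                    f"structure lacks an atom of contact {c.atom_a} -- {c.atom_b}"
                )
        return np.array(ia, dtype=int), np.array(ib, dtype=int)

    def _switch(self, distances: np.ndarray) -> np.ndarray:
        x = distances / self.r0
        val, _ = _switch_core(x, self.n_exponent, self.m_exponent)
        return self.weights * val

    def _switch_and_derivative(self, distances: np.ndarray):
        x = distances / self.r0
        val, der = _switch_core(x, self.n_exponent, self.m_exponent)
        w = self.weights
        return w * val, w * der / self.r0

    @classmethod
    def from_contacts(cls, contacts: Sequence[ContactSpec],
                      inactive_reference: Structure,
                      active_reference: Structure,
                      n: int = DEFAULT_N, m: int = DEFAULT_M) -> "ContactSet":
        """Assemble a ContactSet, evaluating D_γ on both reference structures
        and the normalization N = Σ W²."""
        cs = cls(list(contacts), n_exponent=n, m_exponent=m)
        if not cs.contacts:
            raise ValueError("empty contact set")
        cs.normalization = float(np.sum(cs.weights**2))
        for attr, ref in (("d_ref_inactive", inactive_reference),
                          ("d_ref_active", active_reference)):
            ia, ib = cs.resolve_indices(ref)
            coords = ref.coords
            dist = np.linalg.norm(coords[ia] - coords[ib], axis=1)
            setattr(cs, attr, cs._switch(dist))
        return cs


@dataclass(frozen=True)
class CVRecord:
    time: float  # ps
    cv1: float
    cv2: float


# ---------------------------------------------------------------------------
# Contact-set selection
# ---------------------------------------------------------------------------

def _eligible_indices(structure: Structure) -> np.ndarray:
    return np.array([i for i, a in enumerate(structure.atoms)
                     if a.name in CV_ELIGIBLE_NAMES], dtype=int)


def _pairs_within(structure: Structure, indices: np.ndarray, cutoff: float):
    """Set of eligible atom-key pairs within cutoff (unordered, canonical)."""
    coords = structure.coords[indices]
    keys = [structure.atoms[i].atom_key for i in indices]
    out = set()
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    ii, jj = np.nonzero(dist < cutoff)
    for i, j in zip(ii, jj):
        if i < j:
            out.add(tuple(sorted((keys[i], keys[j]))))
    return out


def _atom_id(key: tuple) -> tuple:
    """(chain, resnum, icode, name) -> (chain, resnum, name); icode folded in."""
    chain, resnum, icode, name = key
    return (chain, resnum, name) if not icode else (chain, (resnum, icode), name)


def build_contact_set(inactive_refs: Sequence[Structure],
                      active_refs: Sequence[Structure],
                      inactive_reference: Structure,
                      active_reference: Structure,
                      cutoff: float = 5.0,
                      min_presence: int = 5,
                      salt_bridges: Sequence[tuple] | None = None,
                      salt_bridge_weight: float = 3.0) -> ContactSet:
    """Select the state-specific contact set Γ from two reference ensembles.

    Candidate pairs are Cα/Cβ/backbone-O pairs within ``cutoff`` in either
    reference structure.  A pair is inactive-specific when it is within
    cutoff in at least ``min_presence`` inactive-ensemble members and fewer
    than ``min_presence`` active-ensemble members (mirrored for
    active-specific); pairs present in both ensembles are discarded as
    common.  ``salt_bridges`` is a sequence of
    ``((atom_id_a, atom_id_b), specificity)`` pairs appended with weight 3;
    atom ids are ``(chain, resnum, atom_name)``.
    """
    for ens, ref, lbl in ((inactive_refs, inactive_reference, "inactive"),
                          (active_refs, active_reference, "active")):
        ref_keys = [a.atom_key for a in ref.atoms]
        for k, member in enumerate(ens):
            if [a.atom_key for a in member.atoms] != ref_keys:
                raise ConsistencyError(
                    f"{lbl} ensemble member {k} atom identities differ from "
                    f"the {lbl} reference structure"
                )

    elig = _eligible_indices(inactive_reference)
    candidates = (_pairs_within(inactive_reference, elig, cutoff)
                  | _pairs_within(active_reference,
                                  _eligible_indices(active_reference), cutoff))

    def presence(ensemble):
        counts = {p: 0 for p in candidates}
        for member in ensemble:
            elig_m = _eligible_indices(member)
            present = _pairs_within(member, elig_m, cutoff)
            for p in candidates:
                if p in present:
                    counts[p] += 1
        return counts

    count_in = presence(inactive_refs)
    count_ac = presence(active_refs)

    contacts = []
    for pair in sorted(candidates):
        in_ok = count_in[pair] >= min_presence
        ac_ok = count_ac[pair] >= min_presence
        if in_ok == ac_ok:  # common to both, or in neither: discard
            continue
        spec = "inactive" if in_ok else "active"
        ref = inactive_reference if in_ok else active_reference
        key_a, key_b = pair
        ia = ref.atom_index(key_a[0], key_a[1], key_a[3], key_a[2])
        ib = ref.atom_index(key_b[0], key_b[1], key_b[3], key_b[2])
        r0 = float(np.linalg.norm(ref.atoms[ia].position - ref.atoms[ib].position))
        contacts.append(ContactSpec(
            atom_a=_atom_id(key_a), atom_b=_atom_id(key_b),
            r0=r0, weight=1.0, specificity=spec,
        ))

    for (id_a, id_b), spec in (salt_bridges or []):
        ref = inactive_reference if spec == "inactive" else active_reference
        ia = ref.atom_index(id_a[0], id_a[1], id_a[2])
        ib = ref.atom_index(id_b[0], id_b[1], id_b[2])
        r0 = float(np.linalg.norm(ref.atoms[ia].position - ref.atoms[ib].position))
        contacts.append(ContactSpec(atom_a=tuple(id_a), atom_b=tuple(id_b),
                                    r0=r0, weight=salt_bridge_weight,
                                    specificity=spec))

    if not contacts:
        raise ValueError("contact selection produced an empty set Γ")
    return ContactSet.from_contacts(contacts, inactive_reference, active_reference)


# ---------------------------------------------------------------------------
# CV evaluation
# ---------------------------------------------------------------------------

def _cv_from_distances(cs: ContactSet, distances: np.ndarray):
    d_now = cs._switch(distances)
    n = cs.normalization
    cv1 = float(np.sum((d_now - cs.d_ref_inactive) ** 2) / n)
    cv2 = float(np.sum((d_now - cs.d_ref_active) ** 2) / n)
    return cv1, cv2


def cv_pair(structure_or_coords, contact_set: ContactSet,
            indices: tuple | None = None):
    """Evaluate (CV1, CV2) for a structure (or raw coordinates with
    pre-resolved contact indices)."""
    if isinstance(structure_or_coords, Structure):
        ia, ib = contact_set.resolve_indices(structure_or_coords)
        coords = structure_or_coords.coords
    else:
        if indices is None:
            raise ValueError("raw coordinates require pre-resolved indices")
        ia, ib = indices
        coords = np.asarray(structure_or_coords, dtype=float)
    distances = np.linalg.norm(coords[ia] - coords[ib], axis=1)
    return _cv_from_distances(contact_set, distances)


def cv_gradient(structure_or_coords, contact_set: ContactSet,
                which: str = "cv1", indices: tuple | None = None) -> np.ndarray:
    """Analytic Cartesian gradient of CV1 or CV2; zero rows for atoms in no
    contact."""
    if which not in ("cv1", "cv2"):
        raise ValueError("which must be 'cv1' or 'cv2'")
    if isinstance(structure_or_coords, Structure):
        ia, ib = contact_set.resolve_indices(structure_or_coords)
        coords = structure_or_coords.coords
    else:
        if indices is None:
            raise ValueError("raw coordinates require pre-resolved indices")
        ia, ib = indices
        coords = np.asarray(structure_or_coords, dtype=float)
    vec = coords[ia] - coords[ib]
    dist = np.linalg.norm(vec, axis=1)
    d_now, d_der = contact_set._switch_and_derivative(dist)
    d_ref = (contact_set.d_ref_inactive if which == "cv1"
             else contact_set.d_ref_active)
    # dCV/dr_γ = (2/N)(D_γ - D_ref,γ) dD/dr ; distribute along the bond vector
    pref = 2.0 / contact_set.normalization * (d_now - d_ref) * d_der
    unit = vec / dist[:, None]
    grad = np.zeros_like(coords)
    np.add.at(grad, ia, pref[:, None] * unit)
    np.add.at(grad, ib, -pref[:, None] * unit)
    return grad


def cv_trajectory(trajectory: Trajectory, contact_set: ContactSet,
                  stride: int = 1) -> list:
    """One CVRecord per (strided) frame."""
    ia, ib = contact_set.resolve_indices(trajectory.template)
    out = []
    for k in range(0, len(trajectory.frames), stride):
        coords = trajectory.frames[k]
        distances = np.linalg.norm(coords[ia] - coords[ib], axis=1)
        cv1, cv2 = _cv_from_distances(contact_set, distances)
        out.append(CVRecord(time=float(trajectory.times[k]), cv1=cv1, cv2=cv2))
    return out


# ---------------------------------------------------------------------------
# Text interchange
# ---------------------------------------------------------------------------

_CONTACT_HEADER = ("chain_a\tresnum_a\tatom_a\tchain_b\tresnum_b\tatom_b\t"
                   "r0\tweight\tspecificity")


def write_contacts(contacts: Sequence[ContactSpec], path) -> None:
    """Contact list as delimited text; bit-exact round-trip (r0 via repr)."""
    lines = [_CONTACT_HEADER]
    for c in contacts:
        lines.append("\t".join([
            str(c.atom_a[0]), str(c.atom_a[1]), c.atom_a[2],
            str(c.atom_b[0]), str(c.atom_b[1]), c.atom_b[2],
            repr(float(c.r0)), repr(float(c.weight)), c.specificity,
        ]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_contacts(path) -> list:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0] != _CONTACT_HEADER:
        raise ConsistencyError(f"{path} is not a contact-set file")
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        out.append(ContactSpec(
            atom_a=(f[0], int(f[1]), f[2]),
            atom_b=(f[3], int(f[4]), f[5]),
            r0=float(f[6]), weight=float(f[7]), specificity=f[8],
        ))
    return out


def write_colvar(records: Sequence[CVRecord], path) -> None:
    """COLVAR-style CV time series."""
    lines = ["#! FIELDS time cv1 cv2"]
    for r in records:
        lines.append(f"{r.time:.6f} {r.cv1:.10f} {r.cv2:.10f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_colvar(path) -> list:
    out = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            t, c1, c2 = ln.split()[:3]
            out.append(CVRecord(float(t), float(c1), float(c2)))
    return out
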