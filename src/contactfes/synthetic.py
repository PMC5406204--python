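"""Synthetic fixtures with machine-readable ground truth.

Every generator is deterministic given its seed, and every planted
quantity (state-specific contacts, basin labels, occupancies, crystal
contacts, fluctuation variances) is returned in a manifest dictionary so
recovery tests never re-derive ground truth from generator internals.

The fixtures are coarse-grained — three atoms per residue (Cα, Cβ,
backbone O; glycine lacks Cβ) on a self-avoiding random walk.  That is
enough to exercise every selector, contact rule and distance criterion in
the analysis machinery without force-field realism.

Two-state references: both reference conformations share a near-straight
backbone and differ only in the Cβ atoms of planted contact pairs, which
bridge an (i, i+2) residue pair at ≈4.3 Å in the state the contact is
specific for and are splayed apart (>7.5 Å) in the other.  The placement
geometry is chosen so that every non-planted atom pair keeps the same
side of the 5 Å contact cutoff in both states, which makes the
contact-selection rules recover exactly the planted state-specific pairs;
a final presence-count verification (with independent distance counting)
re-draws the ensemble noise if a marginal pair ever flips.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._units import KB_KCAL
from .contact_cv import ContactSet, CVRecord, cv_pair
from .errors import ConstraintError
from .sampling import GaussianWellPotential
from .structio import Atom, Structure, Trajectory
from .crystal import fractional_orthogonal, spacegroup_operators

__all__ = [
    "TwoStateSpec",
    "LandscapeSpec",
    "make_toy_chain",
    "random_two_state_spec",
    "make_two_state_references",
    "sample_landscape_trajectory",
    "make_basin_structures",
    "plant_saltbridge_occupancy",
    "make_crystal_fixture",
    "make_harmonic_trajectory",
    "write_manifest",
]

_CA_CA = 3.8       # Å, consecutive Cα distance
_CA_CB = 1.53      # Å
_CA_O = 2.40       # Å
_CONTACT_TARGET = 4.3   # planted contact distance in the specific state
_FAR_MIN = 7.4          # minimum splayed-state distance for a planted pair
_SAFE_LOW = 4.6         # reference-level margin below the 5 Å cutoff


@dataclass
class TwoStateSpec:
    """Recipe for a pair of reference ensembles with planted contacts.

    Planted contacts are ``(resnum_a, resnum_a + 2)`` residue pairs whose
    Cβ atoms bridge in the relevant state.  Residues may appear in at
    most one planted pair.
    """

    n_residues: int = 21
    planted_inactive_contacts: tuple = ()
    planted_active_contacts: tuple = ()
    common_contacts: tuple = ()
    ensemble_size: int = 10
    coordinate_noise: float = 0.12   # Å, per coordinate
    hinge_angle: float = 60.0        # degrees; inter-state backbone bend
    seed: int = 0
    chain_id: str = "A"

    def __post_init__(self):
        used = []
        for pair in (*self.planted_inactive_contacts,
                     *self.planted_active_contacts, *self.common_contacts):
            used.extend(pair)
        if len(set(used)) != len(used):
            raise ValueError("planted pairs must not share residues")
        if self.coordinate_noise < 0:
            raise ValueError("noise must be >= 0")


@dataclass
class LandscapeSpec:
    """Analytic 2-D landscape with known well thermodynamics."""

    centers: tuple = ((0.25, 0.5), (0.75, 0.5))
    depths: tuple = (6.0, 3.0)        # kcal/mol below the plateau
    widths: tuple = (0.12, 0.12)
    temperature: float = 300.0
    domain: tuple = ((0.0, 1.0), (0.0, 1.0))

    def __post_init__(self):
        for c in self.centers:
            if not all(0.0 <= x <= 1.0 for x in c):
                raise ValueError("well centers must lie inside [0,1]^2")
        if any(d <= 0 for d in self.depths):
            raise ValueError("well depths (barriers) must be positive")

    def potential(self) -> GaussianWellPotential:
        return GaussianWellPotential(self.centers, self.depths, self.widths,
                                     domain=self.domain)


# ---------------------------------------------------------------------------
# Coarse chain
# ---------------------------------------------------------------------------

def make_toy_chain(n_residues: int, seed: int = 0, chain_id: str = "A",
                   gly_every: int = 0) -> Structure:
    """Coarse self-avoiding chain: Cα, Cβ (except Gly) and backbone O per
    residue; consecutive Cα at 3.8 Å; deterministic per seed."""
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    ca = np.zeros((n_residues, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_residues):
        for _ in range(300):
            # mildly persistent walk with a weak pull toward the centroid,
            # so the chain folds back and offers mid-range residue pairs
            centroid = ca[:i].mean(axis=0)
            away = ca[i - 1] - centroid
            norm = np.linalg.norm(away)
            pull = -0.5 * away / norm if norm > 1e-9 else 0.0
            trial = 0.3 * direction + rng.standard_normal(3) + pull
            trial /= np.linalg.norm(trial)
            pos = ca[i - 1] + _CA_CA * trial
            if i < 2 or np.all(np.linalg.norm(ca[:i - 1] - pos, axis=1) > 4.2):
                ca[i] = pos
                direction = trial
                break
        else:
            raise ConstraintError(f"self-avoiding walk stuck at residue {i}")

    atoms = []
    serial = 1
    for i in range(n_residues):
        resnum = i + 1
        is_gly = gly_every > 0 and resnum % gly_every == 0
        resname = "GLY" if is_gly else "ALA"
        # local frame perpendicular to the chain
        prev_v = ca[i] - ca[i - 1] if i > 0 else ca[i + 1] - ca[i]
        prev_v = prev_v / np.linalg.norm(prev_v)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, prev_v)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = np.cross(prev_v, ref)
        perp /= np.linalg.norm(perp)
        perp2 = np.cross(prev_v, perp)
        atoms.append(Atom(serial, "CA", resname, resnum, chain_id, ca[i].copy()))
        serial += 1
        if not is_gly:
            atoms.append(Atom(serial, "CB", resname, resnum, chain_id,
                              ca[i] + _CA_CB * perp))
            serial += 1
        atoms.append(Atom(serial, "O", resname, resnum, chain_id,
                          ca[i] + _CA_O * perp2))
        serial += 1
    return Structure(atoms, label=f"toy_chain(n={n_residues},seed={seed})")


# ---------------------------------------------------------------------------
# Two-state reference ensembles
# ---------------------------------------------------------------------------

def _straight_chain(n_residues: int, seed: int, chain_id: str = "A"):
    """Near-straight coarse chain with transported local frames.

    Returns ``(structure, ca, u, n, m)`` where u is the local chain
    direction and (n, m) an orthonormal frame perpendicular to it,
    parallel-transported along the chain.  Standard side positions:
    Cβ = Cα + 0.9·n, O = Cα + 1.0·m.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1, 1)))
    ca = np.zeros((n_residues, 3))
    u = np.zeros((n_residues, 3))
    n_vec = np.zeros((n_residues, 3))
    m_vec = np.zeros((n_residues, 3))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    normal = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(normal) < 0.1:
        normal = np.cross(direction, [0.0, 1.0, 0.0])
    normal /= np.linalg.norm(normal)
    for i in range(n_residues):
        if i > 0:
            direction = direction + 0.08 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            ca[i] = ca[i - 1] + _CA_CA * direction
            normal = normal - np.dot(normal, direction) * direction
            normal /= np.linalg.norm(normal)
        u[i] = direction
        n_vec[i] = normal
        m_vec[i] = np.cross(direction, normal)

    atoms = []
    serial = 1
    for i in range(n_residues):
        resnum = i + 1
        atoms.append(Atom(serial, "CA", "ALA", resnum, chain_id, ca[i].copy()))
        serial += 1
        atoms.append(Atom(serial, "CB", "ALA", resnum, chain_id,
                          ca[i] + 0.9 * n_vec[i]))
        serial += 1
        atoms.append(Atom(serial, "O", "ALA", resnum, chain_id,
                          ca[i] + 1.0 * m_vec[i]))
        serial += 1
    struct = Structure(atoms, label=f"two_state_chain(n={n_residues},seed={seed})")
    return struct, ca, u, n_vec, m_vec


def random_two_state_spec(n_residues: int = 21, n_inactive: int = 2,
                          n_active: int = 2, n_common: int = 1,
                          seed: int = 0, ensemble_size: int = 10,
                          coordinate_noise: float = 0.1,
                          max_attempts: int = 20) -> TwoStateSpec:
    """Pick planted (i, i+2) pairs at random among the non-overlapping
    slots of the chain and return a verified spec."""
    need = n_inactive + n_active + n_common
    hinge = n_residues // 2 + 1
    slots = [(s, s + 2) for s in range(1, n_residues - 1, 4)
             if not s <= hinge < s + 2]
    if len(slots) < need:
        raise ValueError(
            f"{n_residues} residues offer only {len(slots)} planted-pair "
            f"slots, {need} needed"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))
    for attempt in range(max_attempts):
        chain_seed = seed if attempt == 0 else int(rng.integers(0, 2**31 - 1))
        order = rng.permutation(len(slots))
        chosen = [slots[k] for k in order[:need]]
        spec = TwoStateSpec(
            n_residues=n_residues,
            planted_inactive_contacts=tuple(chosen[:n_inactive]),
            planted_active_contacts=tuple(chosen[n_inactive:n_inactive + n_active]),
            common_contacts=tuple(chosen[n_inactive + n_active:]),
            ensemble_size=ensemble_size,
            coordinate_noise=coordinate_noise,
            seed=chain_seed,
        )
        try:
            make_two_state_references(spec)
        except ConstraintError:
            continue
        return spec
    raise ConstraintError(
        f"no feasible fixture found in {max_attempts} attempts"
    )


# offsets of a planted pair's Cβ atoms, worked out so every non-planted
# atom pair stays on one side of the 5 Å cutoff in both states
_BRIDGE_T_LOW = 0.9     # lower residue's Cβ, along the pair axis
_FAR_N_LOW = 2.5        # lower residue's Cβ, splayed along +n
_FAR_W_HIGH = 1.5       # upper residue's Cβ, pulled back along the axis
_FAR_N_HIGH = 2.2       # upper residue's Cβ, splayed along −n


def _place_pair(coords, chain, cid, n_vec, ra, rb, bridged: bool) -> None:
    ia_ca = chain.atom_index(cid, ra, "CA")
    ib_ca = chain.atom_index(cid, rb, "CA")
    ia_cb = chain.atom_index(cid, ra, "CB")
    ib_cb = chain.atom_index(cid, rb, "CB")
    pa, pb = coords[ia_ca], coords[ib_ca]
    w = pb - pa
    d = np.linalg.norm(w)
    w = w / d
    if bridged:
        gap = d - _CONTACT_TARGET - _BRIDGE_T_LOW
        if gap <= 0:
            raise ConstraintError(f"residues {ra},{rb} too close to bridge")
        coords[ia_cb] = pa + _BRIDGE_T_LOW * w
        coords[ib_cb] = pb - gap * w
    else:
        coords[ia_cb] = pa + _FAR_N_LOW * n_vec[ra - 1]
        coords[ib_cb] = pb - _FAR_W_HIGH * w - _FAR_N_HIGH * n_vec[rb - 1]


def _eligible_pair_distances(structure: Structure, coords: np.ndarray):
    idx = [i for i, a in enumerate(structure.atoms) if a.name in ("CA", "CB", "O")]
    idx = np.asarray(idx, int)
    sub = coords[idx]
    diff = sub[:, None, :] - sub[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return idx, dist


def make_two_state_references(spec: TwoStateSpec):
    """Build the two reference ensembles and reference structures.

    Returns ``(inactive_ensemble, active_ensemble, inactive_ref,
    active_ref, manifest)``.  The manifest records the planted
    state-specific and common Cβ–Cβ pairs as atom-identity tuples.
    Raises :class:`ConstraintError` when the planted geometry cannot be
    realized with safe margins.
    """
    cid = spec.chain_id
    for ra, rb in (*spec.planted_inactive_contacts,
                   *spec.planted_active_contacts, *spec.common_contacts):
        if rb - ra != 2:
            raise ValueError(f"planted pairs must be (i, i+2); got ({ra}, {rb})")
        if ra < 1 or rb > spec.n_residues:
            raise ValueError(f"pair ({ra}, {rb}) outside the chain")
    chain, ca, u, n_vec, m_vec = _straight_chain(spec.n_residues, spec.seed,
                                                 chain_id=cid)
    base = chain.coords

    # the active state bends the chain rigidly at a mid-chain hinge: a large
    # backbone RMSD between the states (so basin clustering can tell them
    # apart) without moving any atom pair across the 5 Å contact cutoff
    hinge = spec.n_residues // 2 + 1
    for ra, rb in (*spec.planted_inactive_contacts,
                   *spec.planted_active_contacts, *spec.common_contacts):
        if ra <= hinge < rb:
            raise ValueError(
                f"planted pair ({ra}, {rb}) spans the hinge residue {hinge}"
            )
    theta = np.radians(spec.hinge_angle)
    axis = m_vec[hinge - 1]
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx
    center = ca[hinge - 1]
    arm = np.array([i for i, a in enumerate(chain.atoms)
                    if a.residue_number > hinge], int)
    bent = base.copy()
    bent[arm] = (bent[arm] - center) @ rot.T + center
    n_vec_ac = n_vec.copy()
    n_vec_ac[hinge:] = n_vec[hinge:] @ rot.T

    coords_in = base.copy()
    coords_ac = bent.copy()
    for ra, rb in spec.planted_inactive_contacts:
        _place_pair(coords_in, chain, cid, n_vec, ra, rb, bridged=True)
        _place_pair(coords_ac, chain, cid, n_vec_ac, ra, rb, bridged=False)
    for ra, rb in spec.planted_active_contacts:
        _place_pair(coords_ac, chain, cid, n_vec_ac, ra, rb, bridged=True)
        _place_pair(coords_in, chain, cid, n_vec, ra, rb, bridged=False)
    for ra, rb in spec.common_contacts:
        _place_pair(coords_in, chain, cid, n_vec, ra, rb, bridged=True)
        _place_pair(coords_ac, chain, cid, n_vec_ac, ra, rb, bridged=True)

    def pair_key(ra, rb):
        return tuple(sorted([(cid, ra, "CB"), (cid, rb, "CB")]))

    planted = {}
    for ra, rb in spec.planted_inactive_contacts:
        planted[pair_key(ra, rb)] = "inactive"
    for ra, rb in spec.planted_active_contacts:
        planted[pair_key(ra, rb)] = "active"
    common = {pair_key(ra, rb) for ra, rb in spec.common_contacts}

    # reference-level margin check for the planted pairs themselves
    idx, dist_in = _eligible_pair_distances(chain, coords_in)
    _, dist_ac = _eligible_pair_distances(chain, coords_ac)
    keys = [chain.atoms[i].atom_key for i in idx]
    pos_of = {(k[0], k[1], k[3]): p for p, k in enumerate(keys)}
    for key, state in planted.items():
        a, b = pos_of[key[0]], pos_of[key[1]]
        near, far = ((dist_in[a, b], dist_ac[a, b]) if state == "inactive"
                     else (dist_ac[a, b], dist_in[a, b]))
        if near > _SAFE_LOW or far < _FAR_MIN:
            raise ConstraintError(
                f"planted pair {key} margins violated "
                f"(near {near:.2f} Å, far {far:.2f} Å)"
            )

    ref_in = chain.with_coords(coords_in, label="inactive_reference")
    ref_ac = chain.with_coords(coords_ac, label="active_reference")

    # draw ensemble noise; verify (with independent distance counting) that
    # the planted contract holds in every member and that no incidental
    # pair ends up classified state-specific — re-draw on a failure
    ens_in = ens_ac = None
    for attempt in range(20):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(4, attempt)))

        def ensemble(ref_coords, label):
            members = []
            for k in range(spec.ensemble_size):
                noise = spec.coordinate_noise * rng.standard_normal(ref_coords.shape)
                members.append(chain.with_coords(ref_coords + noise,
                                                 label=f"{label}_{k}"))
            return members

        cand_in = ensemble(coords_in, "inactive")
        cand_ac = ensemble(coords_ac, "active")
        if _two_state_fixture_ok(chain, cand_in, cand_ac, planted, common,
                                 min_presence=spec.ensemble_size // 2):
            ens_in, ens_ac = cand_in, cand_ac
            break
    if ens_in is None:
        raise ConstraintError(
            "could not draw ensemble noise keeping the planted classification "
            "exact; the chain geometry crowds the contact cutoff"
        )

    manifest = {
        "seed": spec.seed,
        "planted_inactive": sorted(
            [list(map(list, k)) for k, v in planted.items() if v == "inactive"]),
        "planted_active": sorted(
            [list(map(list, k)) for k, v in planted.items() if v == "active"]),
        "planted_common": sorted([list(map(list, k)) for k in common]),
        "contact_target": _CONTACT_TARGET,
        "ensemble_size": spec.ensemble_size,
        "coordinate_noise": spec.coordinate_noise,
    }
    return ens_in, ens_ac, ref_in, ref_ac, manifest


def _two_state_fixture_ok(chain, ens_in, ens_ac, planted, common,
                          min_presence: int, cutoff: float = 5.0,
                          far: float = 7.0) -> bool:
    """Independent presence-count check of the planted classification."""
    idx = np.array([i for i, a in enumerate(chain.atoms)
                    if a.name in ("CA", "CB", "O")], int)
    ids = [(chain.atoms[i].chain_id, chain.atoms[i].residue_number,
            chain.atoms[i].name) for i in idx]

    def distances(member):
        sub = member.coords[idx]
        diff = sub[:, None, :] - sub[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    d_in = np.array([distances(m) for m in ens_in])
    d_ac = np.array([distances(m) for m in ens_ac])
    count_in = (d_in < cutoff).sum(axis=0)
    count_ac = (d_ac < cutoff).sum(axis=0)

    specific = {}
    n = len(idx)
    for a in range(n):
        for b in range(a + 1, n):
            in_ok = count_in[a, b] >= min_presence
            ac_ok = count_ac[a, b] >= min_presence
            if in_ok != ac_ok:
                key = tuple(sorted([ids[a], ids[b]]))
                specific[key] = "inactive" if in_ok else "active"
    if specific != planted:
        return False
    pos_of = {k: p for p, k in enumerate(ids)}
    for key, state in planted.items():
        a, b = pos_of[key[0]], pos_of[key[1]]
        near, far_d = ((d_in[:, a, b], d_ac[:, a, b]) if state == "inactive"
                       else (d_ac[:, a, b], d_in[:, a, b]))
        if np.any(near >= cutoff) or np.any(far_d <= far):
            return False
    for key in common:
        a, b = pos_of[key[0]], pos_of[key[1]]
        if count_in[a, b] < min_presence or count_ac[a, b] < min_presence:
            return False
    return True


# ---------------------------------------------------------------------------
# CV-space samplers and basin-structured trajectories
# ---------------------------------------------------------------------------

def sample_landscape_trajectory(spec: LandscapeSpec, n_frames: int,
                                seed: int = 0, thin: int = 5,
                                frame_interval: float = 1.0):
    """Boltzmann sampling of an analytic landscape by independence
    Metropolis–Hastings.

    Proposals mix a uniform draw over the domain with Gaussians centered
    on the wells, so acceptance stays high even for wells many k_B·T
    deep; the chain is thinned so recorded frames are effectively
    independent.  Returns ``(records, labels, manifest)``; a frame's
    ground-truth label is the index of the nearest well center.
    """
    pot = spec.potential()
    kt = KB_KCAL * spec.temperature
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(5,)))
    (lo1, hi1), (lo2, hi2) = spec.domain
    centers = np.array(spec.centers)
    widths = np.resize(np.asarray(spec.widths, float), len(centers))
    area = (hi1 - lo1) * (hi2 - lo2)
    p_uniform = 0.3

    def q_density(y):
        gauss = np.exp(-np.sum((y[None, :] - centers) ** 2, axis=1)
                       / (2.0 * widths**2)) / (2.0 * np.pi * widths**2)
        return p_uniform / area + (1 - p_uniform) * float(np.mean(gauss))

    def propose():
        while True:
            if rng.random() < p_uniform:
                y = np.array([rng.uniform(lo1, hi1), rng.uniform(lo2, hi2)])
            else:
                i = rng.integers(len(centers))
                y = centers[i] + widths[i] * rng.standard_normal(2)
            if lo1 <= y[0] <= hi1 and lo2 <= y[1] <= hi2:
                return y

    x = np.array(spec.centers[0], float)
    e = pot.value(x)
    qx = q_density(x)
    records, labels = [], []
    for k in range(n_frames):
        for _ in range(thin):
            y = propose()
            e_y = pot.value(y)
            qy = q_density(y)
            log_alpha = -(e_y - e) / kt + math.log(qx) - math.log(qy)
            if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
                x, e, qx = y, e_y, qy
        records.append(CVRecord(time=k * frame_interval, cv1=float(x[0]),
                                cv2=float(x[1])))
        labels.append(int(np.argmin(np.sum((centers - x) ** 2, axis=1))))
    manifest = {
        "seed": seed,
        "centers": [list(c) for c in spec.centers],
        "depths": list(spec.depths),
        "temperature": spec.temperature,
        "boltzmann_weights": _well_weights(spec),
    }
    return records, np.array(labels), manifest


def _well_weights(spec: LandscapeSpec):
    """Analytic relative Boltzmann weights of equal-width Gaussian wells
    (harmonic approximation is exact in the ratio only for equal widths;
    we integrate numerically instead)."""
    pot = spec.potential()
    kt = KB_KCAL * spec.temperature
    (lo1, hi1), (lo2, hi2) = spec.domain
    ax1 = np.linspace(lo1, hi1, 201)
    ax2 = np.linspace(lo2, hi2, 201)
    g1, g2 = np.meshgrid(ax1, ax2, indexing="ij")
    pts = np.stack([g1.ravel(), g2.ravel()], axis=1)
    vals = np.array([pot.value(p) for p in pts])
    centers = np.array(spec.centers)
    lab = np.argmin(
        ((pts[:, None, :] - centers[None]) ** 2).sum(axis=2), axis=1)
    w = np.exp(-(vals - vals.min()) / kt)
    totals = [float(w[lab == i].sum()) for i in range(len(centers))]
    s = sum(totals)
    return [t / s for t in totals]


def make_basin_structures(two_state_refs, cv_targets, frames_per_target: int,
                          contact_set: ContactSet, seed: int = 0,
                          noise: float = 0.08, cv_tolerance: float = 0.05,
                          max_attempts: int = 400):
    """Frames populating prescribed CV-space targets.

    Frames are built by interpolating between the inactive and active
    reference structures plus coordinate noise, accepted when their
    computed CVs land within ``cv_tolerance`` of the target.  Returns
    ``(trajectory, labels, manifest)`` with one label per frame giving
    its target index.
    """
    ref_in, ref_ac = two_state_refs
    ci, ca = ref_in.coords, ref_ac.coords
    idx = contact_set.resolve_indices(ref_in)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(6,)))

    lambdas = np.linspace(0.0, 1.0, 201)
    curve = np.array([
        cv_pair((1 - lam) * ci + lam * ca, contact_set, indices=idx)
        for lam in lambdas
    ])

    frames, labels = [], []
    for t_idx, (t1, t2) in enumerate(cv_targets):
        best = int(np.argmin((curve[:, 0] - t1) ** 2 + (curve[:, 1] - t2) ** 2))
        lam0 = lambdas[best]
        got = 0
        for _ in range(max_attempts * frames_per_target):
            lam = float(np.clip(lam0 + 0.02 * rng.standard_normal(), 0, 1))
            coords = (1 - lam) * ci + lam * ca \
                + noise * rng.standard_normal(ci.shape)
            c1, c2 = cv_pair(coords, contact_set, indices=idx)
            if abs(c1 - t1) <= cv_tolerance and abs(c2 - t2) <= cv_tolerance:
                frames.append(coords)
                labels.append(t_idx)
                got += 1
                if got == frames_per_target:
                    break
        if got < frames_per_target:
            raise ConstraintError(
                f"target {(t1, t2)} unreachable: only {got}/{frames_per_target} "
                f"frames accepted (closest curve point {tuple(curve[best])})"
            )
    traj = Trajectory(ref_in, frames)
    manifest = {"seed": seed, "cv_targets": [list(t) for t in cv_targets],
                "frames_per_target": frames_per_target,
                "labels": [int(l) for l in labels]}
    return traj, np.array(labels), manifest


def plant_saltbridge_occupancy(trajectory: Trajectory, pair,
                               target_occupancy: float, seed: int = 0,
                               contact_distance: float = 3.2,
                               apart_distance: float = 7.0,
                               atom_name: str = "CB"):
    """Per frame, place the pair's side-chain atoms in contact with
    probability ``target_occupancy`` (else well apart), independently.

    ``pair`` is ``((chain, resnum), (chain, resnum))``.  Returns
    ``(trajectory, formed_mask, manifest)``.
    """
    if not 0.0 <= target_occupancy <= 1.0:
        raise ValueError("target occupancy must be in [0, 1]")
    (ca_chain, ra), (cb_chain, rb) = pair
    tmpl = trajectory.template
    ia = tmpl.atom_index(ca_chain, ra, atom_name)
    ib = tmpl.atom_index(cb_chain, rb, atom_name)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(7,)))
    new_frames = []
    formed = np.zeros(len(trajectory.frames), dtype=bool)
    for k, frame in enumerate(trajectory.frames):
        f = frame.copy()
        u = f[ib] - f[ia]
        n = np.linalg.norm(u)
        u = u / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
        formed[k] = rng.random() < target_occupancy
        f[ib] = f[ia] + (contact_distance if formed[k] else apart_distance) * u
        new_frames.append(f)
    traj = Trajectory(tmpl, new_frames, trajectory.times.copy())
    manifest = {"seed": seed, "pair": [list(pair[0]), list(pair[1])],
                "target_occupancy": target_occupancy,
                "n_formed": int(formed.sum()),
                "n_frames": len(formed)}
    return traj, formed, manifest


# ---------------------------------------------------------------------------
# Crystal fixture
# ---------------------------------------------------------------------------

def _reciprocal_image(ops, op_id: int, shift):
    """The (operator, shift) under which the reverse residue pair of a
    planted contact appears in the contact map."""
    r_inv = np.linalg.inv(ops[op_id].rot)
    tt = -r_inv @ (ops[op_id].trans + np.asarray(shift, float))
    for j, opj in enumerate(ops):
        if np.allclose(opj.rot, r_inv, atol=1e-9):
            s2 = tt - opj.trans
            if np.allclose(s2, np.round(s2), atol=1e-6):
                return j, tuple(int(round(x)) for x in s2)
    raise ConstraintError("operator set is not closed under inversion")


def make_crystal_fixture(asu_size: int = 6, spacegroup: str = "P212121",
                         planted_contact_pairs: Sequence = (),
                         seed: int = 0, contact_distance: float = 3.5,
                         clearance: float = 6.0, criterion: float = 4.0):
    """Toy crystal: a compact ASU in a roomy cell, with chosen residue
    pairs touching specific symmetry images at < 4 Å and every other
    inter-image residue pair clear of the contact criterion.

    Planted entries are ``(resnum_a, resnum_b, operator_index,
    lattice_shift)``: residue ``resnum_b`` is rigidly translated so that
    the image of its Cβ under the given operator and shift sits
    ``contact_distance`` from residue ``resnum_a``'s Cβ in the ASU.
    Returns ``(structure, manifest)``; the manifest's
    ``expected_contacts`` lists every (asu residue, neighbor residue,
    operator, shift) entry a 4 Å contact map should report — each planted
    contact plus its reciprocal image.
    """
    ops = spacegroup_operators(spacegroup)
    # sparse, near-straight ASU: small residue footprint keeps un-planted
    # images clear of the criterion
    chain, _, u_vec, n_vec, m_vec = _straight_chain(asu_size, seed, chain_id="A")
    coords = chain.coords
    extent = float(np.max(coords.max(axis=0) - coords.min(axis=0))) + 2 * clearance
    cell_len = max(4.0 * extent, 60.0)
    cell = (cell_len, cell_len, cell_len, 90.0, 90.0, 90.0)
    # park the ASU well inside the cell so un-planted images stay remote
    coords = coords - coords.mean(axis=0) + 0.25 * cell_len

    o_mat = fractional_orthogonal(cell, "to_orth")
    f_mat = fractional_orthogonal(cell, "to_frac")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(8,)))

    planted_records = []
    for ra, rb, op_id, shift in planted_contact_pairs:
        if not 0 <= op_id < len(ops):
            raise ConstraintError(f"operator index {op_id} out of range")
        op = ops[op_id]
        if op.is_identity() and tuple(shift) == (0, 0, 0):
            raise ConstraintError("planted image must not be the identity copy")
        ia = chain.atom_index("A", ra, "CB")
        ib = chain.atom_index("A", rb, "CB")
        shift = np.asarray(shift, float)
        # linear map from an ASU displacement to its image displacement
        m = o_mat @ op.rot @ f_mat
        for _ in range(200):
            # approach mostly perpendicular to the chain axis, away from
            # the neighboring residues
            theta = rng.uniform(0.0, 2.0 * np.pi)
            direction = (np.cos(theta) * n_vec[ra - 1]
                         + np.sin(theta) * m_vec[ra - 1]
                         + 0.25 * rng.standard_normal(3))
            direction /= np.linalg.norm(direction)
            target = coords[ia] + contact_distance * direction
            img_b = (op.apply_frac(coords[ib] @ f_mat.T) + shift) @ o_mat.T
            delta = np.linalg.solve(m, target - img_b)
            res_idx = chain.residue_atom_indices("A", rb)
            trial = coords.copy()
            trial[res_idx] += delta
            if _fixture_ok(trial, chain, cell, ops, planted_records
                           + [(ra, rb, op_id, tuple(int(s) for s in shift))],
                           contact_distance, criterion):
                coords = trial
                break
        else:
            raise ConstraintError(
                f"could not place planted contact {ra}-{rb} via operator "
                f"{op_id} shift {tuple(shift)}"
            )
        planted_records.append((ra, rb, op_id, tuple(int(s) for s in shift)))

    if not _fixture_ok(coords, chain, cell, ops, planted_records,
                       contact_distance, criterion):
        raise ConstraintError("fixture verification failed")

    struct = Structure([replace(a, position=c) for a, c in
                        zip(chain.atoms, coords)],
                       cell=cell, symmetry_ops=ops,
                       label=f"crystal_fixture({spacegroup},seed={seed})")
    expected = []
    for ra, rb, op_id, shift in planted_records:
        expected.append({"residue_a": ra, "residue_b": rb,
                         "operator": op_id, "shift": list(shift)})
        rj, sj = _reciprocal_image(ops, op_id, shift)
        expected.append({"residue_a": rb, "residue_b": ra,
                         "operator": rj, "shift": list(sj)})
    manifest = {
        "seed": seed, "spacegroup": spacegroup,
        "cell": list(cell), "n_operators": len(ops),
        "planted_contacts": [
            {"residue_a": ra, "residue_b": rb, "operator": op_id,
             "shift": list(shift)}
            for ra, rb, op_id, shift in planted_records
        ],
        "expected_contacts": expected,
        "contact_distance": contact_distance,
        "criterion": criterion,
    }
    return struct, manifest


def _fixture_ok(coords, chain, cell, ops, planted, contact_distance,
                criterion, margin: float = 0.5) -> bool:
    """Brute-force check: planted images (and their reciprocal views) in
    contact, every other inter-image residue pair clear of the criterion."""
    o_mat = fractional_orthogonal(cell, "to_orth")
    f_mat = fractional_orthogonal(cell, "to_frac")
    frac = coords @ f_mat.T
    res_keys = chain.residues()
    res_idx = {k: np.array(chain.residue_atom_indices(*k)) for k in res_keys}
    allowed = set()
    for ra, rb, op_id, shift in planted:
        allowed.add((ra, rb, op_id, tuple(shift)))
        rj, sj = _reciprocal_image(ops, op_id, shift)
        allowed.add((rb, ra, rj, sj))
    for sa in (-1, 0, 1):
        for sb in (-1, 0, 1):
            for sc in (-1, 0, 1):
                for op_id, op in enumerate(ops):
                    if op.is_identity() and sa == sb == sc == 0:
                        continue
                    img = (op.apply_frac(frac)
                           + np.array([sa, sb, sc], float)) @ o_mat.T
                    for ka in res_keys:
                        for kb in res_keys:
                            d = float(np.min(np.linalg.norm(
                                coords[res_idx[ka]][:, None, :]
                                - img[res_idx[kb]][None, :, :], axis=2)))
                            tag = (ka[1], kb[1], op_id, (sa, sb, sc))
                            if tag in allowed:
                                if d > contact_distance + margin:
                                    return False
                            elif d < criterion + margin:
                                return False
    return True


# ---------------------------------------------------------------------------
# Harmonic-fluctuation trajectories
# ---------------------------------------------------------------------------

def make_harmonic_trajectory(structure: Structure, per_atom_stiffness,
                             temperature: float = 300.0,
                             n_frames: int = 1000, seed: int = 0):
    """Frames with i.i.d. Gaussian displacements per atom, per-coordinate
    variance k_B·T/k (stiffness in kcal/mol/Å²).

    Returns ``(trajectory, manifest)``; the manifest records the expected
    RMSF sqrt(3·k_B·T/k) per atom.
    """
    k = np.broadcast_to(np.asarray(per_atom_stiffness, float),
                        (len(structure.atoms),)).copy()
    if np.any(k <= 0):
        raise ValueError("stiffness must be positive")
    sigma = np.sqrt(KB_KCAL * temperature / k)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(9,)))
    ref = structure.coords
    frames = [ref + sigma[:, None] * rng.standard_normal(ref.shape)
              for _ in range(n_frames)]
    traj = Trajectory(structure, frames)
    manifest = {"seed": seed, "temperature": temperature,
                "stiffness": k.tolist(),
                "expected_rmsf": np.sqrt(3.0 * KB_KCAL * temperature / k).tolist()}
    return traj, manifest


def write_manifest(manifest: dict, path) -> None:
    """Sidecar ground-truth manifest as JSON text."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
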