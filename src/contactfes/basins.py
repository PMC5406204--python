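"""Basin-population analysis: frame assignment, gromos clustering,
representative (medoid) structures, interaction occupancies and distance
histograms.

Clustering follows the gromos algorithm: repeatedly take the frame with
the most neighbors within an RMSD cutoff (Cα RMSD after pairwise
superposition, cutoff 2 Å by default), form a cluster from it and its
neighbors, remove them, and iterate.  The representative of a cluster is
its medoid — the member with the smallest summed RMSD to all other
members.

Interaction occupancies are the fraction of a cluster's frames in which a
residue pair's minimal filtered distance is within a cutoff; pairs above
75% are classified *strong*, pairs in the 60–75% band *weak*, the rest
*below* (excluded from the default report).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .contact_cv import CVRecord
from .errors import ResidueLookupError
from .fes import Basin, FESGrid
from .structio import Structure, Trajectory, select_atoms, superpose

__all__ = [
    "Cluster",
    "CVRectangle",
    "assign_frames",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "representative",
    "top_clusters_coverage",
    "contact_occupancy",
    "classify_occupancy",
    "distance_histogram",
    "STRONG_THRESHOLD",
    "WEAK_THRESHOLD",
]

#: occupancy above this fraction is a *strong* interaction
STRONG_THRESHOLD = 0.75
#: occupancy in [WEAK_THRESHOLD, STRONG_THRESHOLD] is *weak*
WEAK_THRESHOLD = 0.60


@dataclass
class Cluster:
    member_frames: list   # frame indices
    medoid_frame: int

    def __post_init__(self):
        if self.medoid_frame not in self.member_frames:
            raise ValueError("medoid must be a member of the cluster")

    def __len__(self) -> int:
        return len(self.member_frames)


@dataclass(frozen=True)
class CVRectangle:
    """Axis-aligned CV-space rectangle (an alternative basin definition)."""

    cv1_range: tuple
    cv2_range: tuple

    def contains(self, cv1: float, cv2: float) -> bool:
        return (self.cv1_range[0] <= cv1 <= self.cv1_range[1]
                and self.cv2_range[0] <= cv2 <= self.cv2_range[1])


def assign_frames(cv_series: Sequence[CVRecord], basin,
                  fes: FESGrid | None = None) -> np.ndarray:
    """Indices of frames whose (CV1, CV2) falls inside a basin.

    ``basin`` may be a :class:`~contactfes.fes.Basin` (requires the
    ``fes`` grid it came from, for cell lookup) or a :class:`CVRectangle`.
    Frames exactly on a cell boundary go to the lower-index cell.
    """
    out = []
    if isinstance(basin, CVRectangle):
        for k, rec in enumerate(cv_series):
            if basin.contains(rec.cv1, rec.cv2):
                out.append(k)
        return np.array(out, dtype=int)
    if fes is None:
        raise ValueError("Basin assignment requires the FES grid")
    members = basin.member_cells
    for k, rec in enumerate(cv_series):
        if fes.cell_of(rec.cv1, rec.cv2) in members:
            out.append(k)
    return np.array(out, dtype=int)


def pairwise_rmsd_matrix(frames: Sequence[np.ndarray],
                         fit_indices=None) -> np.ndarray:
    """All-pairs RMSD with each pair superposed independently (the cited
    clustering tool's convention)."""
    frames = [np.asarray(f, float) for f in frames]
    idx = (np.arange(len(frames[0])) if fit_indices is None
           else np.asarray(list(fit_indices), int))
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose(frames[j], frames[i], idx)
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(frames: Sequence[np.ndarray], fit_indices=None,
                   cutoff: float = 2.0,
                   rmsd_matrix: np.ndarray | None = None) -> list:
    """gromos clustering at an RMSD cutoff (default 2 Å, Cα set supplied
    via ``fit_indices``).

    Iteratively: the frame with the most neighbors within ``cutoff``
    (ties to the lowest frame index) seeds a cluster of itself plus its
    neighbors; those frames are removed and the procedure repeats.  The
    output clusters partition the input frames and each cluster's medoid
    is precomputed.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("need at least one frame")
    mat = (pairwise_rmsd_matrix(frames, fit_indices)
           if rmsd_matrix is None else np.asarray(rmsd_matrix, float))
    within = mat <= cutoff
    np.fill_diagonal(within, True)
    alive = np.ones(n, dtype=bool)
    clusters = []
    while np.any(alive):
        counts = (within & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(within[seed] & alive)
        sub = mat[np.ix_(members, members)]
        med = int(members[int(np.argmin(sub.sum(axis=1)))])
        clusters.append(Cluster(member_frames=members.tolist(), medoid_frame=med))
        alive[members] = False
    return clusters


def representative(cluster: Cluster, frames: Sequence[np.ndarray],
                   fit_indices=None,
                   rmsd_matrix: np.ndarray | None = None) -> int:
    """Medoid frame of a cluster: the member minimizing the summed RMSD to
    all other members; ties resolved to the lowest frame index."""
    members = np.asarray(cluster.member_frames, int)
    if len(members) == 1:
        return int(members[0])
    if rmsd_matrix is not None:
        sub = np.asarray(rmsd_matrix, float)[np.ix_(members, members)]
    else:
        sub = pairwise_rmsd_matrix([frames[i] for i in members], fit_indices)
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])


def top_clusters_coverage(clusters: Sequence[Cluster], k: int = 5) -> float:
    """Fraction of all frames contained in the k most populated clusters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sizes = sorted((len(c) for c in clusters), reverse=True)
    total = sum(sizes)
    return sum(sizes[:k]) / total if total else 0.0


def classify_occupancy(occupancy: float) -> str:
    if occupancy > STRONG_THRESHOLD:
        return "strong"
    if occupancy >= WEAK_THRESHOLD:
        return "weak"
    return "below"


def contact_occupancy(trajectory: Trajectory, pairs: Sequence[tuple],
                      cutoff: float = 4.0,
                      atom_filter: str | None = "name CB OD1 OD2 OE1 OE2 NZ NH1 NH2 NE ND1 NE2 OG OG1 OH",
                      frame_indices=None,
                      include_below: bool = False) -> pd.DataFrame:
    """Interaction-occupancy table over a set of residue pairs.

    ``pairs`` are ``((chain, resnum), (chain, resnum))`` tuples.  A pair
    counts as interacting in a frame when the minimal distance between the
    two residues' filtered atoms is ≤ ``cutoff`` (default 4 Å between
    side-chain N/O-bearing atoms, mirroring the crystal-contact
    criterion).  Occupancies are classified strong (>75%), weak (60–75%)
    or below; *below* rows are dropped unless ``include_below``.
    """
    template = trajectory.template
    frame_ids = (range(len(trajectory.frames)) if frame_indices is None
                 else list(frame_indices))
    allowed = None
    if atom_filter is not None:
        allowed = set(select_atoms(template, atom_filter).tolist())

    def residue_indices(res):
        chain, num = res[0], res[1]
        icode = res[2] if len(res) > 2 else ""
        idx = template.residue_atom_indices(chain, num, icode)
        if allowed is not None:
            filt = [i for i in idx if i in allowed]
            idx = filt or idx  # fall back to all atoms if the filter empties
        return np.asarray(idx, int)

    rows = []
    for res_a, res_b in pairs:
        ia = residue_indices(res_a)
        ib = residue_indices(res_b)
        hits = 0
        for k in frame_ids:
            coords = trajectory.frames[k]
            if cdist(coords[ia], coords[ib]).min() <= cutoff:
                hits += 1
        occ = hits / len(list(frame_ids)) if len(list(frame_ids)) else 0.0
        rows.append({
            "residue_a": f"{res_a[0]}{res_a[1]}",
            "residue_b": f"{res_b[0]}{res_b[1]}",
            "occupancy": occ,
            "class": classify_occupancy(occ),
        })
    table = pd.DataFrame(rows, columns=["residue_a", "residue_b",
                                        "occupancy", "class"])
    if not include_below:
        table = table[table["class"] != "below"].reset_index(drop=True)
    return table


def distance_histogram(trajectory: Trajectory, pair, bin_width: float = 0.2,
                       atom_filter: str | None = None,
                       frame_indices=None) -> tuple:
    """Histogram of per-frame minimal distances between two residues (or
    atom groups) with the stated bin width; returns
    ``(bin_edges, counts, mean)``.

    ``pair`` is ``((chain, resnum), (chain, resnum))`` or a pair of
    explicit atom-index arrays.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    template = trajectory.template
    frame_ids = (range(len(trajectory.frames)) if frame_indices is None
                 else list(frame_indices))
    a, b = pair
    if isinstance(a, (list, tuple, np.ndarray)) and len(a) and \
            isinstance(a[0], (int, np.integer)):
        ia, ib = np.asarray(a, int), np.asarray(b, int)
    else:
        allowed = None
        if atom_filter is not None:
            allowed = set(select_atoms(template, atom_filter).tolist())

        def res_idx(res):
            idx = template.residue_atom_indices(res[0], res[1],
                                                res[2] if len(res) > 2 else "")
            if allowed is not None:
                idx = [i for i in idx if i in allowed] or idx
            return np.asarray(idx, int)

        ia, ib = res_idx(a), res_idx(b)
    dists = np.array([
        cdist(trajectory.frames[k][ia], trajectory.frames[k][ib]).min()
        for k in frame_ids
    ])
    lo = np.floor(dists.min() / bin_width) * bin_width
    hi = np.ceil(dists.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(dists, bins=edges)
    return edges, counts, float(dists.mean())
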