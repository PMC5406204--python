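"""Per-atom fluctuation analysis: RMSF, B-factor conversion, and rank-based
comparison against crystallographic B-factors.

RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) over frames superposed on a fit set
(two-pass: align all frames to the first, form the mean structure,
re-align to the mean).  The crystallographic displacement parameter
follows B = (8π²/3)·RMSF².  The comparison with experimental B-factors is
deliberately rank-based (Spearman): absolute-scale agreement between a
simulation and refined B-factors is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ConsistencyError
from .structio import Structure, Trajectory, apply_transform, superpose

__all__ = ["RMSFProfile", "rmsf", "bfactor_from_rmsf", "profile_compare",
           "BFACTOR_PER_RMSF2"]

#: B = (8π²/3) · RMSF²
BFACTOR_PER_RMSF2 = 8.0 * np.pi**2 / 3.0


@dataclass
class RMSFProfile:
    """Per-atom RMSF (Å) for a chosen measure set, with atom bookkeeping."""

    atom_indices: np.ndarray
    values: np.ndarray            # Å
    reference_label: str = ""
    b_factors: np.ndarray | None = None  # Å², converted on demand

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("RMSF must be non-negative")


def rmsf(trajectory: Trajectory, fit_indices, measure_indices=None) -> RMSFProfile:
    """Root-mean-square fluctuation per atom after mean-structure fitting.

    Two-pass: frames are aligned to the first frame on ``fit_indices``,
    the mean structure is formed, and frames re-aligned to that mean
    before computing 3-D displacement fluctuations over
    ``measure_indices`` (defaults to all atoms).
    """
    if len(trajectory.frames) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit = np.asarray(list(fit_indices), int)
    meas = (np.arange(trajectory.frames[0].shape[0])
            if measure_indices is None else np.asarray(list(measure_indices), int))
    first = trajectory.frames[0]
    aligned = []
    for frame in trajectory.frames:
        rot, trans, _ = superpose(frame, first, fit)
        aligned.append(apply_transform(frame, rot, trans))
    mean = np.mean(aligned, axis=0)
    aligned2 = []
    for frame in trajectory.frames:
        rot, trans, _ = superpose(frame, mean, fit)
        aligned2.append(apply_transform(frame, rot, trans))
    stack = np.asarray(aligned2)
    mean2 = stack.mean(axis=0)
    disp2 = np.sum((stack - mean2[None]) ** 2, axis=2)  # (frames, atoms)
    values = np.sqrt(disp2.mean(axis=0))[meas]
    return RMSFProfile(atom_indices=meas, values=values,
                       reference_label=trajectory.template.label)


def bfactor_from_rmsf(profile: RMSFProfile) -> np.ndarray:
    """Convert an RMSF profile to B-factors, B = (8π²/3)·RMSF² (Å²)."""
    b = BFACTOR_PER_RMSF2 * profile.values**2
    profile.b_factors = b
    return b


def profile_compare(simulated: RMSFProfile, reference_b,
                    template: Structure | None = None) -> tuple:
    """Rank comparison of a simulated fluctuation profile with reference
    B-factors.

    Returns ``(spearman_rho, table)`` where the table lists, per atom (or
    per residue when a template is given), the simulated RMSF, its
    converted B and the reference B.
    """
    reference_b = np.asarray(reference_b, float)
    if reference_b.shape != simulated.values.shape:
        raise ConsistencyError(
            f"profile has {simulated.values.size} atoms, reference "
            f"{reference_b.size}"
        )
    sim_b = bfactor_from_rmsf(simulated)
    rho = float(spearmanr(sim_b, reference_b).statistic)
    rows = {"rmsf": simulated.values, "b_simulated": sim_b,
            "b_reference": reference_b}
    if template is not None:
        atoms = [template.atoms[i] for i in simulated.atom_indices]
        rows = {"chain": [a.chain_id for a in atoms],
                "residue": [a.residue_number for a in atoms],
                "atom": [a.name for a in atoms], **rows}
    return rho, pd.DataFrame(rows)
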