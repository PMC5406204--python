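"""Desk-scale well-tempered metadynamics with parallel tempering.

The dynamics is overdamped (Brownian) Langevin,

    x ← x − (Δt/γ)·∇(U + V) + sqrt(2·k_B·T·Δt/γ)·ξ,

either directly in the 2-D collective-variable plane on an analytic model
potential, or on coarse bead coordinates with bias forces routed through
the contact-map CV gradients.  Hills are deposited in CV space with the
well-tempered height law

    W = W0 · exp(−V(s,t) / (k_B·(f−1)·T)),

where V(s,t) is the bias already accumulated at the current CV point and
f > 1 the bias factor.  Replica exchange follows the Metropolis rule
p = min(1, exp[(βi−βj)(U⁺i−U⁺j)]) on neighboring rungs of the temperature
ladder, with exchange energies including any static bias terms.

A preliminary well-tempered-ensemble stage can bias the potential energy
itself; its frozen 1-D bias table broadens the energy fluctuations of the
production run (raising exchange rates) and is never updated there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from ._units import KB_KCAL, kj_to_kcal
from .contact_cv import ContactSet, CVRecord, cv_gradient, cv_pair
from .errors import ConfigurationError, ConsistencyError
from .structio import Structure, Trajectory

__all__ = [
    "ModelPotential",
    "GaussianWellPotential",
    "HarmonicPotential",
    "TablePotential",
    "make_potential",
    "BeadSystem",
    "EngineParams",
    "Hill",
    "ReplicaState",
    "wt_hill_height",
    "bias_potential_and_force",
    "langevin_step",
    "attempt_exchange",
    "EnergyBiasTable",
    "precompute_energy_bias",
    "run_pt_metad",
    "tune_ladder",
    "write_hills",
    "read_hills",
]


# ---------------------------------------------------------------------------
# Model potentials (analytic stand-ins for the molecular energy surface)
# ---------------------------------------------------------------------------

class ModelPotential:
    """Scalar potential on the CV plane with an analytic gradient."""

    dim = 2

    def value(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GaussianWellPotential(ModelPotential):
    """Sum of inverted Gaussian wells plus soft harmonic walls.

    The free-energy zero is the plateau between wells, so a well of depth
    ``d`` sits ``d`` kcal/mol below the barrier plateau: barriers measured
    from a well minimum equal that well's depth (for well separations large
    against the widths).
    """

    def __init__(self, centers, depths, widths,
                 domain=((0.0, 1.0), (0.0, 1.0)), wall_k: float = 200.0):
        self.centers = np.atleast_2d(np.asarray(centers, float))
        self.depths = np.atleast_1d(np.asarray(depths, float))
        self.widths = np.atleast_1d(np.asarray(widths, float))
        if self.widths.size == 1:
            self.widths = np.full(len(self.depths), float(self.widths[0]))
        self.domain = tuple(tuple(map(float, d)) for d in domain)
        self.wall_k = float(wall_k)
        self.dim = self.centers.shape[1]

    def _wells(self, x):
        diff = x[None, :] - self.centers  # (K, dim)
        q = np.sum(diff**2, axis=1) / (2.0 * self.widths**2)
        g = self.depths * np.exp(-q)
        return diff, g

    def value(self, x) -> float:
        x = np.asarray(x, float)
        _, g = self._wells(x)
        v = -float(np.sum(g))
        for k in range(self.dim):
            lo, hi = self.domain[k]
            if x[k] < lo:
                v += self.wall_k * (lo - x[k]) ** 2
            elif x[k] > hi:
                v += self.wall_k * (x[k] - hi) ** 2
        return v

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        diff, g = self._wells(x)
        grad = np.sum(g[:, None] * diff / self.widths[:, None] ** 2, axis=0)
        for k in range(self.dim):
            lo, hi = self.domain[k]
            if x[k] < lo:
                grad[k] += -2.0 * self.wall_k * (lo - x[k])
            elif x[k] > hi:
                grad[k] += 2.0 * self.wall_k * (x[k] - hi)
        return grad


class HarmonicPotential(ModelPotential):
    def __init__(self, stiffness: float = 1.0, center=(0.0, 0.0)):
        self.k = float(stiffness)
        self.center = np.asarray(center, float)
        self.dim = self.center.size

    def value(self, x) -> float:
        d = np.asarray(x, float) - self.center
        return 0.5 * self.k * float(np.dot(d, d))

    def gradient(self, x) -> np.ndarray:
        return self.k * (np.asarray(x, float) - self.center)


class TablePotential(ModelPotential):
    """Bilinear interpolation of a user-supplied grid."""

    def __init__(self, axis1, axis2, values, wall_k: float = 200.0):
        self.axis1 = np.asarray(axis1, float)
        self.axis2 = np.asarray(axis2, float)
        self.values = np.asarray(values, float)
        if self.values.shape != (len(self.axis1), len(self.axis2)):
            raise ConsistencyError("table shape does not match axes")
        self.wall_k = wall_k
        self._interp = _Bilinear(self.axis1, self.axis2)

    def value(self, x) -> float:
        return self._interp.value(self.values, x)

    def gradient(self, x) -> np.ndarray:
        return self._interp.gradient(self.values, x)


def make_potential(kind: str, **params) -> ModelPotential:
    if kind == "double_well_2d":
        return GaussianWellPotential(
            centers=params.get("centers", ((0.25, 0.5), (0.75, 0.5))),
            depths=params.get("depths", (6.0, 3.0)),
            widths=params.get("widths", 0.12),
            domain=params.get("domain", ((0.0, 1.0), (0.0, 1.0))),
            wall_k=params.get("wall_k", 200.0),
        )
    if kind == "triple_well_2d":
        return GaussianWellPotential(
            centers=params.get("centers", ((0.2, 0.7), (0.5, 0.3), (0.8, 0.7))),
            depths=params.get("depths", (6.0, 4.0, 5.0)),
            widths=params.get("widths", 0.1),
            domain=params.get("domain", ((0.0, 1.0), (0.0, 1.0))),
            wall_k=params.get("wall_k", 200.0),
        )
    if kind == "harmonic":
        return HarmonicPotential(params.get("stiffness", 1.0),
                                 params.get("center", (0.0, 0.0)))
    if kind == "user_table":
        return TablePotential(params["axis1"], params["axis2"], params["values"])
    raise ConfigurationError(f"unknown potential kind {kind!r}")


def calibrated_double_well(delta_f: float = 3.0, barrier: float = 6.0,
                           widths: float = 0.1,
                           centers=((0.25, 0.5), (0.75, 0.5)),
                           domain=((0.0, 1.0), (0.0, 1.0)),
                           wall_k: float = 200.0) -> GaussianWellPotential:
    """Two-well landscape whose realized minima difference and deep-well
    barrier equal ``delta_f`` and ``barrier`` exactly.

    Gaussian wells overlap slightly, so raw depths are corrected by a
    short fixed-point iteration against the saddle found on the
    inter-well line.
    """
    c = np.asarray(centers, float)
    d1, d2 = barrier, barrier - delta_f
    for _ in range(8):
        pot = GaussianWellPotential(c, (d1, d2), widths, domain=domain,
                                    wall_k=wall_k)
        line = np.linspace(0.0, 1.0, 2001)[:, None]
        pts = c[0] + line * (c[1] - c[0])
        vals = np.array([pot.value(p) for p in pts])
        v_min1 = vals[0:50].min()
        v_min2 = vals[-50:].min()
        v_saddle = vals[500:1500].max()
        d1 += (barrier - (v_saddle - v_min1))
        d2 = d1 - delta_f + ((v_min2 - v_min1) - delta_f)
    return GaussianWellPotential(c, (d1, d2), widths, domain=domain,
                                 wall_k=wall_k)


class BeadSystem:
    """Coarse bead structure tethered harmonically to a reference.

    Used for structure-mode sampling: the molecular potential is a simple
    per-atom restraint field and the metadynamics bias acts through the
    contact-map CV gradients.
    """

    def __init__(self, reference: Structure, stiffness: float = 2.0):
        self.reference = reference
        self.ref_coords = reference.coords
        self.k = float(stiffness)

    def value(self, coords: np.ndarray) -> float:
        d = coords - self.ref_coords
        return 0.5 * self.k * float(np.sum(d * d))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.k * (coords - self.ref_coords)


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------

#: temperature ladder used in the production protocol (K)
DEFAULT_LADDER = (300.0, 310.0, 320.0, 330.0, 341.0, 352.0, 363.0, 375.0,
                  387.0, 400.0)


@dataclass
class EngineParams:
    temperature_ladder: tuple = DEFAULT_LADDER
    friction: float = 50.0          # kcal/mol·ps per (CV unit)^2 (or per Å^2)
    timestep: float = 0.05          # ps
    deposition_stride: int = 40     # steps; 2 ps at the default timestep
    w0: float = kj_to_kcal(5.0)     # initial hill height, kcal/mol (5 kJ/mol)
    bias_factor: float = 10.0
    sigma: tuple = (0.05, 0.05)     # hill widths per CV
    exchange_stride: int = 20       # steps; 1 ps at the default timestep
    seed: int = 0
    multiple_walkers: bool = False  # deposit hills from every replica
    domain: tuple = ((-0.2, 1.2), (-0.2, 1.2))  # engine bias-grid extent
    grid_spacing: float = 0.01
    truncation: float = 6.0         # hills evaluated within this many σ

    def __post_init__(self):
        if self.bias_factor <= 1:
            raise ConfigurationError("bias factor f must exceed 1")
        ladder = tuple(float(t) for t in self.temperature_ladder)
        if any(t <= 0 for t in ladder):
            raise ConfigurationError("temperatures must be positive")
        if len(ladder) > 1 and any(np.diff(ladder) <= 0):
            raise ConfigurationError("temperature ladder must be strictly increasing")
        self.temperature_ladder = ladder
        for name in ("friction", "timestep", "w0"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian in CV space."""

    time: float            # ps
    center: tuple          # (s1, s2)
    widths: tuple          # (σ1, σ2)
    height: float          # kcal/mol
    bias_factor: float

    def __post_init__(self):
        if min(self.widths) <= 0:
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")


@dataclass
class ReplicaState:
    coordinates: np.ndarray     # CV-space point or (N,3) bead coordinates
    potential_energy: float
    temperature_index: int
    stream_id: int = 0


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def wt_hill_height(v_at_s: float, w0: float, f: float, temperature: float) -> float:
    """Well-tempered hill height W0·exp(−V/(k_B(f−1)T))."""
    if f <= 1:
        raise ConfigurationError("bias factor f must exceed 1")
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    return w0 * math.exp(-v_at_s / (KB_KCAL * (f - 1.0) * temperature))


def bias_potential_and_force(hills: Sequence[Hill], point,
                             truncation: float = 6.0):
    """Accumulated bias V and its CV-space gradient at ``point``.

    Hills farther than ``truncation``·σ from the point (in any CV) are
    skipped.  Returns ``(V, dV_ds)`` with dV_ds a 2-vector.
    """
    point = np.asarray(point, float)
    v = 0.0
    dv = np.zeros_like(point)
    if not hills:
        return 0.0, dv
    centers = np.array([h.center for h in hills])
    widths = np.array([h.widths for h in hills])
    heights = np.array([h.height for h in hills])
    diff = point[None, :] - centers
    keep = np.all(np.abs(diff) <= truncation * widths, axis=1)
    if not np.any(keep):
        return 0.0, dv
    diff = diff[keep]
    widths = widths[keep]
    g = heights[keep] * np.exp(-np.sum(diff**2 / (2.0 * widths**2), axis=1))
    v = float(np.sum(g))
    dv = -np.sum(g[:, None] * diff / widths**2, axis=0)
    return v, dv


class _Bilinear:
    """Bilinear value/gradient interpolation on a regular 2-D grid."""

    def __init__(self, axis1, axis2):
        self.a1 = np.asarray(axis1, float)
        self.a2 = np.asarray(axis2, float)
        self.h1 = self.a1[1] - self.a1[0]
        self.h2 = self.a2[1] - self.a2[0]

    def _locate(self, x):
        i = int(np.clip((x[0] - self.a1[0]) / self.h1, 0, len(self.a1) - 2))
        j = int(np.clip((x[1] - self.a2[0]) / self.h2, 0, len(self.a2) - 2))
        u = (x[0] - self.a1[i]) / self.h1
        v = (x[1] - self.a2[j]) / self.h2
        return i, j, min(max(u, 0.0), 1.0), min(max(v, 0.0), 1.0)

    def value(self, grid, x):
        i, j, u, v = self._locate(np.asarray(x, float))
        return float(
            grid[i, j] * (1 - u) * (1 - v) + grid[i + 1, j] * u * (1 - v)
            + grid[i, j + 1] * (1 - u) * v + grid[i + 1, j + 1] * u * v
        )

    def gradient(self, grid, x):
        i, j, u, v = self._locate(np.asarray(x, float))
        d1 = ((grid[i + 1, j] - grid[i, j]) * (1 - v)
              + (grid[i + 1, j + 1] - grid[i, j + 1]) * v) / self.h1
        d2 = ((grid[i, j + 1] - grid[i, j]) * (1 - u)
              + (grid[i + 1, j + 1] - grid[i + 1, j]) * u) / self.h2
        return np.array([d1, d2])


class _BiasGrid:
    """Incrementally accumulated metadynamics bias on a regular grid.

    Stores the bias value and its two analytic gradient components per
    node; hill deposition adds a truncated Gaussian patch to all three.
    """

    def __init__(self, domain, spacing, truncation=6.0):
        (lo1, hi1), (lo2, hi2) = domain
        self.axis1 = np.arange(lo1, hi1 + 0.5 * spacing, spacing)
        self.axis2 = np.arange(lo2, hi2 + 0.5 * spacing, spacing)
        self.v = np.zeros((len(self.axis1), len(self.axis2)))
        self.g1 = np.zeros_like(self.v)
        self.g2 = np.zeros_like(self.v)
        self.truncation = truncation
        self._interp = _Bilinear(self.axis1, self.axis2)

    def add_hill(self, hill: Hill) -> None:
        c1, c2 = hill.center
        s1, s2 = hill.widths
        t = self.truncation
        i0 = np.searchsorted(self.axis1, c1 - t * s1)
        i1 = np.searchsorted(self.axis1, c1 + t * s1, side="right")
        j0 = np.searchsorted(self.axis2, c2 - t * s2)
        j1 = np.searchsorted(self.axis2, c2 + t * s2, side="right")
        if i0 >= i1 or j0 >= j1:
            return
        d1 = (self.axis1[i0:i1] - c1)[:, None]
        d2 = (self.axis2[j0:j1] - c2)[None, :]
        g = hill.height * np.exp(-(d1**2 / (2 * s1**2) + d2**2 / (2 * s2**2)))
        self.v[i0:i1, j0:j1] += g
        self.g1[i0:i1, j0:j1] += -g * d1 / s1**2
        self.g2[i0:i1, j0:j1] += -g * d2 / s2**2

    def potential(self, x) -> float:
        return self._interp.value(self.v, x)

    def force_gradient(self, x) -> np.ndarray:
        return np.array([self._interp.value(self.g1, x),
                         self._interp.value(self.g2, x)])


def langevin_step(state: ReplicaState, potential, hills, params: EngineParams,
                  rng: np.random.Generator,
                  contact_set: ContactSet | None = None,
                  contact_indices=None,
                  energy_bias: "EnergyBiasTable | None" = None) -> ReplicaState:
    """One overdamped Langevin update of a replica.

    In CV mode ``potential`` is a :class:`ModelPotential` and ``hills`` a
    hill list (or ``_BiasGrid``); in structure mode ``potential`` is a
    :class:`BeadSystem` and the bias force is chained through the CV
    gradients of ``contact_set``.  A frozen well-tempered-ensemble
    ``energy_bias`` rescales the conservative force by
    ``1 + scale·dB/dE`` (clamped for numerical sanity); at ``scale = 0``
    the update is bit-identical to the unbiased one.
    """
    t = params.temperature_ladder[state.temperature_index]
    dt = params.timestep
    gamma = params.friction
    x = np.asarray(state.coordinates, float)

    wte_mult = 1.0
    if energy_bias is not None and energy_bias.scale != 0.0:
        wte_mult = float(np.clip(
            1.0 + energy_bias.dbias_de(state.potential_energy), 0.05, 20.0))

    if isinstance(potential, BeadSystem):
        grad = wte_mult * potential.gradient(x)
        if contact_set is not None:
            s = np.array(cv_pair(x, contact_set, indices=contact_indices))
            dv = _bias_gradient_at(hills, s, params)
            if np.any(dv):
                grad = grad + dv[0] * cv_gradient(x, contact_set, "cv1",
                                                 indices=contact_indices)
                grad = grad + dv[1] * cv_gradient(x, contact_set, "cv2",
                                                  indices=contact_indices)
    else:
        grad = wte_mult * potential.gradient(x)
        grad = grad + _bias_gradient_at(hills, x, params)

    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(
            f"non-finite force at coordinates {x!r} (replica at {t} K)"
        )
    noise = math.sqrt(2.0 * KB_KCAL * t * dt / gamma) * rng.standard_normal(x.shape)
    x_new = x - (dt / gamma) * grad + noise
    e_new = potential.value(x_new)
    return replace(state, coordinates=x_new, potential_energy=float(e_new))


def _bias_gradient_at(hills, point, params):
    if hills is None:
        return np.zeros(2)
    if isinstance(hills, _BiasGrid):
        return hills.force_gradient(point)
    _, dv = bias_potential_and_force(hills, point, params.truncation)
    return dv


def attempt_exchange(u_plus_i: float, u_plus_j: float,
                     temp_i: float, temp_j: float,
                     rng: np.random.Generator) -> bool:
    """Metropolis swap decision between neighboring replicas.

    ``u_plus`` are the exchange energies including any static bias terms;
    accepted with p = min(1, exp[(βi−βj)(U⁺i−U⁺j)]).
    """
    beta_i = 1.0 / (KB_KCAL * temp_i)
    beta_j = 1.0 / (KB_KCAL * temp_j)
    log_p = (beta_i - beta_j) * (u_plus_i - u_plus_j)
    if log_p >= 0:
        # draw anyway so the stream advances identically on both branches
        rng.random()
        return True
    return rng.random() < math.exp(log_p)


# ---------------------------------------------------------------------------
# Well-tempered-ensemble energy bias
# ---------------------------------------------------------------------------

@dataclass
class EnergyBiasTable:
    """Frozen 1-D bias over potential energy from the preliminary stage."""

    energies: np.ndarray
    values: np.ndarray
    scale: float = 1.0

    def bias(self, e: float) -> float:
        if self.scale == 0.0:
            return 0.0
        return self.scale * float(np.interp(e, self.energies, self.values))

    def dbias_de(self, e: float) -> float:
        if self.scale == 0.0:
            return 0.0
        h = self.energies[1] - self.energies[0]
        lo = self.bias(e - 0.5 * h)
        hi = self.bias(e + 0.5 * h)
        return (hi - lo) / h

    def write(self, path) -> None:
        lines = ["#! FIELDS energy bias", f"#! SET scale {float(self.scale)!r}"]
        for e, v in zip(self.energies, self.values):
            lines.append(f"{float(e)!r} {float(v)!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "EnergyBiasTable":
        energies, values, scale = [], [], 1.0
        with open(path) as fh:
            for ln in fh:
                if ln.startswith("#! SET scale"):
                    scale = float(ln.split()[-1])
                elif ln.startswith("#") or not ln.strip():
                    continue
                else:
                    e, v = ln.split()
                    energies.append(float(e))
                    values.append(float(v))
        return cls(np.array(energies), np.array(values), scale)


def precompute_energy_bias(potential, params: EngineParams,
                           n_steps: int = 20000,
                           sigma_e: float | None = None,
                           e_range: tuple | None = None,
                           n_bins: int = 200,
                           scale: float = 1.0,
                           w0_factor: float = 0.25,
                           start=None) -> EnergyBiasTable:
    """Preliminary stage: well-tempered metadynamics biasing the potential
    energy only; returns the frozen bias table for production runs.

    ``scale`` lowers the applied bias afterwards (used to tune the
    production exchange rate down from the tuning stage's).  ``scale=0``
    makes production identical to unbiased PT.
    """
    t0 = params.temperature_ladder[0]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed,
                                                       spawn_key=(900,)))
    x = np.asarray(start if start is not None else
                   getattr(potential, "centers", [[0.5, 0.5]])[0], float).copy()
    # explore unbiased first to set the energy window
    energies = []
    state = ReplicaState(x, potential.value(x), 0)
    for _ in range(n_steps):
        state = langevin_step(state, potential, None, params, rng)
        energies.append(state.potential_energy)
    energies = np.array(energies)
    if e_range is None:
        lo, hi = float(energies.min()), float(energies.max())
        pad = 0.25 * (hi - lo + 1e-9)
        e_range = (lo - pad, hi + pad)
    if sigma_e is None:
        sigma_e = max(1.0 * float(energies.std()), 1e-6)

    e_axis = np.linspace(e_range[0], e_range[1], n_bins)
    table = np.zeros(n_bins)
    # second pass: deposit gentle 1-D well-tempered hills along the energy
    w0_e = w0_factor * params.w0
    state = ReplicaState(x.copy(), potential.value(x), 0)
    for step in range(n_steps):
        state = langevin_step(state, potential, None, params, rng)
        if (step + 1) % params.deposition_stride == 0:
            e = state.potential_energy
            v_here = float(np.interp(e, e_axis, table))
            h = wt_hill_height(v_here, w0_e, params.bias_factor, t0)
            table += h * np.exp(-(e_axis - e) ** 2 / (2.0 * sigma_e**2))
    return EnergyBiasTable(e_axis, table, scale)


# ---------------------------------------------------------------------------
# The PT-metaD production engine
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Outputs of :func:`run_pt_metad`."""

    replica_paths: list          # per replica: (n_records, ...) coordinate array
    times: np.ndarray            # record times, ps
    hills: list                  # hills deposited by the biased walker(s)
    cv_records: list             # CVRecord series for the T[0] replica
    exchange_attempts: int = 0
    exchange_accepts: int = 0
    seed: int = 0

    @property
    def exchange_rate(self) -> float:
        return (self.exchange_accepts / self.exchange_attempts
                if self.exchange_attempts else 0.0)

    def trajectory(self, template: Structure, replica: int = 0) -> Trajectory:
        frames = [np.asarray(f) for f in self.replica_paths[replica]]
        return Trajectory(template, frames, self.times)


def _replica_rng(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))


def run_pt_metad(system, params: EngineParams, n_steps: int,
                 contact_set: ContactSet | None = None,
                 mode: str = "cv",
                 start=None,
                 energy_bias: EnergyBiasTable | None = None,
                 record_stride: int | None = None,
                 n_replicas: int | None = None,
                 deposit_hills: bool = True) -> SimulationResult:
    """Run well-tempered PT-metaD for ``n_steps`` per replica.

    ``mode='cv'``: ``system`` is a :class:`ModelPotential` and replicas are
    points in the CV plane.  ``mode='structure'``: ``system`` is a
    :class:`BeadSystem`; a :class:`ContactSet` is then required and bias
    forces act through the CV gradients.

    Hills are deposited every ``deposition_stride`` steps from the
    lowest-temperature replica (all replicas when
    ``params.multiple_walkers``), exchanges attempted every
    ``exchange_stride`` steps on alternating even/odd neighbor pairs.
    Everything is reproducible from ``params.seed``.
    """
    if mode not in ("cv", "structure"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if isinstance(system, BeadSystem):
        mode = "structure"
    if mode == "structure":
        if not isinstance(system, BeadSystem):
            raise ConfigurationError("structure mode requires a BeadSystem")
        if contact_set is None:
            if deposit_hills:
                raise ConfigurationError(
                    "structure mode requires a contact_set to deposit hills"
                )
            indices = None
        else:
            indices = contact_set.resolve_indices(system.reference)
    else:
        indices = None

    ladder = params.temperature_ladder
    n_rep = len(ladder) if n_replicas is None else int(n_replicas)
    if n_rep < 1 or n_rep > len(ladder):
        raise ConfigurationError("n_replicas out of ladder range")
    record_stride = record_stride or params.deposition_stride

    if start is None:
        if mode == "cv":
            start = getattr(system, "centers", np.array([[0.5, 0.5]]))[0]
        else:
            start = system.ref_coords
    start = np.asarray(start, float)

    replicas = [
        ReplicaState(start.copy(), float(system.value(start)), k, stream_id=k)
        for k in range(n_rep)
    ]
    rngs = [_replica_rng(params.seed, k) for k in range(n_rep)]
    ex_rng = _replica_rng(params.seed, 10_000)

    bias = _BiasGrid(params.domain, params.grid_spacing, params.truncation)
    hills: list = []
    paths = [[] for _ in range(n_rep)]
    times = []
    cv_records = []
    n_att = n_acc = 0

    def cv_of(state: ReplicaState) -> np.ndarray:
        if mode == "cv":
            return np.asarray(state.coordinates, float)
        if contact_set is None:
            return np.zeros(2)
        return np.array(cv_pair(state.coordinates, contact_set, indices=indices))

    def u_plus(state: ReplicaState) -> float:
        u = state.potential_energy
        if energy_bias is not None:
            u += energy_bias.bias(state.potential_energy)
        u += bias.potential(cv_of(state))
        return u

    for step in range(n_steps):
        for k, state in enumerate(replicas):
            biased = params.multiple_walkers or k == 0
            replicas[k] = langevin_step(
                state, system, bias if biased else None, params, rngs[k],
                contact_set=contact_set if mode == "structure" else None,
                contact_indices=indices, energy_bias=energy_bias,
            )
        if deposit_hills and (step + 1) % params.deposition_stride == 0:
            walkers = range(n_rep) if params.multiple_walkers else (0,)
            for k in walkers:
                s = cv_of(replicas[k])
                v_here = bias.potential(s)
                h = wt_hill_height(v_here, params.w0, params.bias_factor,
                                   ladder[k])
                hill = Hill(time=(step + 1) * params.timestep,
                            center=(float(s[0]), float(s[1])),
                            widths=tuple(params.sigma), height=h,
                            bias_factor=params.bias_factor)
                hills.append(hill)
                bias.add_hill(hill)
        if n_rep > 1 and (step + 1) % params.exchange_stride == 0:
            phase = ((step + 1) // params.exchange_stride) % 2
            for i in range(phase, n_rep - 1, 2):
                j = i + 1
                n_att += 1
                if attempt_exchange(u_plus(replicas[i]), u_plus(replicas[j]),
                                    ladder[i], ladder[j], ex_rng):
                    n_acc += 1
                    xi = replicas[i].coordinates
                    ei = replicas[i].potential_energy
                    replicas[i] = replace(replicas[i],
                                          coordinates=replicas[j].coordinates,
                                          potential_energy=replicas[j].potential_energy)
                    replicas[j] = replace(replicas[j], coordinates=xi,
                                          potential_energy=ei)
        if (step + 1) % record_stride == 0:
            t_now = (step + 1) * params.timestep
            times.append(t_now)
            for k in range(n_rep):
                paths[k].append(np.array(replicas[k].coordinates, copy=True))
            s0 = cv_of(replicas[0])
            cv_records.append(CVRecord(time=t_now, cv1=float(s0[0]),
                                       cv2=float(s0[1])))

    return SimulationResult(
        replica_paths=[np.array(p) for p in paths],
        times=np.array(times), hills=hills, cv_records=cv_records,
        exchange_attempts=n_att, exchange_accepts=n_acc, seed=params.seed,
    )


def tune_ladder(system, params: EngineParams, target_rate: float = 0.30,
                tolerance: float = 0.05, n_steps: int = 4000,
                max_iter: int = 12, max_ratio: float = 1.5) -> tuple:
    """Adjust a geometric temperature ladder to hit a target exchange rate.

    Returns ``(ladder, measured_rate)``; keeps the rung count fixed and
    bisects on the geometric ratio (bounded by ``max_ratio``).
    """
    t_lo = params.temperature_ladder[0]
    n_rep = len(params.temperature_ladder)
    lo_ratio, hi_ratio = 1.0005, max_ratio

    def rate_for(ratio):
        ladder = tuple(t_lo * ratio**k for k in range(n_rep))
        p = replace(params, temperature_ladder=ladder)
        res = run_pt_metad(system, p, n_steps, deposit_hills=False)
        return res.exchange_rate, ladder

    best = None
    for _ in range(max_iter):
        mid = math.sqrt(lo_ratio * hi_ratio)
        r, ladder = rate_for(mid)
        best = (ladder, r)
        if abs(r - target_rate) <= tolerance:
            break
        # wider spacing -> lower acceptance
        if r > target_rate:
            lo_ratio = mid
        else:
            hi_ratio = mid
    return best


# ---------------------------------------------------------------------------
# HILLS file interchange (PLUMED-compatible layout)
# ---------------------------------------------------------------------------

def write_hills(hills: Sequence[Hill], path) -> None:
    lines = ["#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf"]
    for h in hills:
        lines.append(
            f"{h.time:.6f} {h.center[0]:.10f} {h.center[1]:.10f} "
            f"{h.widths[0]:.10f} {h.widths[1]:.10f} {h.height:.10f} "
            f"{h.bias_factor:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_hills(path) -> list:
    out = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            t, c1, c2, s1, s2, h, f = ln.split()[:7]
            out.append(Hill(time=float(t), center=(float(c1), float(c2)),
                            widths=(float(s1), float(s2)), height=float(h),
                            bias_factor=float(f)))
    return out
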