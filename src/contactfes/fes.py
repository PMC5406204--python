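"""Free-energy surfaces from deposited hills: reconstruction, projection,
convergence checks, minima and basin extraction.

In the well-tempered scheme the accumulated bias converges to
−(1 − 1/f)·(F(s) − min F) up to a constant, so the free energy is
estimated by integrating the deposited bias and rescaling,

    F̂(s) = −(f/(f−1)) · V(s),

then shifting so the global minimum is zero.  Basins are extracted as
4-connected flood fills within a depth window above their minimum (the
window defaults to 2 kcal/mol, the depth band used to label minima), with
watershed ties going to the deeper minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._units import KB_KCAL
from .errors import ConsistencyError
from .sampling import Hill

__all__ = [
    "FESGrid",
    "Basin",
    "default_axes",
    "fes_from_hills",
    "project_1d",
    "check_convergence",
    "convergence_from_hills",
    "find_minima",
    "extract_basin",
    "extract_basins",
    "fes_difference",
    "write_fes",
    "read_fes",
    "plot_fes",
]


def default_axes(spacing: float = 0.01, lo: float = 0.0, hi: float = 1.0):
    """Default CV grid: [0,1]² at 0.01 spacing (cell centers)."""
    ax = np.arange(lo, hi + 0.5 * spacing, spacing)
    return ax, ax.copy()


@dataclass
class FESGrid:
    """Free energy on a regular (CV1, CV2) grid; values[i, j] at
    (axes[0][i], axes[1][j]), kcal/mol."""

    axes: tuple
    values: np.ndarray
    temperature: float = 300.0
    bias_factor: float = 10.0
    shifted: bool = True

    def __post_init__(self):
        self.axes = (np.asarray(self.axes[0], float), np.asarray(self.axes[1], float))
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.axes[0]), len(self.axes[1])):
            raise ConsistencyError("FES values shape does not match axes")
        for ax in self.axes:
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("axes must be strictly increasing")

    @property
    def spacing(self) -> tuple:
        return (float(self.axes[0][1] - self.axes[0][0]),
                float(self.axes[1][1] - self.axes[1][0]))

    def shift_to_zero(self) -> "FESGrid":
        v = self.values - self.values.min()
        return FESGrid(self.axes, v, self.temperature, self.bias_factor, True)

    def cell_of(self, cv1: float, cv2: float) -> tuple:
        """Cell index of a CV point; values exactly on a cell boundary go to
        the lower-index cell."""
        def locate(ax, v):
            mid = 0.5 * (ax[1:] + ax[:-1])
            return int(np.clip(np.searchsorted(mid, v, side="left"), 0, len(ax) - 1))
        return locate(self.axes[0], cv1), locate(self.axes[1], cv2)


@dataclass
class Basin:
    """A free-energy basin: a connected set of cells within a depth window
    of its minimum."""

    minimum_location: tuple     # (cv1, cv2)
    minimum_value: float        # kcal/mol
    member_cells: set           # {(i, j), ...}, 4-connected
    depth_window: float = 2.0

    def __post_init__(self):
        if not self.member_cells:
            raise ValueError("basin has no member cells")


def fes_from_hills(hills: Sequence[Hill], axes=None,
                   temperature: float = 300.0,
                   shift: bool = True) -> FESGrid:
    """Reconstruct F̂ = −(f/(f−1))·V from the deposited hills.

    All hills must share one bias factor; the surface is shifted so its
    minimum is zero unless ``shift=False``.
    """
    if axes is None:
        axes = default_axes()
    a1, a2 = np.asarray(axes[0], float), np.asarray(axes[1], float)
    v = np.zeros((len(a1), len(a2)))
    hills = list(hills)
    if hills:
        factors = {h.bias_factor for h in hills}
        if len(factors) > 1:
            raise ConsistencyError(
                f"hills carry mixed bias factors {sorted(factors)}"
            )
        f = hills[0].bias_factor
        for h in hills:
            c1, c2 = h.center
            s1, s2 = h.widths
            d1 = (a1 - c1)[:, None]
            d2 = (a2 - c2)[None, :]
            v += h.height * np.exp(-(d1**2 / (2 * s1**2) + d2**2 / (2 * s2**2)))
        fes = -(f / (f - 1.0)) * v
    else:
        f = 10.0
        fes = v
    grid = FESGrid((a1, a2), fes, temperature=temperature, bias_factor=f,
                   shifted=False)
    return grid.shift_to_zero() if shift else grid


def project_1d(fes: FESGrid, axis: str = "cv1") -> tuple:
    """Boltzmann-marginalized 1-D profile along one CV, shifted to min 0.

    F1(a) = −k_B·T · ln Σ_b exp(−F(a,b)/k_B·T) · Δb
    """
    if axis not in ("cv1", "cv2"):
        raise ValueError("axis must be 'cv1' or 'cv2'")
    kt = KB_KCAL * fes.temperature
    vals = fes.values if axis == "cv1" else fes.values.T
    da = fes.spacing[1] if axis == "cv1" else fes.spacing[0]
    # logsumexp per row for numerical safety
    m = vals.min(axis=1, keepdims=True)
    prof = -kt * (np.log(np.sum(np.exp(-(vals - m) / kt), axis=1) * da)
                  - m[:, 0] / kt)
    prof = prof - prof.min()
    ax = fes.axes[0] if axis == "cv1" else fes.axes[1]
    return ax.copy(), prof


def check_convergence(fes_earlier: FESGrid, fes_later: FESGrid,
                      threshold: float = 2.0,
                      region_cap: float = 10.0) -> tuple:
    """Trailing-window convergence test.

    Both grids are aligned to min 0; the maximum |ΔF| is taken over cells
    where the later surface is at most ``region_cap`` kcal/mol, and over
    both 1-D projections (restricted the same way).  Converged iff every
    maximum change is ≤ ``threshold`` (default 2 kcal/mol).
    Returns ``(converged, max_change)``.
    """
    if fes_earlier.values.shape != fes_later.values.shape or \
            not np.allclose(fes_earlier.axes[0], fes_later.axes[0]) or \
            not np.allclose(fes_earlier.axes[1], fes_later.axes[1]):
        raise ConsistencyError("convergence check requires congruent grids")
    a = fes_earlier.values - fes_earlier.values.min()
    b = fes_later.values - fes_later.values.min()
    mask = b <= region_cap
    max_change = float(np.abs(a - b)[mask].max()) if np.any(mask) else 0.0
    changes = [max_change]
    for axis in ("cv1", "cv2"):
        _, pa = project_1d(fes_earlier, axis)
        _, pb = project_1d(fes_later, axis)
        m1 = pb <= region_cap
        if np.any(m1):
            changes.append(float(np.abs(pa - pb)[m1].max()))
    overall = max(changes)
    return overall <= threshold, overall


def convergence_from_hills(hills, axes=None, temperature: float = 300.0,
                           trailing_fraction: float = 0.1,
                           threshold: float = 2.0,
                           region_cap: float = 10.0) -> tuple:
    """Convergence over the trailing deposition window.

    Compares the surface reconstructed from all hills against the one
    without the last ``trailing_fraction`` of deposition time (the
    trailing-window generalization of a fixed final interval).
    """
    hills = list(hills)
    if len(hills) < 2:
        return False, float("inf")
    t_end = hills[-1].time
    t_cut = t_end - trailing_fraction * (t_end - hills[0].time)
    early = [h for h in hills if h.time <= t_cut]
    if not early:
        return False, float("inf")
    f_early = fes_from_hills(early, axes, temperature)
    f_all = fes_from_hills(hills, axes, temperature)
    return check_convergence(f_early, f_all, threshold, region_cap)


def find_minima(fes: FESGrid) -> list:
    """Local minima: cells strictly below all 8 neighbors (plateaus resolved
    to the lowest-index member cell), sorted ascending by free energy.

    Returns a list of ``((cv1, cv2), F)`` tuples.
    """
    v = fes.values
    ni, nj = v.shape
    padded = np.full((ni + 2, nj + 2), np.inf)
    padded[1:-1, 1:-1] = v
    neigh_min = np.full_like(v, np.inf)
    strict_ok = np.ones_like(v, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = padded[1 + di:1 + di + ni, 1 + dj:1 + dj + nj]
            neigh_min = np.minimum(neigh_min, shifted)
    strict = v < neigh_min
    # plateau handling: candidate cells <= all neighbors, grouped by
    # connectivity at equal value; keep lowest-index cell of a component
    # whose value is below every outside neighbor
    leq = v <= neigh_min
    plateau = leq & ~strict
    out = []
    for i, j in zip(*np.nonzero(strict)):
        out.append(((float(fes.axes[0][i]), float(fes.axes[1][j])),
                    float(v[i, j]), (int(i), int(j))))
    if np.any(plateau):
        seen = set()
        for i0, j0 in zip(*np.nonzero(plateau)):
            if (i0, j0) in seen:
                continue
            val = v[i0, j0]
            stack = [(i0, j0)]
            comp = set()
            ok = True
            while stack:
                i, j = stack.pop()
                if (i, j) in comp:
                    continue
                comp.add((i, j))
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    a, b = i + di, j + dj
                    if 0 <= a < ni and 0 <= b < nj:
                        if v[a, b] == val and (a, b) not in comp:
                            stack.append((a, b))
                        elif v[a, b] < val:
                            ok = False
            seen |= comp
            if ok:
                i, j = min(comp)
                out.append(((float(fes.axes[0][i]), float(fes.axes[1][j])),
                            float(val), (i, j)))
    out.sort(key=lambda t: (t[1], t[2]))
    return [(loc, val) for loc, val, _ in out]


def extract_basin(fes: FESGrid, minimum, depth_window: float = 2.0) -> Basin:
    """Basin of a single minimum: see :func:`extract_basins`."""
    basins = extract_basins(fes, [minimum], depth_window, exclusive=False)
    return basins[0]


def extract_basins(fes: FESGrid, minima=None, depth_window: float = 2.0,
                   exclusive: bool = True) -> list:
    """Flood-fill basins around minima.

    Cells with F ≤ F_min + window, 4-connected to the minimum.  With
    ``exclusive`` (the default for multiple minima) fills proceed in
    ascending order of minimum depth and stop at cells already claimed by
    a deeper minimum — the watershed tie goes to the lower minimum.
    ``minimum`` entries are ``((cv1, cv2), F)`` pairs from
    :func:`find_minima`.
    """
    if minima is None:
        minima = find_minima(fes)
    minima = sorted(minima, key=lambda t: t[1])
    v = fes.values
    ni, nj = v.shape
    claimed: dict = {}
    basins = []
    for loc, fmin in minima:
        i0, j0 = fes.cell_of(*loc)
        limit = fmin + depth_window
        cells = set()
        stack = [(i0, j0)]
        while stack:
            i, j = stack.pop()
            if (i, j) in cells:
                continue
            if exclusive and (i, j) in claimed:
                continue
            if v[i, j] > limit:
                continue
            cells.add((i, j))
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < ni and 0 <= b < nj:
                    stack.append((a, b))
        if not cells:
            cells = {(i0, j0)}
        if exclusive:
            for c in cells:
                claimed[c] = len(basins)
        basins.append(Basin(minimum_location=tuple(loc), minimum_value=float(fmin),
                            member_cells=cells, depth_window=depth_window))
    return basins


def _basin_free_energy(fes: FESGrid, basin: Basin) -> float:
    kt = KB_KCAL * fes.temperature
    cells = np.array(sorted(basin.member_cells))
    if cells.size == 0:
        raise ValueError("empty basin")
    f = fes.values[cells[:, 0], cells[:, 1]]
    da, db = fes.spacing
    m = f.min()
    return float(-kt * (np.log(np.sum(np.exp(-(f - m) / kt)) * da * db) - m / kt))


def fes_difference(fes: FESGrid, basin_a: Basin, basin_b: Basin) -> float:
    """Free-energy difference F(a) − F(b) of two basins, each computed as
    −k_B·T·ln of the basin's Boltzmann-weighted cell sum (kcal/mol)."""
    return _basin_free_energy(fes, basin_a) - _basin_free_energy(fes, basin_b)


# ---------------------------------------------------------------------------
# Text interchange and plotting
# ---------------------------------------------------------------------------

def write_fes(fes: FESGrid, path) -> None:
    lines = ["#! FIELDS cv1 cv2 free",
             f"#! SET temperature {float(fes.temperature)!r}",
             f"#! SET biasf {float(fes.bias_factor)!r}"]
    for i, a in enumerate(fes.axes[0]):
        for j, b in enumerate(fes.axes[1]):
            lines.append(f"{float(a)!r} {float(b)!r} {float(fes.values[i, j])!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fes(path) -> FESGrid:
    temperature, biasf = 300.0, 10.0
    rows = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#! SET temperature"):
                temperature = float(ln.split()[-1])
            elif ln.startswith("#! SET biasf"):
                biasf = float(ln.split()[-1])
            elif ln.startswith("#") or not ln.strip():
                continue
            else:
                a, b, f = ln.split()
                rows.append((float(a), float(b), float(f)))
    a1 = np.unique([r[0] for r in rows])
    a2 = np.unique([r[1] for r in rows])
    v = np.empty((len(a1), len(a2)))
    ia = {x: i for i, x in enumerate(a1)}
    ib = {x: i for i, x in enumerate(a2)}
    for a, b, f in rows:
        v[ia[a], ib[b]] = f
    return FESGrid((a1, a2), v, temperature=temperature, bias_factor=biasf)


def plot_fes(fes: FESGrid, path=None, contour_interval: float = 2.0,
             vmax: float | None = None):
    """Filled contour plot with lines every ``contour_interval`` kcal/mol."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = fes.values - fes.values.min()
    top = vmax if vmax is not None else min(float(np.percentile(v, 99)), 20.0)
    levels = np.arange(0.0, top + contour_interval, contour_interval)
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(fes.axes[0], fes.axes[1], v.T, levels=levels, cmap="viridis")
    ax.contour(fes.axes[0], fes.axes[1], v.T, levels=levels, colors="k",
               linewidths=0.4)
    fig.colorbar(cs, ax=ax, label="free energy (kcal/mol)")
    ax.set_xlabel("CV1")
    ax.set_ylabel("CV2")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
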