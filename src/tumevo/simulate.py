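"""Off-lattice cell-based simulation of tumour growth.

Each cell is a hard sphere of radius ``cell_radius`` carrying a genotype.
Division places a daughter at contact distance in a uniformly random
direction; the resulting overlaps are resolved by a width-first push cascade
in which each overlapped neighbour is displaced along the connecting axis by
the overlap plus a small buffer margin.  Division rates fall linearly with
the local cell density, from ``b0`` at zero density to zero at the critical
density ``rho_c``; ``rho_c = inf`` gives density-independent (volume) growth,
while ``rho_c`` at the close-packed density confines divisions to the rim
(surface growth).  Cells die at a constant rate ``d``.  Events are scheduled
by an exact Gillespie algorithm.  Mutations follow an infinite-sites model:
at every division both mother and daughter gain a Poisson(``mu``) number of
brand-new mutations, recorded in a genotype tree with live cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K

__all__ = [
    "SimParams",
    "GenotypeTree",
    "Population",
    "Simulation",
    "simulate",
    "simulate_surviving",
    "birth_rate",
    "local_density",
    "draw_mutation_count",
    "divide_cell",
    "push_apart",
    "close_packed_density",
    "ball_measure",
]


def ball_measure(radius: float, dim: int) -> float:
    """Area (2D) or volume (3D) of a ball."""
    if dim == 2:
        return math.pi * radius**2
    if dim == 3:
        return 4.0 / 3.0 * math.pi * radius**3
    raise ValueError(f"dimension must be 2 or 3, got {dim}")


def close_packed_density(dim: int, min_dist: float, density_radius: float) -> float:
    """Density reported by the windowed estimator for a close-packed lattice.

    Builds a hexagonal (2D) or FCC (3D) lattice with nearest-neighbour
    distance ``min_dist`` and counts lattice points within ``density_radius``
    of a lattice site, divided by the window measure.  This is the natural
    ``rho_c`` for the surface-growth preset: it is the largest density the
    estimator can report for a packing at contact distance.
    """
    if density_radius <= 0 or min_dist <= 0:
        raise ValueError("min_dist and density_radius must be positive")
    reach = int(math.ceil(density_radius / min_dist)) + 2
    pts = []
    if dim == 2:
        for i in range(-reach, reach + 1):
            for j in range(-reach, reach + 1):
                x = (i + 0.5 * j) * min_dist
                y = j * math.sqrt(3) / 2 * min_dist
                pts.append((x, y))
    elif dim == 3:
        a = min_dist * math.sqrt(2)
        basis = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
        for i in range(-reach, reach + 1):
            for j in range(-reach, reach + 1):
                for k in range(-reach, reach + 1):
                    for bx, by, bz in basis:
                        pts.append(((i + bx) * a, (j + by) * a, (k + bz) * a))
    else:
        raise ValueError(f"dimension must be 2 or 3, got {dim}")
    pts = np.asarray(pts)
    r = np.sqrt((pts**2).sum(axis=1))
    count = int(((r > 1e-9) & (r <= density_radius + 1e-9)).sum())
    return count / ball_measure(density_radius, dim)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the growth model.

    b0 and d are rates per cell per unit time; mu is the mean number of new
    mutations per daughter genome per division; rho_c is in cells per unit
    area (2D) or volume (3D) and may be ``inf``; lengths are in units where
    the default cell diameter is 1.
    """

    dimension: int = 2
    b0: float = 1.0
    d: float = 0.0
    mu: float = 0.0
    rho_c: float = math.inf
    cell_radius: float = 0.5
    push_margin: float | None = None
    density_radius: float | None = None
    n_max: int = 1000
    seed: int = 0
    t_max: float = math.inf
    max_events: int | None = None

    def __post_init__(self):
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.d < 0:
            raise ValueError("d must be non-negative")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not self.rho_c > 0:
            raise ValueError("rho_c must be positive (or inf)")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if self.push_margin is not None and self.push_margin < 0:
            raise ValueError("push_margin must be non-negative")
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")

    @property
    def margin(self) -> float:
        return 0.05 * self.cell_radius if self.push_margin is None else self.push_margin

    @property
    def dens_radius(self) -> float:
        return 3.0 * self.cell_radius if self.density_radius is None else self.density_radius

    @property
    def min_dist(self) -> float:
        return 2.0 * self.cell_radius

    def surface_growth(self) -> "SimParams":
        """Variant with rho_c at the close-packed density (surface growth)."""
        rc = close_packed_density(self.dimension, self.min_dist, self.dens_radius)
        return replace(self, rho_c=rc)


def birth_rate(rho: float, p: SimParams) -> float:
    """Division rate at local density rho: linear from b0 at rho=0 to 0 at rho_c."""
    if np.any(np.asarray(rho) < 0):
        raise ValueError("density must be non-negative")
    if math.isinf(p.rho_c):
        return p.b0 * np.ones_like(np.asarray(rho, dtype=float)) if np.ndim(rho) else p.b0
    return np.maximum(0.0, p.b0 * (1.0 - np.asarray(rho, dtype=float) / p.rho_c)) if np.ndim(rho) \
        else max(0.0, p.b0 * (1.0 - rho / p.rho_c))


def draw_mutation_count(mu: float, rng: np.random.Generator) -> int:
    """Number of new mutations acquired by one daughter genome: Poisson(mu)."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mu == 0:
        return 0
    return int(rng.poisson(mu))


class GenotypeTree:
    """Tree of genotypes; node 0 is the wildtype root.

    Mutations are globally numbered integers; node ``g`` gained the
    contiguous block ``[first_mut[g], first_mut[g] + n_muts[g])``.
    """

    def __init__(self):
        self.parent = [-1]
        self.first_mut = [0]
        self.n_muts = [0]
        self.birth_time = [0.0]
        self.birth_popsize = [1]
        self.live_count = [1]
        self.n_mutations_total = 0

    def __len__(self):
        return len(self.parent)

    def add_node(self, parent: int, k_muts: int, time: float, popsize: int) -> int:
        g = len(self.parent)
        self.parent.append(parent)
        self.first_mut.append(self.n_mutations_total)
        self.n_muts.append(k_muts)
        self.birth_time.append(time)
        self.birth_popsize.append(popsize)
        self.live_count.append(0)
        self.n_mutations_total += k_muts
        return g

    def mutations_gained(self, g: int) -> np.ndarray:
        return np.arange(self.first_mut[g], self.first_mut[g] + self.n_muts[g])

    def genotype_mutations(self, g: int) -> np.ndarray:
        """All mutations carried by genotype g (union along the root path)."""
        out = []
        while g >= 0:
            out.append(self.mutations_gained(g))
            g = self.parent[g]
        return np.sort(np.concatenate(out)) if out else np.empty(0, dtype=int)

    def mutation_node(self) -> np.ndarray:
        """Array mapping mutation id -> genotype node where it was gained."""
        out = np.empty(self.n_mutations_total, dtype=np.int64)
        for g in range(len(self.parent)):
            out[self.first_mut[g]: self.first_mut[g] + self.n_muts[g]] = g
        return out

    def arrays(self):
        return (np.asarray(self.parent), np.asarray(self.first_mut),
                np.asarray(self.n_muts), np.asarray(self.birth_time),
                np.asarray(self.birth_popsize), np.asarray(self.live_count))

    def subtree_live_counts(self) -> np.ndarray:
        """Live cells in the clade rooted at each node (node + descendants)."""
        parent = np.asarray(self.parent)
        out = np.asarray(self.live_count, dtype=np.int64).copy()
        # children are always appended after parents, so one reverse sweep works
        for g in range(len(parent) - 1, 0, -1):
            out[parent[g]] += out[g]
        return out

    def to_frame(self):
        import pandas as pd

        parent, first, nm, bt, bp, lc = self.arrays()
        gained = [",".join(map(str, range(f, f + n))) for f, n in zip(first, nm)]
        return pd.DataFrame({
            "genotype_id": np.arange(len(parent)),
            "parent_id": parent,
            "mutations_gained": gained,
            "birth_time": bt,
            "birth_popsize": bp,
            "live_count": lc,
        })

    def to_newick(self) -> str:
        """Newick string with genotype ids as labels and waiting times as branch lengths."""
        children: list[list[int]] = [[] for _ in range(len(self.parent))]
        for g in range(1, len(self.parent)):
            children[self.parent[g]].append(g)

        def fmt(g: int) -> str:
            bl = self.birth_time[g] - (self.birth_time[self.parent[g]] if g else 0.0)
            if children[g]:
                inner = ",".join(fmt(c) for c in children[g])
                return f"({inner}){g}:{bl:.6g}"
            return f"{g}:{bl:.6g}"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * len(self.parent) + 100))
        try:
            return fmt(0) + ";"
        finally:
            sys.setrecursionlimit(old)


@dataclass
class Population:
    """Snapshot of a simulated population: live cells plus the genotype tree."""

    cell_ids: np.ndarray
    positions: np.ndarray
    genotypes: np.ndarray
    tree: GenotypeTree
    time: float
    births: int
    deaths: int
    extinct: bool
    params: SimParams
    timed_out: bool = False
    history: np.ndarray | None = None  # (time, size) records

    @property
    def size(self) -> int:
        return len(self.cell_ids)

    def cells_frame(self):
        import pandas as pd

        cols = {"id": self.cell_ids}
        for d, name in enumerate("xyz"[: self.params.dimension]):
            cols[name] = self.positions[:, d]
        cols["genotype_id"] = self.genotypes
        return pd.DataFrame(cols)

    def mutation_carrier_counts(self) -> np.ndarray:
        """Number of live cells carrying each mutation."""
        sub = self.tree.subtree_live_counts()
        node = self.tree.mutation_node()
        return sub[node]


class Simulation:
    """Mutable simulation state; ``run`` advances it to completion."""

    def __init__(self, params: SimParams):
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        K.seed_kernel_rng(int(self.rng.integers(0, 2**31 - 1)))
        self.dim = params.dimension
        self._setup_grid()
        cap = max(int(params.n_max * 1.5) + 64, 256)
        self._alloc(cap)
        self.n_slots = 0
        self.n_alive = 0
        self.time = 0.0
        self.births = 0
        self.deaths = 0
        self.events = 0
        self.tree = GenotypeTree()
        self.tree.live_count[0] = 0
        self.surface_mode = not math.isinf(params.rho_c)
        self.total_b = 0.0
        self.last_division = None  # daughter slot of the latest division
        self.last_division_mother = None
        self._stamp_val = 0
        self._ball = ball_measure(params.dens_radius, self.dim)
        self._hist_t = []
        self._hist_n = []
        # seed cell at the origin
        self._add_cell(np.zeros(self.dim), 0)
        self.tree.live_count[0] = 1
        if self.surface_mode:
            self._update_densities(np.zeros((1, self.dim)))
        self._record_history()

    # -- setup ---------------------------------------------------------------

    def _setup_grid(self):
        p = self.p
        bw = p.min_dist
        # density-limited (surface) growth leaves partly refilled gaps behind
        # the rim, so those tumours occupy more room per cell
        per_cell = 1.15 if math.isinf(p.rho_c) else 4.0
        if self.dim == 2:
            half = max(1.7 * math.sqrt(per_cell * p.n_max / math.pi), 8.0) * bw
        else:
            half = max(1.7 * (3 * per_cell * p.n_max / (4 * math.pi)) ** (1 / 3), 6.0) * bw
        nb = 2 * int(math.ceil(half / bw)) + 3
        self.nb = nb
        self.bw = bw
        self.inv_bw = 1.0 / bw
        self.origin = -nb * bw / 2.0
        self.gcount = np.zeros(nb**self.dim, dtype=np.int32)
        self.gcells = np.zeros((nb**self.dim, 16), dtype=np.int32)
        self.max_pushes = 100_000
        self.queue = np.zeros(self.max_pushes + 2, dtype=np.int32)
        self.nbr_buf = np.zeros(128, dtype=np.int32)
        self.moved_pos = np.zeros((self.max_pushes + 2, self.dim))

    def _alloc(self, cap):
        self.cap = cap
        self.pos = np.zeros((cap, self.dim))
        self.genotype = np.zeros(cap, dtype=np.int64)
        self.alive_list = np.zeros(cap, dtype=np.int32)
        self.pos_in_alive = np.full(cap, -1, dtype=np.int32)
        self.brate_alive = np.zeros(cap)
        self.stamp = np.zeros(cap, dtype=np.int64)
        self.affected = np.zeros(cap, dtype=np.int32)

    def _grow(self):
        old_cap = self.cap
        cap = old_cap * 2
        for name in ("pos", "genotype", "alive_list", "pos_in_alive",
                     "brate_alive", "stamp", "affected"):
            arr = getattr(self, name)
            new = np.zeros((cap,) + arr.shape[1:], dtype=arr.dtype)
            new[:old_cap] = arr
            setattr(self, name, new)
        self.pos_in_alive[old_cap:] = -1
        self.cap = cap

    # -- bookkeeping ---------------------------------------------------------

    def _add_cell(self, position, genotype, insert_grid=True):
        if self.n_slots >= self.cap:
            self._grow()
        slot = self.n_slots
        self.n_slots += 1
        self.pos[slot] = position
        self.genotype[slot] = genotype
        if insert_grid:
            flat = K.bin_of(self.pos, slot, self.origin, self.inv_bw, self.nb, self.dim)
            if flat < 0 or not K.grid_insert(self.gcount, self.gcells, flat, slot):
                raise RuntimeError("cell outside simulation box or bucket overflow")
        ai = self.n_alive
        self.alive_list[ai] = slot
        self.pos_in_alive[slot] = ai
        self.brate_alive[ai] = 0.0 if self.surface_mode else self.p.b0
        if not self.surface_mode:
            self.total_b += self.p.b0
        self.n_alive += 1
        return slot

    def _remove_cell(self, slot):
        flat = K.bin_of(self.pos, slot, self.origin, self.inv_bw, self.nb, self.dim)
        K.grid_remove(self.gcount, self.gcells, flat, slot)
        ai = self.pos_in_alive[slot]
        last = self.n_alive - 1
        self.total_b -= self.brate_alive[ai]
        if ai != last:
            moved_slot = self.alive_list[last]
            self.alive_list[ai] = moved_slot
            self.brate_alive[ai] = self.brate_alive[last]
            self.pos_in_alive[moved_slot] = ai
        self.pos_in_alive[slot] = -1
        self.n_alive = last

    def _update_densities(self, changed_pos):
        self._stamp_val += 1
        cp = np.ascontiguousarray(changed_pos)
        delta, _ = K.update_densities(
            self.pos, self.gcount, self.gcells, self.origin, self.inv_bw,
            self.nb, self.dim, cp, cp.shape[0], self.stamp, self._stamp_val,
            self.affected, self.p.dens_radius, 1.2 * self.p.min_dist,
            self.p.b0, self.p.rho_c, self._ball, self.brate_alive,
            self.pos_in_alive)
        self.total_b += delta

    def _record_history(self):
        self._hist_t.append(self.time)
        self._hist_n.append(self.n_alive)

    def _unit_direction(self):
        while True:
            v = self.rng.normal(size=self.dim)
            norm = np.linalg.norm(v)
            if norm > 1e-12:
                return v / norm

    # -- events --------------------------------------------------------------

    def divide(self, slot: int):
        """Division of the cell in `slot`: place daughter, resolve overlaps,
        draw mutations for mother and daughter."""
        if self.pos_in_alive[slot] < 0:
            raise ValueError(f"cell {slot} is not alive")
        p = self.p
        g0 = int(self.genotype[slot])
        # the kernel sets the daughter's position and inserts it into the grid
        daughter = self._add_cell(self.pos[slot], g0, insert_grid=False)
        n_moved, status = K.place_and_resolve(
            self.pos, self.gcount, self.gcells, self.origin, self.inv_bw,
            self.nb, self.dim, slot, daughter, self._unit_direction(),
            p.min_dist, p.margin, self.queue, self.nbr_buf, self.moved_pos,
            self.max_pushes)
        if status == K.STATUS_OUT_OF_BOUNDS:
            raise RuntimeError("population outgrew the simulation box")
        if status != K.STATUS_OK:
            raise RuntimeError(f"push cascade failed with status {status}")
        self.births += 1
        # mutations: both mother and daughter draw Poisson(mu) new mutations
        popsize = self.n_alive
        self.tree.live_count[g0] += 1  # daughter provisionally inherits g0
        for cell in (slot, daughter):
            k = draw_mutation_count(p.mu, self.rng)
            if k > 0:
                g_new = self.tree.add_node(g0, k, self.time, popsize)
                self.tree.live_count[g0] -= 1
                self.tree.live_count[g_new] += 1
                self.genotype[cell] = g_new
        if self.surface_mode:
            nm = n_moved
            self.moved_pos[nm] = self.pos[daughter]
            self._update_densities(self.moved_pos[: nm + 1])
        self.last_division = daughter
        self.last_division_mother = slot
        return daughter

    def kill(self, slot: int):
        if self.pos_in_alive[slot] < 0:
            raise ValueError(f"cell {slot} is not alive")
        dead_pos = self.pos[slot].copy()
        self._remove_cell(slot)
        self.tree.live_count[int(self.genotype[slot])] -= 1
        self.deaths += 1
        if self.surface_mode:
            self._update_densities(dead_pos[None, :])

    def step(self) -> str:
        """One Gillespie event; returns 'division' or 'death'."""
        n = self.n_alive
        if self.surface_mode and self.events % 1024 == 0:
            self.total_b = float(self.brate_alive[:n].sum())
        total_b = self.total_b if self.surface_mode else self.p.b0 * n
        total_rate = total_b + self.p.d * n
        self.time += self.rng.exponential(1.0 / total_rate)
        u = self.rng.random() * total_rate
        self.events += 1
        if u < total_b:
            if self.surface_mode:
                cs = np.cumsum(self.brate_alive[:n])
                ai = min(int(np.searchsorted(cs, u, side="right")), n - 1)
            else:
                ai = int(self.rng.integers(n))
            self.divide(int(self.alive_list[ai]))
            return "division"
        ai = int(self.rng.integers(n))
        self.kill(int(self.alive_list[ai]))
        return "death"

    def run(self, validate_geometry: bool = False, history_every: int = 64) -> Population:
        p = self.p
        tol = p.min_dist - 1e-6
        while 0 < self.n_alive < p.n_max and self.time < p.t_max:
            if p.max_events is not None and self.events >= p.max_events:
                return self.snapshot(timed_out=True)
            self.step()
            if self.events % history_every == 0:
                self._record_history()
            if validate_geometry and self.n_alive > 1:
                md = K.min_pairwise_dist(self.pos, self.alive_list, self.n_alive)
                if md < tol:
                    raise AssertionError(
                        f"overlap after event {self.events}: min distance {md}")
        self._record_history()
        return self.snapshot()

    def snapshot(self, timed_out: bool = False) -> Population:
        slots = self.alive_list[: self.n_alive].copy()
        order = np.sort(slots)
        return Population(
            cell_ids=order.astype(np.int64),
            positions=self.pos[order].copy(),
            genotypes=self.genotype[order].copy(),
            tree=self.tree,
            time=self.time,
            births=self.births,
            deaths=self.deaths,
            extinct=self.n_alive == 0,
            params=self.p,
            timed_out=timed_out,
            history=np.column_stack([self._hist_t, self._hist_n]),
        )

    @classmethod
    def from_positions(cls, positions, params: SimParams, genotypes=None) -> "Simulation":
        """Build a simulation state from explicit cell positions (for tests
        and for dissecting single events)."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if positions.shape[1] != params.dimension:
            raise ValueError("position dimension does not match params.dimension")
        sim = cls(params)
        # discard the seed cell placed by __init__
        sim._remove_cell(0)
        sim.tree.live_count[0] = 0
        sim.n_slots = 0
        for row in positions:
            g = 0
            sim._add_cell(row, g)
        sim.tree.live_count[0] = len(positions)
        if genotypes is not None:
            raise NotImplementedError("custom genotypes not supported here")
        if sim.surface_mode:
            sim._update_densities(positions)
        return sim


def local_density(cell_id: int, pop: Population, p: SimParams | None = None) -> float:
    """Count of other cells within the density window, per window measure."""
    p = p or pop.params
    idx = np.flatnonzero(pop.cell_ids == cell_id)
    if idx.size == 0:
        raise ValueError(f"no cell with id {cell_id}")
    x = pop.positions[idx[0]]
    d2 = ((pop.positions - x) ** 2).sum(axis=1)
    cnt = int((d2 <= p.dens_radius**2).sum()) - 1
    return cnt / ball_measure(p.dens_radius, p.dimension)


def divide_cell(sim: Simulation, cell_id: int) -> int:
    """Trigger a division of the given cell; returns the daughter's id."""
    return sim.divide(cell_id)


def push_apart(positions, seed_index: int, params: SimParams):
    """Resolve overlaps around ``positions[seed_index]`` with the width-first
    push cascade; returns the new position array."""
    sim = Simulation.from_positions(positions, params)
    n_moved, status = K.resolve_overlaps(
        sim.pos, sim.gcount, sim.gcells, sim.origin, sim.inv_bw, sim.nb,
        sim.dim, seed_index, params.min_dist, params.margin, sim.queue,
        sim.nbr_buf, sim.moved_pos, sim.max_pushes)
    if status != K.STATUS_OK:
        raise RuntimeError(f"push cascade failed with status {status}")
    return sim.pos[: len(positions)].copy()


def simulate(params: SimParams, validate_geometry: bool = False) -> Population:
    """Run a full simulation from a single wildtype cell.

    Stops when the population reaches ``n_max`` (success), goes extinct
    (``extinct`` flag set), or exceeds ``t_max``/``max_events``.
    Fully reproducible given ``params.seed``.
    """
    return Simulation(params).run(validate_geometry=validate_geometry)


def simulate_surviving(params: SimParams, max_retries: int = 200) -> Population:
    """Repeat the simulation with derived seeds until the population survives
    to ``n_max``, mirroring analyses conditioned on non-extinct tumours."""
    seed_rng = np.random.default_rng(params.seed)
    for _ in range(max_retries):
        sub = replace(params, seed=int(seed_rng.integers(0, 2**31 - 1)))
        pop = simulate(sub)
        if not pop.extinct and not pop.timed_out and pop.size >= params.n_max:
            return pop
    raise RuntimeError(f"no surviving run in {max_retries} attempts")
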