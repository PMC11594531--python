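"""Cell-turnover metrics and their inversion to death and mutation rates.

Cell death removes cells that already had offspring, producing 'orphan'
genotypes whose parental genotype no longer exists.  Two observable metrics
quantify this:

* clone turnover — the fraction of genotypes whose parental genotype is no
  longer extant (simulation truth) or never observed as a sample's exact
  mutation set (data);
* clade turnover — the fraction of clades (carrier sets of a mutation) that
  coincide with their ancestral clade, which requires the whole
  parent-minus-child lineage to have died out.

Both metrics increase with the relative death rate d/b; the clone turnover
additionally rises with the per-division mutation rate μ.  Inverting the map
(d/b, μ) → (clone turnover, clade turnover) — built here by seeded
simulation with the *identical* sampling and estimation pipeline applied to
the data — recovers the two rates, with bootstrap confidence intervals over
mutations.  Conventions on the data side (multi-mutation gains count as one
genotype event; a parent genotype is 'extant' iff its exact set is observed)
largely cancel because the inversion table shares them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .sampling import SamplePlan, SampleTable, sample_population
from .simulate import GenotypeTree, Population, SimParams, simulate_surviving

__all__ = [
    "clone_turnover_true",
    "clade_turnover_true",
    "observed_genotypes",
    "mutation_events",
    "clone_turnover",
    "clade_turnover",
    "turnover_statistics",
    "InversionTable",
    "build_inversion_table",
    "TurnoverEstimates",
    "infer_rates",
    "population_size_at_origin",
    "detected_origin_sizes",
    "per_site_rate",
]


# ---------------------------------------------------------------------------
# ground-truth metrics on the simulated genotype tree

def clone_turnover_true(tree: GenotypeTree) -> float:
    """Fraction of extant non-root genotypes whose parental genotype has no
    living cells."""
    live = np.asarray(tree.live_count)
    extant = np.flatnonzero(live > 0)
    extant = extant[extant != 0]
    if extant.size == 0:
        return np.nan
    parents = np.asarray(tree.parent)[extant]
    return float((live[parents] == 0).mean())


def clade_turnover_true(tree: GenotypeTree) -> float:
    """Fraction of extant clades that coincide with their ancestral clade.

    A clade is the set of live cells carrying the mutations gained at one
    genotype event; it coincides with the parent's clade when every live
    carrier of the parent's mutations also carries the child's.
    """
    sub = tree.subtree_live_counts()
    nodes = np.flatnonzero(sub > 0)
    nodes = nodes[nodes != 0]
    if nodes.size == 0:
        return np.nan
    parents = np.asarray(tree.parent)[nodes]
    return float((sub[nodes] == sub[parents]).mean())


# ---------------------------------------------------------------------------
# observed metrics on a sample table

def observed_genotypes(table: SampleTable):
    """Deduplicated per-sample detected mutation sets, arranged by subset
    containment.

    Returns (genotypes, parent_index): genotypes is a list of frozensets
    (the wildtype/empty set is prepended as the root if absent); parent of a
    genotype is its largest proper subset among the others (ties broken
    deterministically), the root otherwise.
    """
    det = table.detected()
    per_sample = det.groupby("sample_id")["mutation_id"].agg(frozenset)
    per_sample = per_sample.reindex(table.samples["sample_id"]).dropna()
    sets = sorted({frozenset()} | set(per_sample), key=lambda s: (len(s), sorted(s)))
    parent = []
    for i, g in enumerate(sets):
        best = -1
        for j, h in enumerate(sets):
            if j == i or len(h) >= len(g):
                continue
            if h <= g and (best < 0 or len(h) > len(sets[best])):
                best = j
        parent.append(best if best >= 0 else (0 if i else -1))
    return sets, np.asarray(parent)


def mutation_events(table: SampleTable, freq_decimals: int = 6):
    """Collapse detected mutations into genotype events and build the event
    containment tree.

    Mutations gained at the same division are carried by exactly the same
    cells, so their sampled frequency vectors are identical: mutations whose
    frequency vectors agree (to ``freq_decimals``) collapse into one event
    (multi-mutation gains count as one genotype event).  Two events can
    still share a carrier *sample* set while differing in frequencies —
    that is the footprint of a parental lineage partially converted by cell
    death, which the clade turnover counts.

    The parent of an event is the event whose carrier sample set contains
    its own with the smallest carrier count, frequencies breaking ties (the
    ancestral clade is at least as frequent everywhere); −1 (wildtype root)
    when none exists.  Returns a dict with the event definitions and the
    per-mutation mapping.
    """
    mut_ids, F, P = table.matrices()
    n_mut = len(mut_ids)
    if n_mut == 0:
        raise ValueError("no detected mutations")
    Fq = np.round(F, freq_decimals)
    groups: dict[bytes, list[int]] = {}
    for i in range(n_mut):
        groups.setdefault(Fq[i].tobytes(), []).append(i)
    order = sorted(groups)  # deterministic event numbering
    event_of_mut = np.empty(n_mut, dtype=np.int64)
    ev_P, ev_F, members = [], [], []
    for e, k in enumerate(order):
        idx = groups[k]
        for i in idx:
            event_of_mut[i] = e
        ev_P.append(P[idx[0]])
        ev_F.append(F[idx[0]])
        members.append(idx)
    ev_P = np.asarray(ev_P)
    ev_F = np.asarray(ev_F)
    n_ev = len(ev_P)
    ncar = ev_P.sum(axis=1)
    tot = ev_F.sum(axis=1)
    parent = np.full(n_ev, -1, dtype=np.int64)
    for e in range(n_ev):
        cover = ev_P[:, ev_P[e]].all(axis=1)
        sup = np.flatnonzero(cover & ((ncar > ncar[e]) |
                                      ((ncar == ncar[e]) & (tot > tot[e] + 1e-9))))
        if sup.size:
            o = np.lexsort((np.arange(n_ev)[sup], tot[sup], ncar[sup]))
            parent[e] = sup[o[0]]
    return {
        "mut_ids": mut_ids,
        "event_of_mut": event_of_mut,
        "members": members,
        "presence": ev_P,
        "freq": ev_F,
        "parent": parent,
        "total_freq": tot,
        "n_carriers": ncar,
    }


def _path_sets(events, table: SampleTable):
    """Implied genotype (set of mutation ids on the root path) of each event."""
    parent = events["parent"]
    mut_ids = events["mut_ids"]
    memo: dict[int, frozenset] = {-1: frozenset()}

    def path(e: int) -> frozenset:
        if e in memo:
            return memo[e]
        own = frozenset(int(mut_ids[i]) for i in events["members"][e])
        memo[e] = path(int(parent[e])) | own
        return memo[e]

    return [path(e) for e in range(len(parent))]


def clone_turnover(table: SampleTable, events=None):
    """Observed clone turnover with per-event indicators.

    An event's parental genotype is the implied mutation set of its parent
    event (the wildtype for root children); it counts as no-longer-extant
    when no sample's exact detected set equals it.  Returns
    (turnover, per-event indicator array, events dict).
    """
    events = events or mutation_events(table)
    det = table.detected()
    sample_sets = set(det.groupby("sample_id")["mutation_id"]
                      .agg(lambda s: frozenset(int(x) for x in s)))
    nonempty = set(det["sample_id"])
    if len(nonempty) < table.n_samples:
        has_cells = table.samples.loc[table.samples["cell_count"] > 0, "sample_id"]
        if len(set(has_cells) - nonempty):
            sample_sets.add(frozenset())  # a wildtype-only sample
    paths = _path_sets(events, table)
    parent = events["parent"]
    ind = np.empty(len(parent), dtype=bool)
    for e, pe in enumerate(parent):
        pset = paths[int(pe)] if pe >= 0 else frozenset()
        ind[e] = pset not in sample_sets
    return float(ind.mean()), ind, events


def clade_turnover(table: SampleTable, events=None):
    """Observed clade turnover with per-mutation indicators.

    A mutation's clade coincides with its ancestral clade when both cover
    the same carrier samples: the parent event has an identical presence
    set (frequencies differing — the parental lineage has been converted
    wherever it was detectable), or the event is truncal and its ancestral
    clade is the whole tumour.  Returns (turnover, per-mutation indicator
    array, events dict).
    """
    events = events or mutation_events(table)
    n_mut = len(events["mut_ids"])
    n_nonempty = int((table.samples["cell_count"] > 0).sum())
    parent = events["parent"]
    P = events["presence"]
    ind = np.zeros(n_mut, dtype=bool)
    for e, idx in enumerate(events["members"]):
        pe = int(parent[e])
        if pe >= 0:
            coincide = bool((P[e] == P[pe]).all())
        else:
            coincide = P[e].sum() >= n_nonempty  # truncal: root clade
        for i in idx:
            ind[i] = coincide
    return float(ind.mean()), ind, events


def turnover_statistics(table: SampleTable, genotype_freq_min: float = 0.5):
    """(clone turnover, clade turnover) plus the indicator structures needed
    for bootstrapping over mutations.

    ``genotype_freq_min`` re-thresholds the table first: the genotype of a
    sample is its *consensus* set — mutations carried by at least this
    fraction of its cells.  A union over every cell in the disc would
    saturate the clone turnover, since no sample's set would ever equal a
    parental genotype.  The same threshold must be (and is) used when
    building the inversion table.
    """
    from .sampling import apply_detection

    if genotype_freq_min is not None:
        table = apply_detection(table, genotype_freq_min)
    events = mutation_events(table)
    clone_t, clone_ind, _ = clone_turnover(table, events)
    clade_t, clade_ind, _ = clade_turnover(table, events)
    # mean consensus-genotype size per non-empty sample; additive over
    # mutations, which makes it bootstrappable the same way
    n_nonempty = max(int((table.samples["cell_count"] > 0).sum()), 1)
    mut_ids, F, P = table.matrices()
    burden_per_mut = P.sum(axis=1) / n_nonempty
    return {
        "clone_turnover": clone_t,
        "clade_turnover": clade_t,
        "burden": float(burden_per_mut.sum()),
        "multiplicity": len(events["mut_ids"]) / len(events["parent"]),
        "clone_ind": clone_ind,
        "clade_ind": clade_ind,
        "burden_per_mut": burden_per_mut,
        "event_of_mut": events["event_of_mut"],
        "n_mutations": len(events["mut_ids"]),
        "n_events": len(events["parent"]),
    }


# ---------------------------------------------------------------------------
# inversion table

@dataclass
class InversionTable:
    """Simulation-derived map (d/b, μ) → expected summary statistics.

    Three statistics are stored per grid point: clone turnover, clade
    turnover and the mean per-sample consensus burden.  The two turnovers
    alone do not identify (d/b, μ) on sampled data — the observed clade
    turnover picks up multi-mutation gain events and so rises with μ as well
    as with d/b — while the burden axis separates the resulting ridge.
    Inversion is nearest-statistics lookup on a bilinearly interpolated fine
    mesh, each statistic standardised by its range over the table (burden on
    a log scale).
    """

    db_grid: np.ndarray
    mu_grid: np.ndarray
    clone_t: np.ndarray  # shape (len(db_grid), len(mu_grid))
    clade_t: np.ndarray
    burden_t: np.ndarray
    mult_t: np.ndarray
    sim_params: dict = field(default_factory=dict)
    plan: dict = field(default_factory=dict)
    mesh_points: int = 80

    def __post_init__(self):
        self.db_grid = np.asarray(self.db_grid, dtype=float)
        self.mu_grid = np.asarray(self.mu_grid, dtype=float)
        self.clone_t = np.asarray(self.clone_t, dtype=float)
        self.clade_t = np.asarray(self.clade_t, dtype=float)
        self.burden_t = np.asarray(self.burden_t, dtype=float)
        self.mult_t = np.asarray(self.mult_t, dtype=float)
        self._build_mesh()

    def _standardise(self, stats: np.ndarray) -> np.ndarray:
        out = np.empty_like(stats, dtype=float)
        out[:, 0] = stats[:, 0] / self._scale[0]
        out[:, 1] = stats[:, 1] / self._scale[1]
        out[:, 2] = np.log(np.maximum(stats[:, 2], 1e-6)) / self._scale[2]
        out[:, 3] = np.log(np.maximum(stats[:, 3], 1e-6)) / self._scale[3]
        return out

    def _build_mesh(self):
        db_f = np.linspace(self.db_grid[0], self.db_grid[-1], self.mesh_points)
        mu_f = np.geomspace(self.mu_grid[0], self.mu_grid[-1], self.mesh_points)
        grid = (self.db_grid, np.log(self.mu_grid))
        interp = [RegularGridInterpolator(grid, z)
                  for z in (self.clone_t, self.clade_t, self.burden_t,
                            self.mult_t)]
        DB, MU = np.meshgrid(db_f, mu_f, indexing="ij")
        pts = np.column_stack([DB.ravel(), np.log(MU.ravel())])
        self._mesh_db = DB.ravel()
        self._mesh_mu = MU.ravel()
        stats = np.column_stack([f(pts) for f in interp])
        self._scale = np.array([
            max(np.ptp(self.clone_t), 0.05),
            max(np.ptp(self.clade_t), 0.05),
            max(np.ptp(np.log(np.maximum(self.burden_t, 1e-6))), 0.05),
            max(np.ptp(np.log(np.maximum(self.mult_t, 1e-6))), 0.05),
        ])
        self._mesh_stats = stats
        self._tree = cKDTree(self._standardise(stats))
        self._boundary = ((DB == DB.min()) | (DB == DB.max()) |
                          (MU == MU.min()) | (MU == MU.max())).ravel()

    def invert(self, clone_t, clade_t, burden, multiplicity):
        """Nearest-statistics inversion on the interpolated mesh.

        Accepts scalars or arrays; returns (d/b, μ, extrapolated-flag)."""
        q = np.column_stack([np.atleast_1d(clone_t), np.atleast_1d(clade_t),
                             np.atleast_1d(burden),
                             np.atleast_1d(multiplicity)])
        _, idx = self._tree.query(self._standardise(q))
        db = self._mesh_db[idx]
        mu = self._mesh_mu[idx]
        extra = self._boundary[idx]
        if np.isscalar(clone_t):
            return float(db[0]), float(mu[0]), bool(extra[0])
        return db, mu, extra

    def check_monotone(self) -> dict:
        """Monotonicity along the d/b axis (both metrics should increase)."""
        return {
            "clone_up_db": bool(np.all(np.diff(self.clone_t, axis=0) >= -0.05)),
            "clade_up_db": bool(np.all(np.diff(self.clade_t, axis=0) >= -0.05)),
        }

    def to_dict(self) -> dict:
        return {
            "db_grid": self.db_grid.tolist(),
            "mu_grid": self.mu_grid.tolist(),
            "clone_t": self.clone_t.tolist(),
            "clade_t": self.clade_t.tolist(),
            "burden_t": self.burden_t.tolist(),
            "mult_t": self.mult_t.tolist(),
            "sim_params": self.sim_params,
            "plan": self.plan,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InversionTable":
        return cls(d["db_grid"], d["mu_grid"], d["clone_t"], d["clade_t"],
                   d["burden_t"], d["mult_t"],
                   d.get("sim_params", {}), d.get("plan", {}))


def _default_plan(n_samples=280, detection_freq_min=0.05, seed=0) -> SamplePlan:
    return SamplePlan(layout="honeycomb", n_samples=n_samples,
                      detection_freq_min=detection_freq_min, seed=seed)


def build_inversion_table(db_grid, mu_grid, n_max=3000, dimension=2, b0=1.0,
                          reps=2, seed=0, plan: SamplePlan | None = None,
                          genotype_freq_min: float = 0.5,
                          progress=False) -> InversionTable:
    """Seeded simulations at every (d/b, μ) grid point, sampled and processed
    with the same estimators as real data; replicate means are stored."""
    db_grid = np.asarray(db_grid, dtype=float)
    mu_grid = np.asarray(mu_grid, dtype=float)
    plan = plan or _default_plan(seed=seed)
    seed_rng = np.random.default_rng(seed)
    clone = np.zeros((db_grid.size, mu_grid.size))
    clade = np.zeros_like(clone)
    burden = np.zeros_like(clone)
    mult = np.zeros_like(clone)
    for i, db in enumerate(db_grid):
        for j, mu in enumerate(mu_grid):
            cl, cd, bu, ml = [], [], [], []
            for _ in range(reps):
                p = SimParams(dimension=dimension, b0=b0, d=db * b0, mu=mu,
                              n_max=n_max,
                              seed=int(seed_rng.integers(0, 2**31 - 1)))
                pop = simulate_surviving(p)
                table = sample_population(pop, plan)
                st = turnover_statistics(table, genotype_freq_min)
                cl.append(st["clone_turnover"])
                cd.append(st["clade_turnover"])
                bu.append(st["burden"])
                ml.append(st["multiplicity"])
            clone[i, j] = np.mean(cl)
            clade[i, j] = np.mean(cd)
            burden[i, j] = np.mean(bu)
            mult[i, j] = np.mean(ml)
            if progress:
                print(f"d/b={db:.2f} mu={mu:.2f}: clone={clone[i,j]:.3f} "
                      f"clade={clade[i,j]:.3f} burden={burden[i,j]:.2f}")
    return InversionTable(
        db_grid, mu_grid, clone, clade, burden, mult,
        sim_params={"n_max": n_max, "dimension": dimension, "b0": b0,
                    "reps": reps, "seed": seed,
                    "genotype_freq_min": genotype_freq_min},
        plan={"layout": plan.layout, "n_samples": plan.n_samples,
              "detection_freq_min": plan.detection_freq_min})


# ---------------------------------------------------------------------------
# inference

@dataclass
class TurnoverEstimates:
    clone_turnover: float
    clade_turnover: float
    n_genotypes: int
    n_clades: int
    death_ratio: float
    death_ratio_ci: tuple[float, float]
    mu: float
    mu_ci: tuple[float, float]
    extrapolated: bool
    subsample_fractions: tuple[float, ...] = ()
    subsample_death_ratio: tuple[float, ...] = ()
    subsample_mu: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "clone_turnover": self.clone_turnover,
            "clade_turnover": self.clade_turnover,
            "n_genotypes": self.n_genotypes,
            "n_clades": self.n_clades,
            "death_ratio": self.death_ratio,
            "death_ratio_ci": list(self.death_ratio_ci),
            "mu": self.mu,
            "mu_ci": list(self.mu_ci),
            "extrapolated": self.extrapolated,
            "subsample_fractions": list(self.subsample_fractions),
            "subsample_death_ratio": list(self.subsample_death_ratio),
            "subsample_mu": list(self.subsample_mu),
        }


def infer_rates(table: SampleTable, inversion: InversionTable,
                n_boot: int = 1000, ci: float = 0.90,
                subsample_fractions=(0.5, 0.6, 0.7, 0.8, 0.9),
                seed: int = 0) -> TurnoverEstimates:
    """Invert observed turnovers to (d/b, μ) with bootstrap CIs.

    The genotype consensus threshold is taken from the inversion table so
    data and table share one pipeline.  The bootstrap resamples mutations
    with replacement and recomputes both turnovers as draw-weighted means of
    the per-unit indicators (clone turnover over events weighted by their
    sampled mutations, clade turnover over mutations), then re-inverts each
    replicate.  Subsampling fractions re-infer on random mutation subsets
    with μ rescaled by 1/fraction, probing robustness to incomplete mutation
    detection.
    """
    from .sampling import apply_detection

    gmin = inversion.sim_params.get("genotype_freq_min", 0.5)
    if gmin is not None:
        table = apply_detection(table, gmin)
    rng = np.random.default_rng(seed)
    st = turnover_statistics(table, genotype_freq_min=None)
    db_hat, mu_hat, extra = inversion.invert(
        st["clone_turnover"], st["clade_turnover"], st["burden"],
        st["multiplicity"])
    m = st["n_mutations"]
    eom = st["event_of_mut"]
    clade_ind = st["clade_ind"].astype(float)
    clone_ind = st["clone_ind"].astype(float)
    bpm = st["burden_per_mut"]
    # bootstrap over mutations
    draws = rng.integers(0, m, size=(n_boot, m))
    clade_b = clade_ind[draws].mean(axis=1)
    burden_b = bpm[draws].sum(axis=1)
    ev_draws = eom[draws]
    n_ev = st["n_events"]
    clone_b = np.empty(n_boot)
    mult_b = np.empty(n_boot)
    for r in range(n_boot):
        w = np.bincount(ev_draws[r], minlength=n_ev)
        clone_b[r] = (clone_ind * w).sum() / m
        mult_b[r] = m / max(int((w > 0).sum()), 1)
    db_b, mu_b, _ = inversion.invert(clone_b, clade_b, burden_b, mult_b)
    alpha = (1.0 - ci) / 2.0
    db_ci = (float(np.quantile(db_b, alpha)), float(np.quantile(db_b, 1 - alpha)))
    mu_ci = (float(np.quantile(mu_b, alpha)), float(np.quantile(mu_b, 1 - alpha)))
    # subsampling robustness
    all_ids = mutation_events(table)["mut_ids"]
    sub_db, sub_mu = [], []
    for frac in subsample_fractions:
        keep_ids = rng.choice(m, size=max(2, int(round(frac * m))), replace=False)
        chosen = set(int(all_ids[i]) for i in keep_ids)
        sub_table = SampleTable(
            table.samples,
            table.calls[table.calls["mutation_id"].isin(chosen)],
            dim=table.dim)
        try:
            sub_st = turnover_statistics(sub_table, genotype_freq_min=None)
        except ValueError:
            continue
        dbs, mus, _ = inversion.invert(sub_st["clone_turnover"],
                                       sub_st["clade_turnover"],
                                       sub_st["burden"] / frac,
                                       sub_st["multiplicity"] / frac)
        sub_db.append(float(dbs))
        sub_mu.append(float(mus) / frac)
    return TurnoverEstimates(
        clone_turnover=st["clone_turnover"],
        clade_turnover=st["clade_turnover"],
        n_genotypes=st["n_events"],
        n_clades=st["n_events"],
        death_ratio=float(db_hat),
        death_ratio_ci=db_ci,
        mu=float(mu_hat),
        mu_ci=mu_ci,
        extrapolated=bool(extra),
        subsample_fractions=tuple(subsample_fractions[: len(sub_db)]),
        subsample_death_ratio=tuple(sub_db),
        subsample_mu=tuple(sub_mu),
    )


# ---------------------------------------------------------------------------
# population size at origin and per-site rate

def population_size_at_origin(f_min: float) -> float:
    """Population size when a mutation of final whole-tumour frequency f
    arose, under neutral deterministic growth: N = 1/f."""
    if not 0 < f_min <= 1:
        raise ValueError("frequency must be in (0, 1]")
    return 1.0 / f_min


def detected_origin_sizes(pop: Population, table: SampleTable) -> np.ndarray:
    """Population sizes at which the detected mutations arose (simulation
    truth): the empirical counterpart of 1/f_min under spatial sampling and
    stochastic growth."""
    det = table.detected()
    mut_ids = np.sort(det["mutation_id"].unique()).astype(int)
    node = pop.tree.mutation_node()
    bp = np.asarray(pop.tree.birth_popsize)
    return bp[node[mut_ids]]


def per_site_rate(mu: float, n_effective_sites: float,
                  ploidy_factor: float = 1.0) -> float:
    """Per-site mutation rate: μ divided by the effective number of sites
    times the ploidy convention factor."""
    if n_effective_sites <= 0:
        raise ValueError("n_effective_sites must be positive")
    if ploidy_factor <= 0:
        raise ValueError("ploidy_factor must be positive")
    return mu / (ploidy_factor * n_effective_sites)
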