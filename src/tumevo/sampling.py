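"""Virtual multi-region sampling of simulated tumours.

Mimics the multi-region designs of genotyped hepatocellular-carcinoma
studies: evenly spaced sample discs (honeycomb or square grids, or verbatim
positions from the real tumour's geometry) are placed over a tumour section,
each sample reporting the within-sample frequency of every mutation carried
by the cells inside its disc.  Detection thresholds and optional simulated
read counts emulate limited sequencing resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .simulate import Population, GenotypeTree

__all__ = [
    "SamplePlan",
    "SampleTable",
    "take_cross_section",
    "place_samples",
    "collect_samples",
    "apply_detection",
    "simulate_reads",
    "sample_population",
    "honeycomb_positions",
]


class SampleTable:
    """Per-(sample, mutation) frequencies with sample coordinates.

    ``samples``: one row per sample (sample_id, x, y[, z], cell_count) —
    empty samples are kept with cell_count 0 and no call rows.
    ``calls``: one row per (sample_id, mutation_id) with frequency in [0, 1],
    a presence flag and optional alt_reads / total_reads.
    """

    SAMPLE_COLS = ["sample_id", "x", "y", "z", "cell_count"]
    CALL_COLS = ["sample_id", "mutation_id", "frequency", "present",
                 "alt_reads", "total_reads"]

    def __init__(self, samples: pd.DataFrame, calls: pd.DataFrame, dim: int = 2):
        self.dim = dim
        self.samples = samples.reset_index(drop=True)
        self.calls = calls.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def positions(self) -> np.ndarray:
        cols = ["x", "y", "z"][: self.dim]
        return self.samples[cols].to_numpy(dtype=float)

    def sample_index(self) -> pd.Series:
        return pd.Series(np.arange(self.n_samples), index=self.samples["sample_id"])

    def detected(self) -> pd.DataFrame:
        return self.calls[self.calls["present"]]

    def matrices(self):
        """(mutation_ids, frequency matrix, presence matrix), matrices shaped
        (n_mutations, n_samples) over detected calls."""
        det = self.detected()
        mut_ids = np.sort(det["mutation_id"].unique())
        mpos = pd.Series(np.arange(len(mut_ids)), index=mut_ids)
        spos = self.sample_index()
        F = np.zeros((len(mut_ids), self.n_samples))
        F[mpos[det["mutation_id"]].to_numpy(), spos[det["sample_id"]].to_numpy()] = \
            det["frequency"].to_numpy()
        P = F > 0
        return mut_ids, F, P

    def whole_tumour_frequencies(self) -> pd.Series:
        """Aggregate frequency of each mutation over all sampled cells."""
        cells = self.samples.set_index("sample_id")["cell_count"]
        total = cells.sum()
        carriers = (self.calls["frequency"] *
                    self.calls["sample_id"].map(cells)).groupby(
                        self.calls["mutation_id"]).sum()
        return carriers / total

    def to_frame(self) -> pd.DataFrame:
        """Flat one-file representation (empty samples keep a row with no
        mutation)."""
        flat = self.samples.merge(self.calls, on="sample_id", how="left")
        flat["mutation_id"] = flat["mutation_id"].astype("Int64")
        return flat

    @classmethod
    def from_frame(cls, flat: pd.DataFrame, dim: int | None = None) -> "SampleTable":
        if dim is None:
            dim = 3 if ("z" in flat.columns and flat["z"].notna().any()) else 2
        if "z" not in flat.columns:
            flat = flat.assign(z=np.nan)
        samples = (flat[["sample_id", "x", "y", "z", "cell_count"]]
                   .drop_duplicates("sample_id"))
        calls = flat.loc[flat["mutation_id"].notna(),
                         [c for c in cls.CALL_COLS if c in flat.columns]].copy()
        calls["mutation_id"] = calls["mutation_id"].astype(np.int64)
        if "present" not in calls.columns:
            calls["present"] = calls["frequency"] > 0
        return cls(samples, calls, dim=dim)


@dataclass
class SamplePlan:
    """Sampling design: layout, disc size and detection thresholds."""

    layout: str = "honeycomb"  # honeycomb | square | positions
    n_samples: int = 280
    sample_radius: float | None = None  # default: half the grid spacing
    positions: np.ndarray | None = None  # used when layout == "positions"
    section_axis: int | None = None  # 3D -> 2D cut axis (0, 1 or 2)
    section_value: float = 0.0
    section_thickness: float = 2.0
    detection_freq_min: float = 0.05
    whole_tumour_freq_min: float | None = None
    read_depth: float | None = None
    vaf: str = "cell-fraction"  # or "diploid" (reads drawn at frequency/2)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if not 0 <= self.detection_freq_min <= 1:
            raise ValueError("detection_freq_min must be in [0, 1]")
        if self.layout not in ("honeycomb", "square", "positions"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "positions" and self.positions is None:
            raise ValueError("layout 'positions' requires a positions array")


def take_cross_section(pop: Population, axis: int = 2, value: float = 0.0,
                       thickness: float = 2.0):
    """Cells within a slab |coordinate − value| ≤ thickness/2, projected to
    the plane.  Returns (positions_2d, genotypes)."""
    if pop.params.dimension != 3:
        raise ValueError("cross-sections require a 3D population")
    keep = np.abs(pop.positions[:, axis] - value) <= thickness / 2.0
    if not keep.any():
        raise ValueError("cross-section contains no cells")
    other = [d for d in range(3) if d != axis]
    return pop.positions[np.ix_(keep, other)], pop.genotypes[keep]


def honeycomb_positions(n: int, spacing: float = 1.0,
                        center=(0.0, 0.0)) -> np.ndarray:
    """The n points of a triangular (honeycomb) lattice closest to `center`,
    deterministically ordered."""
    reach = int(np.ceil(np.sqrt(n))) + 3
    ii, jj = np.meshgrid(np.arange(-reach, reach + 1),
                         np.arange(-reach, reach + 1), indexing="ij")
    x = (ii + 0.5 * jj).ravel() * spacing + center[0]
    y = (jj * np.sqrt(3) / 2).ravel() * spacing + center[1]
    pts = np.column_stack([x, y])
    d = np.linalg.norm(pts - np.asarray(center), axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], np.round(d, 9)))
    if len(order) < n:
        raise ValueError("lattice patch too small")
    return pts[order[:n]]


def _lattice(layout: str, spacing: float, center, reach: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(-reach, reach + 1),
                         np.arange(-reach, reach + 1), indexing="ij")
    if layout == "honeycomb":
        x = (ii + 0.5 * jj).ravel() * spacing
        y = (jj * np.sqrt(3) / 2).ravel() * spacing
    else:
        x = ii.ravel() * spacing
        y = jj.ravel() * spacing
    return np.column_stack([x + center[0], y + center[1]])


def place_samples(cell_positions: np.ndarray, plan: SamplePlan):
    """Evenly spaced sample centres clipped to the occupied region.

    Returns (centers, spacing).  The lattice spacing is found by bisection so
    that at least ``n_samples`` lattice points fall on the occupied region;
    the n closest to the centroid are kept (deterministic).
    """
    cell_positions = np.asarray(cell_positions, dtype=float)
    if plan.layout == "positions":
        centers = np.asarray(plan.positions, dtype=float)
        nn = 2.0 * (plan.sample_radius or 1.0)
        if len(centers) > 1:
            tr = cKDTree(centers)
            nn = tr.query(centers, k=2)[0][:, 1].min()
        return centers, nn
    center = cell_positions.mean(axis=0)
    if plan.n_samples == 1:
        return center[None, :], np.inf
    tree = cKDTree(cell_positions)
    extent = np.linalg.norm(cell_positions - center, axis=1).max()

    def occupied_count(s):
        pts = _lattice(plan.layout, s, center, int(extent / s) + 2)
        d, _ = tree.query(pts, k=1)
        return int((d <= max(s / 2.0, 1.0)).sum())

    lo, hi = 1e-3 * extent, 2.2 * extent
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if occupied_count(mid) >= plan.n_samples:
            lo = mid
        else:
            hi = mid
    s = lo
    pts = _lattice(plan.layout, s, center, int(extent / s) + 2)
    d, _ = tree.query(pts, k=1)
    pts = pts[d <= max(s / 2.0, 1.0)]
    dc = np.linalg.norm(pts - center, axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], np.round(dc, 9)))
    return pts[order[: plan.n_samples]], s


def _genotype_mutation_lists(tree: GenotypeTree, genotypes: np.ndarray) -> dict:
    """Memoized mutation lists for the genotypes present in a section."""
    cache: dict[int, np.ndarray] = {}

    def muts(g: int) -> np.ndarray:
        got = cache.get(g)
        if got is None:
            if g <= 0:
                got = tree.mutations_gained(0) if g == 0 else np.empty(0, dtype=np.int64)
            else:
                got = np.concatenate([muts(tree.parent[g]), tree.mutations_gained(g)])
            cache[g] = got
        return got

    for g in np.unique(genotypes):
        muts(int(g))
    return cache


def collect_samples(cell_positions: np.ndarray, genotypes: np.ndarray,
                    tree: GenotypeTree, centers: np.ndarray,
                    radius: float) -> SampleTable:
    """Assemble the sample table: frequency of a mutation in a sample is
    (carriers in disc) / (cells in disc)."""
    if radius <= 0:
        raise ValueError("sample radius must be positive")
    cell_positions = np.asarray(cell_positions, dtype=float)
    centers = np.asarray(centers, dtype=float)
    dim = centers.shape[1]
    ctree = cKDTree(cell_positions)
    members = ctree.query_ball_point(centers, radius)
    mut_lists = _genotype_mutation_lists(tree, genotypes)

    sample_rows = []
    call_rows = []
    for si, idx in enumerate(members):
        sid = si
        cc = len(idx)
        coords = list(centers[si]) + [np.nan] * (3 - dim)
        sample_rows.append((sid, *coords, cc))
        if cc == 0:
            continue
        counts: dict[int, int] = {}
        gs, gc = np.unique(genotypes[idx], return_counts=True)
        for g, c in zip(gs, gc):
            for m in mut_lists[int(g)]:
                counts[int(m)] = counts.get(int(m), 0) + int(c)
        for m, c in sorted(counts.items()):
            call_rows.append((sid, m, c / cc, True, np.nan, np.nan))

    samples = pd.DataFrame(sample_rows, columns=SampleTable.SAMPLE_COLS)
    calls = pd.DataFrame(call_rows, columns=SampleTable.CALL_COLS)
    return SampleTable(samples, calls, dim=dim)


def apply_detection(table: SampleTable, detection_freq_min: float = 0.0,
                    whole_tumour_freq_min: float | None = None) -> SampleTable:
    """Limited-resolution filter: drop calls below the within-sample
    frequency threshold, and optionally drop mutations whose whole-tumour
    frequency is below ``whole_tumour_freq_min`` (e.g. 1/40)."""
    calls = table.calls[table.calls["frequency"] >= detection_freq_min].copy()
    if whole_tumour_freq_min is not None:
        wt = SampleTable(table.samples, calls, table.dim).whole_tumour_frequencies()
        keep = wt.index[wt.to_numpy() > whole_tumour_freq_min]
        calls = calls[calls["mutation_id"].isin(keep)]
    calls["present"] = calls["frequency"] > 0
    return SampleTable(table.samples, calls, dim=table.dim)


def simulate_reads(table: SampleTable, depth: float,
                   rng: np.random.Generator, vaf: str = "cell-fraction") -> SampleTable:
    """Draw read counts: total ~ Poisson(depth); alt ~ Binomial(total, q)
    with q the cell fraction (or half of it under the diploid convention)."""
    if depth <= 0:
        raise ValueError("read depth must be positive")
    calls = table.calls.copy()
    q = calls["frequency"].to_numpy(dtype=float)
    if vaf == "diploid":
        q = q / 2.0
    total = rng.poisson(depth, size=len(calls))
    alt = rng.binomial(total, np.clip(q, 0, 1))
    calls["total_reads"] = total
    calls["alt_reads"] = alt
    return SampleTable(table.samples, calls, dim=table.dim)


def sample_population(pop: Population, plan: SamplePlan) -> SampleTable:
    """Full sampling pipeline: optional 3D→2D cross-section, sample
    placement, collection, detection filter, optional read simulation."""
    if pop.params.dimension == 3 and plan.section_axis is not None:
        positions, genotypes = take_cross_section(
            pop, plan.section_axis, plan.section_value, plan.section_thickness)
    else:
        positions, genotypes = pop.positions, pop.genotypes
    centers, spacing = place_samples(positions, plan)
    radius = plan.sample_radius if plan.sample_radius is not None else spacing / 2.0
    table = collect_samples(positions, genotypes, pop.tree, centers, radius)
    table = apply_detection(table, plan.detection_freq_min, plan.whole_tumour_freq_min)
    if plan.read_depth is not None:
        rng = np.random.default_rng(plan.seed)
        table = simulate_reads(table, plan.read_depth, rng, vaf=plan.vaf)
    return table
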