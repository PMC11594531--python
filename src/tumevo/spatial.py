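"""Growth-mode diagnostics from multi-region sample tables.

Three spatial statistics discriminate surface from volume growth:

* the direction angle θ between (tumour centre → parent clone) and
  (parent clone → child clone): flat under isotropic volume growth, peaked
  near zero under radially outward surface growth;
* the mutation burden of a sample versus its distance from the tumour
  centre: increasing under surface growth, flat under volume growth;
* the dispersion parameter σ of a mutation: mean pairwise distance among
  carrying samples divided by the mean pairwise distance the same number of
  cells would have in the tightest (disc/ball) packing.  σ ≈ 1 marks a
  compact clone; σ ≫ 1 a clone scattered by cell pushing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .sampling import SampleTable
from .simulate import GenotypeTree

__all__ = [
    "tumour_centre",
    "clone_position",
    "direction_angle",
    "true_parent_map",
    "reconstruct_parent_map",
    "angle_distribution",
    "angle_uniformity_test",
    "radial_mutation_burden",
    "expected_packed_distance",
    "DispersionConfig",
    "dispersion_sigma",
    "dispersion_table",
    "ks_statistic",
]


def tumour_centre(table: SampleTable) -> np.ndarray:
    """Unweighted centroid of the sample positions."""
    return table.positions().mean(axis=0)


def clone_position(mutation: int, table: SampleTable) -> np.ndarray:
    """Frequency-weighted centroid of the samples carrying a mutation."""
    det = table.detected()
    rows = det[det["mutation_id"] == mutation]
    if rows.empty:
        raise ValueError(f"mutation {mutation} not detected in any sample")
    spos = table.sample_index()
    pts = table.positions()[spos[rows["sample_id"]].to_numpy()]
    w = rows["frequency"].to_numpy()
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def direction_angle(centre, parent_pos, child_pos, signed: bool | None = None) -> float:
    """Angle in degrees between (parent − centre) and (child − parent).

    Signed in 2D (positive = counter-clockwise), unsigned [0, 180] in 3D.
    Raises for zero-length vectors.
    """
    centre = np.asarray(centre, dtype=float)
    parent_pos = np.asarray(parent_pos, dtype=float)
    child_pos = np.asarray(child_pos, dtype=float)
    u = parent_pos - centre
    v = child_pos - parent_pos
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("direction angle undefined for zero-length vector")
    if signed is None:
        signed = len(centre) == 2
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    ang = math.degrees(math.acos(cosang))
    if signed:
        cross = u[0] * v[1] - u[1] * v[0]
        if cross < 0:
            ang = -ang
    return ang


def true_parent_map(tree: GenotypeTree) -> dict[int, int]:
    """mutation -> parent mutation (−1 for root) from the simulated genotype
    tree; within a multi-mutation gain the block forms a chain."""
    parent: dict[int, int] = {}
    last_mut = np.full(len(tree), -1, dtype=np.int64)
    for g in range(len(tree)):
        if g == 0:
            continue
        pg = tree.parent[g]
        anc = last_mut[pg]
        first, n = tree.first_mut[g], tree.n_muts[g]
        prev = anc
        for m in range(first, first + n):
            parent[m] = int(prev)
            prev = m
        last_mut[g] = prev if n else anc
    return parent


def reconstruct_parent_map(table: SampleTable, eps: float = 0.05) -> dict[int, int]:
    """Containment-based parent map from observed frequencies.

    Parent of m is the mutation with the smallest carrier set that contains
    m's carrier set (frequency tolerance ``eps``, i.e. f_parent ≥ f_m − eps
    everywhere) and strictly larger total frequency; ties broken by larger
    total frequency; −1 (root) if no candidate exists.  The same procedure is
    applied to simulated tables wherever simulations are compared with data,
    so convention effects largely cancel.
    """
    mut_ids, F, P = table.matrices()
    tot = F.sum(axis=1)
    ncar = P.sum(axis=1)
    parent: dict[int, int] = {}
    for i, m in enumerate(mut_ids):
        contains = np.all(F >= F[i] - eps, axis=1)
        contains &= tot > tot[i] + 1e-12
        cand = np.flatnonzero(contains)
        cand = cand[cand != i]
        if cand.size == 0:
            parent[int(m)] = -1
            continue
        order = np.lexsort((mut_ids[cand], -tot[cand], ncar[cand]))
        parent[int(m)] = int(mut_ids[cand[order[0]]])
    return parent


def _pair_angle_matrix(pts: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """theta[a, b] = direction angle with parent sample a and child sample b;
    NaN where a vector degenerates."""
    u = pts - centre  # (S, dim)
    v = pts[None, :, :] - pts[:, None, :]  # (S, S, dim), v[a, b] = b - a
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ad,abd->ab", u, v) / (nu[:, None] * nv)
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if pts.shape[1] == 2:
            cross = u[:, 0][:, None] * v[:, :, 1] - u[:, 1][:, None] * v[:, :, 0]
            theta = np.where(cross < 0, -theta, theta)
    theta[(nv < 1e-12) | (nu[:, None] < 1e-12)] = np.nan
    return theta


def angle_distribution(table: SampleTable, parent_map: dict[int, int],
                       mode: str = "centroid",
                       background: str = "full") -> pd.DataFrame:
    """Direction angles of each mutant clone relative to its parent clone.

    Returns a frame (mutation_id, theta, weight); the weights of every clone
    sum to one.  In ``centroid`` mode (default) each clone contributes a
    single angle between the parent's carrier centroid and the child's
    carrier centroid; in ``pairwise`` mode every (parent sample, child
    sample) pair contributes with weight parent × child frequency.

    ``background`` picks the parent weighting: ``full`` uses the parent
    mutation's own frequencies (carriers of the child included — they carry
    the parent mutation too); ``subtract`` uses max(f_parent − f_child, 0).
    Subtraction makes the parent position anti-correlated with the child
    whenever the parent clone is spread over much of the tumour, which
    biases θ towards ±180° even under isotropic growth, so ``full`` is the
    default.
    """
    if mode not in ("pairwise", "centroid"):
        raise ValueError(f"unknown mode {mode!r}")
    if background not in ("full", "subtract"):
        raise ValueError(f"unknown background {background!r}")
    mut_ids, F, P = table.matrices()
    mpos = {int(m): i for i, m in enumerate(mut_ids)}
    pts = table.positions()
    centre = tumour_centre(table)
    pair_theta = _pair_angle_matrix(pts, centre) if mode == "pairwise" else None
    out_m, out_t, out_w = [], [], []
    for m, pm in parent_map.items():
        if pm < 0 or m not in mpos or pm not in mpos:
            continue
        fc = F[mpos[m]]
        fp = F[mpos[pm]]
        bg = np.maximum(fp - fc, 0.0) if background == "subtract" else fp
        if bg.sum() <= 0 or fc.sum() <= 0:
            continue
        if mode == "centroid":
            ppos = (pts * bg[:, None]).sum(axis=0) / bg.sum()
            cpos = (pts * fc[:, None]).sum(axis=0) / fc.sum()
            try:
                theta = direction_angle(centre, ppos, cpos)
            except ValueError:
                continue
            out_m.append(np.array([m]))
            out_t.append(np.array([theta]))
            out_w.append(np.array([1.0]))
        else:
            W = np.outer(bg, fc)
            W[np.isnan(pair_theta)] = 0.0
            wsum = W.sum()
            if wsum <= 0:
                continue
            a, b = np.nonzero(W)
            out_m.append(np.full(a.size, m))
            out_t.append(pair_theta[a, b])
            out_w.append(W[a, b] / wsum)
    if not out_m:
        return pd.DataFrame(columns=["mutation_id", "theta", "weight"])
    return pd.DataFrame({
        "mutation_id": np.concatenate(out_m),
        "theta": np.concatenate(out_t),
        "weight": np.concatenate(out_w),
    })


def angle_uniformity_test(theta, weight=None, dim: int = 2, groups=None):
    """Weighted KS test of the direction angles against the isotropic null.

    2D: flat on [−180, 180].  3D: angles are unsigned and the isotropic null
    is sin-weighted, CDF (1 − cos θ)/2.  Returns (D, n_eff, p) with the
    asymptotic Kolmogorov p-value at √n_eff · D.  When ``groups`` (one label
    per angle, e.g. the clone id) is given, contributions within a group are
    treated as one dependent observation and n_eff = (Σ_g W_g)²/Σ_g W_g²
    over group weight totals; otherwise n_eff = (Σw)²/Σw².
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("no angles")
    w = np.ones_like(theta) if weight is None else np.asarray(weight, dtype=float)
    if groups is not None:
        gw = pd.Series(w).groupby(pd.Series(np.asarray(groups))).sum().to_numpy()
        n_eff = float(gw.sum() ** 2 / (gw**2).sum())
    else:
        n_eff = float(w.sum() ** 2 / (w**2).sum())
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    cw = np.cumsum(w) / w.sum()
    if dim == 2:
        f0 = (theta + 180.0) / 360.0
    else:
        f0 = (1.0 - np.cos(np.radians(theta))) / 2.0
    prev = np.concatenate([[0.0], cw[:-1]])
    D = float(np.max(np.maximum(np.abs(cw - f0), np.abs(prev - f0))))
    p = float(special.kolmogorov(math.sqrt(n_eff) * D))
    return D, n_eff, p


def radial_mutation_burden(table: SampleTable, n_bins: int = 8,
                           min_cell_fraction: float = 0.5):
    """Per-cell mutation burden of each sample versus distance from the
    tumour centre.

    The burden of a sample is the sum of its detected mutation frequencies
    (the mean number of detected mutations carried per cell), which is
    insensitive to the sample's cell count; samples with fewer than
    ``min_cell_fraction`` × median cells (partially filled edge discs) are
    excluded.  Returns (per-sample frame, binned means frame, spearman
    result): the correlation is ≈ 0 under volume growth and positive under
    surface growth, where lineages at the rim have divided more often.
    """
    centre = tumour_centre(table)
    pts = table.positions()
    dist = np.linalg.norm(pts - centre, axis=1)
    det = table.detected()
    burden = (det.groupby("sample_id")["frequency"].sum()
              .reindex(table.samples["sample_id"], fill_value=0.0).to_numpy())
    counts = (det.groupby("sample_id").size()
              .reindex(table.samples["sample_id"], fill_value=0).to_numpy())
    cells = table.samples["cell_count"].to_numpy()
    ok = cells >= min_cell_fraction * np.median(cells[cells > 0])
    per_sample = pd.DataFrame({
        "sample_id": table.samples["sample_id"],
        "distance": dist,
        "n_mutations": burden,
        "n_detected": counts,
        "cell_count": cells,
    })[ok]
    edges = np.linspace(0, per_sample["distance"].max() + 1e-9, n_bins + 1)
    which = np.digitize(per_sample["distance"], edges) - 1
    binned = per_sample.groupby(which).agg(
        distance=("distance", "mean"), n_mutations=("n_mutations", "mean"))
    rho = stats.spearmanr(per_sample["distance"], per_sample["n_mutations"])
    return per_sample, binned, rho


# mean pairwise distance of uniform points: 128R/(45π) in a disc, 36R/35 in a ball
_DISC_CONST = 128.0 / (45.0 * math.pi)
_BALL_CONST = 36.0 / 35.0


def expected_packed_distance(n_cells: float, cell_cross_section: float,
                             dim: int) -> float:
    """Mean pairwise distance of cells packed into the tightest disc/ball.

    The disc (2D) or ball (3D) has measure n_cells × cell_cross_section; the
    result is the mean distance between two uniform points in it.
    """
    if n_cells <= 1:
        return 0.0
    measure = n_cells * cell_cross_section
    if dim == 2:
        R = math.sqrt(measure / math.pi)
        return _DISC_CONST * R
    if dim == 3:
        R = (3.0 * measure / (4.0 * math.pi)) ** (1.0 / 3.0)
        return _BALL_CONST * R
    raise ValueError(f"dimension must be 2 or 3, got {dim}")


@dataclass
class DispersionConfig:
    """Scale parameters for σ.

    ``cell_cross_section`` is the area (2D) / volume (3D) one cell occupies
    at close packing: √3/2·D² and D³/√2 for cell diameter D (default 1).
    ``coverage_fraction`` is the fraction of the section's cells contained in
    samples; the clone's total cell number is the carrier-weighted sample sum
    rescaled by it.
    """

    cell_diameter: float = 1.0
    coverage_fraction: float = 1.0
    dim: int | None = None  # default: table dimension

    def cross_section(self, dim: int) -> float:
        if dim == 2:
            return math.sqrt(3) / 2.0 * self.cell_diameter**2
        return self.cell_diameter**3 / math.sqrt(2)


def dispersion_sigma(mutation: int, table: SampleTable,
                     config: DispersionConfig | None = None) -> dict:
    """Dispersion σ of one mutation.

    Numerator: carrier-weighted mean pairwise distance between carrying
    samples (weight = frequency × cell count).  Denominator: expected packed
    distance for the clone's estimated total cell number.  Requires at least
    two carrying samples.
    """
    config = config or DispersionConfig()
    dim = config.dim or table.dim
    det = table.detected()
    rows = det[det["mutation_id"] == mutation]
    if len(rows) < 2:
        raise ValueError("sigma is undefined with fewer than 2 carrying samples")
    spos = table.sample_index()
    idx = spos[rows["sample_id"]].to_numpy()
    pts = table.positions()[idx]
    cells = table.samples["cell_count"].to_numpy()[idx]
    w = rows["frequency"].to_numpy() * cells
    dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    wmat = np.outer(w, w)
    np.fill_diagonal(wmat, 0.0)
    numer = float((wmat * dmat).sum() / wmat.sum())
    n_clone = float(w.sum() / config.coverage_fraction)
    denom = expected_packed_distance(n_clone, config.cross_section(dim), dim)
    sigma = numer / denom if denom > 0 else np.nan
    return {
        "mutation_id": int(mutation),
        "sigma": sigma,
        "n_samples_carrying": int(len(rows)),
        "estimated_clone_cells": n_clone,
    }


def dispersion_table(table: SampleTable,
                     config: DispersionConfig | None = None) -> pd.DataFrame:
    """σ for every mutation with at least two carrying samples."""
    det = table.detected()
    out = []
    for m, grp in det.groupby("mutation_id"):
        if len(grp) < 2:
            continue
        out.append(dispersion_sigma(int(m), table, config))
    return pd.DataFrame(out, columns=["mutation_id", "sigma",
                                      "n_samples_carrying",
                                      "estimated_clone_cells"])


def ks_statistic(a, b) -> float:
    """Scaled two-sample KS statistic √(n₁n₂/(n₁+n₂))·D."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    D = stats.ks_2samp(a, b).statistic
    return float(math.sqrt(len(a) * len(b) / (len(a) + len(b))) * D)
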