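"""Readers, writers, configuration and fixture generation.

Tables travel as TSV with strict schemas; configurations as YAML/JSON.
Every CLI run writes a JSON manifest (parameters, seed, package versions)
so identical manifests imply identical outputs for deterministic commands.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sampling import SamplePlan, SampleTable, honeycomb_positions
from .simulate import Population, SimParams

__all__ = [
    "read_sample_table",
    "write_sample_table",
    "write_population",
    "read_population",
    "read_sim_params",
    "read_sample_plan",
    "reference_grid_positions",
    "write_manifest",
    "make_fixture",
]

_REQUIRED = ["sample_id", "x", "y", "cell_count", "mutation_id", "frequency"]


def read_sample_table(path) -> SampleTable:
    """Read a flat samples.tsv; every required column must be present."""
    flat = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED if c not in flat.columns]
    if missing:
        raise ValueError(f"sample table is missing columns: {missing}")
    return SampleTable.from_frame(flat)


def write_sample_table(table: SampleTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_population(pop: Population, outdir) -> None:
    """cells.tsv + tree.tsv + run.json (+ clone tree newick)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop.cells_frame().to_csv(outdir / "cells.tsv", sep="\t", index=False)
    pop.tree.to_frame().to_csv(outdir / "tree.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(pop.tree.to_newick() + "\n")
    run = {
        "params": dataclasses.asdict(pop.params),
        "time": pop.time,
        "births": pop.births,
        "deaths": pop.deaths,
        "size": pop.size,
        "extinct": pop.extinct,
        "timed_out": pop.timed_out,
    }
    run["params"] = {k: (None if isinstance(v, float) and np.isinf(v) else v)
                     for k, v in run["params"].items()}
    (outdir / "run.json").write_text(json.dumps(run, indent=2) + "\n")


def read_population(indir) -> Population:
    """Rebuild a Population from a directory written by write_population."""
    from .simulate import GenotypeTree

    indir = Path(indir)
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    tree_df = pd.read_csv(indir / "tree.tsv", sep="\t",
                          keep_default_na=False)
    run = json.loads((indir / "run.json").read_text())
    params = dict(run["params"])
    if params.get("rho_c") is None:
        params["rho_c"] = np.inf
    p = SimParams(**params)
    tree = GenotypeTree()
    tree.parent = tree_df["parent_id"].astype(int).tolist()
    gained = [str(g) for g in tree_df["mutations_gained"]]
    firsts, counts = [], []
    for g in gained:
        ids = [int(x) for x in g.split(",")] if g not in ("", "nan") else []
        firsts.append(ids[0] if ids else 0)
        counts.append(len(ids))
    tree.first_mut = firsts
    tree.n_muts = counts
    tree.birth_time = tree_df["birth_time"].astype(float).tolist()
    tree.birth_popsize = tree_df["birth_popsize"].astype(int).tolist()
    tree.live_count = tree_df["live_count"].astype(int).tolist()
    tree.n_mutations_total = int(sum(counts))
    dims = [c for c in ("x", "y", "z") if c in cells.columns]
    return Population(
        cell_ids=cells["id"].to_numpy(),
        positions=cells[dims].to_numpy(dtype=float),
        genotypes=cells["genotype_id"].to_numpy(),
        tree=tree,
        time=run["time"],
        births=run["births"],
        deaths=run["deaths"],
        extinct=run["extinct"],
        params=p,
    )


def _load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_sim_params(path) -> SimParams:
    """SimParams from a YAML/JSON config; rho_c accepts 'inf' and
    'close-packed'."""
    cfg = dict(_load_config(path))
    rho_c = cfg.pop("rho_c", "inf")
    surface = False
    if isinstance(rho_c, str):
        if rho_c in ("inf", "infinite"):
            rho_c = np.inf
        elif rho_c in ("close-packed", "surface"):
            surface = True
            rho_c = np.inf
        else:
            rho_c = float(rho_c)
    p = SimParams(rho_c=rho_c, **cfg)
    return p.surface_growth() if surface else p


def read_sample_plan(path) -> SamplePlan:
    cfg = dict(_load_config(path))
    pos = cfg.pop("positions_file", None)
    if pos is not None:
        pts = pd.read_csv(pos, sep="\t")
        cfg["positions"] = pts[["x", "y"]].to_numpy()
        cfg["layout"] = "positions"
    return SamplePlan(**cfg)


def reference_grid_positions() -> np.ndarray:
    """The packaged 285-position honeycomb sampling grid (synthetic
    reconstruction of a planar multi-region design; spacing 2 length
    units)."""
    with resources.files("tumevo").joinpath(
            "data/honeycomb285_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")[["x", "y"]].to_numpy()


def write_manifest(path, command: str, params: dict, seed: int | None) -> None:
    import scipy

    from . import __version__

    manifest = {
        "command": command,
        "params": params,
        "seed": seed,
        "versions": {
            "tumevo": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def toy_capture_table() -> SampleTable:
    """Three samples, three mutations: m1 private to s1, m2 shared by all
    with its frequency peak in s2, m3 private to s2."""
    samples = pd.DataFrame({
        "sample_id": [0, 1, 2],
        "x": [0.0, 1.0, 2.0],
        "y": [0.0, 0.0, 0.0],
        "z": [np.nan] * 3,
        "cell_count": [100, 100, 100],
    })
    calls = pd.DataFrame({
        "sample_id": [0, 0, 1, 1, 2],
        "mutation_id": [1, 2, 2, 3, 2],
        "frequency": [0.4, 0.1, 0.5, 0.3, 0.2],
        "present": [True] * 5,
        "alt_reads": [np.nan] * 5,
        "total_reads": [np.nan] * 5,
    })
    return SampleTable(samples, calls, dim=2)


def make_fixture(name: str, seed: int = 0, outdir=".") -> Path:
    """Write a named fixture; reproducible given the seed.

    Names: 'grid-285' (the packaged honeycomb positions), 'toy-capture'
    (3 samples × 3 mutations), 'mini-volume' / 'mini-surface' (seeded small
    simulations, n_max=2000, sampled on a 120-position honeycomb).
    """
    from .sampling import sample_population
    from .simulate import simulate_surviving

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "grid-285":
        pts = honeycomb_positions(285, spacing=2.0)
        out = outdir / "grid285.tsv"
        pd.DataFrame({"sample_id": np.arange(285),
                      "x": np.round(pts[:, 0], 6),
                      "y": np.round(pts[:, 1], 6)}).to_csv(out, sep="\t", index=False)
        return out
    if name == "toy-capture":
        out = outdir / "toy_capture.tsv"
        write_sample_table(toy_capture_table(), out)
        return out
    if name in ("mini-volume", "mini-surface"):
        p = SimParams(dimension=2, b0=1.0, d=0.8 if name == "mini-volume" else 0.4,
                      mu=0.3, n_max=2000, seed=seed)
        if name == "mini-surface":
            p = p.surface_growth()
        pop = simulate_surviving(p)
        plan = SamplePlan(layout="honeycomb", n_samples=120,
                          detection_freq_min=0.05, seed=seed)
        table = sample_population(pop, plan)
        out = outdir / f"{name.replace('-', '_')}_samples.tsv"
        write_sample_table(table, out)
        return out
    raise ValueError(f"unknown fixture {name!r}")
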