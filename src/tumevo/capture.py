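"""Fraction of a tumour's mutations captured by k samples.

Cell migration (pushing) spreads mutations far beyond their clone of
origin, so a handful of samples detects a disproportionate share of all
mutations.  The migration filter removes, for a given subset of samples,
every mutation that reaches a higher frequency in some sample outside the
subset — those mutations plausibly arose elsewhere and migrated in.  After
filtering, k samples capture roughly k/n of the mutations; before it, far
more.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampling import SampleTable

__all__ = [
    "support_filter",
    "capture_fraction",
    "migration_filtered_fraction",
    "capture_curve",
]


def support_filter(table: SampleTable, min_alt: int = 5,
                   min_total: int = 150) -> SampleTable:
    """Keep calls supported by at least ``min_alt`` reads at a coverage of at
    least ``min_total`` reads."""
    calls = table.calls
    if calls["alt_reads"].isna().any() or calls["total_reads"].isna().any():
        raise ValueError("support_filter requires read counts on every call")
    keep = (calls["alt_reads"] >= min_alt) & (calls["total_reads"] >= min_total)
    return SampleTable(table.samples, calls[keep], dim=table.dim)


def capture_fraction(subset, table: SampleTable) -> float:
    """|mutations detected in the subset| / |mutations detected anywhere|."""
    det = table.detected()
    all_muts = det["mutation_id"].unique()
    if all_muts.size == 0:
        raise ValueError("no detected mutations")
    sub = det[det["sample_id"].isin(set(subset))]
    return sub["mutation_id"].nunique() / all_muts.size


def migration_filtered_fraction(subset, table: SampleTable) -> float:
    """Capture fraction counting only mutations whose maximum frequency
    inside the subset is at least their maximum frequency outside (ties kept:
    'migrated in' requires a strictly higher frequency elsewhere)."""
    det = table.detected()
    all_muts = det["mutation_id"].unique()
    if all_muts.size == 0:
        raise ValueError("no detected mutations")
    subset = set(subset)
    inside = det["sample_id"].isin(subset)
    max_in = det[inside].groupby("mutation_id")["frequency"].max()
    max_out = det[~inside].groupby("mutation_id")["frequency"].max()
    max_out = max_out.reindex(max_in.index, fill_value=-np.inf)
    return int((max_in >= max_out).sum()) / all_muts.size


def capture_curve(table: SampleTable, k_range=None, reps: int = 1000,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Mean capture fraction and 95-percentile band versus subset size k.

    For each k, ``reps`` random subsets of the non-empty samples are drawn;
    both the unfiltered and the migration-filtered fractions are recorded.
    Returns a frame with columns k, mean, lo, hi (2.5th/97.5th percentiles)
    for both statistics.
    """
    rng = rng or np.random.default_rng()
    ids = table.samples.loc[table.samples["cell_count"] > 0, "sample_id"].to_numpy()
    n = len(ids)
    if k_range is None:
        k_range = range(1, n + 1)
    rows = []
    for k in k_range:
        if not 1 <= k <= n:
            raise ValueError(f"subset size {k} out of range 1..{n}")
        caps, fils = [], []
        n_draws = reps if k < n else 1
        for _ in range(n_draws):
            subset = rng.choice(ids, size=k, replace=False)
            caps.append(capture_fraction(subset, table))
            fils.append(migration_filtered_fraction(subset, table))
        rows.append({
            "k": k,
            "capture_mean": np.mean(caps),
            "capture_lo": np.percentile(caps, 2.5),
            "capture_hi": np.percentile(caps, 97.5),
            "filtered_mean": np.mean(fils),
            "filtered_lo": np.percentile(fils, 2.5),
            "filtered_hi": np.percentile(fils, 97.5),
        })
    return pd.DataFrame(rows)
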