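"""SBS96 mutational-signature profiles and non-negative refitting.

Single-base substitutions are counted in the standard 96 trinucleotide
channels (pyrimidine-reference convention: purine-reference mutations map to
the reverse-complement channel).  A profile is decomposed over a signature
catalog by non-negative least squares, and a resampling test estimates the
probability that a signature present in a reference mixture would be missed
entirely in a finite sample of mutations — used to decide whether the
absence of a signature among late (subclonal) mutations is real or sampling
noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .sampling import SampleTable

__all__ = [
    "SBS96_CHANNELS",
    "channel_of",
    "build_profile",
    "split_clonality",
    "read_catalog",
    "synthetic_catalog",
    "refit_weights",
    "summarize_weights",
    "absence_pvalue",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

SBS96_CHANNELS = [
    f"{up}[{sub}]{down}"
    for sub in _SUBS
    for up in "ACGT"
    for down in "ACGT"
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str:
    """SBS96 channel of a substitution given its trinucleotide context.

    ``context`` is the reference trinucleotide with the mutated base in the
    middle; purine references are reverse-complemented (e.g. G>A in TGT is
    the A[C>T]A channel).
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref == alt or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        context = _revcomp(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_profile(mutations: pd.DataFrame) -> pd.Series:
    """SBS96 counts from a frame with columns ref, alt, context.

    The profile sums to the number of input mutations.
    """
    counts = np.zeros(96, dtype=float)
    for ref, alt, ctx in mutations[["ref", "alt", "context"]].itertuples(index=False):
        counts[_CHANNEL_INDEX[channel_of(ref, alt, ctx)]] += 1
    return pd.Series(counts, index=SBS96_CHANNELS, name="count")


def split_clonality(table: SampleTable, tau: float = 0.05):
    """Split detected mutations into clonal (early) and subclonal (late).

    Clonal mutations are detected in at least (1 − τ) of the non-empty
    samples; the rest are subclonal.  Returns (clonal_ids, subclonal_ids).
    """
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    det = table.detected()
    n_nonempty = int((table.samples["cell_count"] > 0).sum())
    per_mut = det.groupby("mutation_id")["sample_id"].nunique()
    clonal = per_mut.index[per_mut >= (1.0 - tau) * n_nonempty]
    subclonal = per_mut.index.difference(clonal)
    return np.asarray(clonal), np.asarray(subclonal)


def read_catalog(path) -> pd.DataFrame:
    """COSMIC-style SBS96 catalog TSV: first column channel labels, one
    column per signature; columns must sum to 1 (renormalised exactly)."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(SBS96_CHANNELS) - set(cat.index)
    if missing:
        raise ValueError(f"catalog is missing {len(missing)} channels, "
                         f"e.g. {sorted(missing)[:3]}")
    cat = cat.loc[SBS96_CHANNELS]
    sums = cat.sum(axis=0)
    if (np.abs(sums - 1.0) > 1e-3).any():
        bad = sums[np.abs(sums - 1.0) > 1e-3].index.tolist()
        raise ValueError(f"catalog columns do not sum to 1: {bad}")
    return cat / sums


def synthetic_catalog(n_signatures: int = 6, seed: int = 0,
                      concentration: float = 0.08) -> pd.DataFrame:
    """A synthetic signature catalog for tests and examples.

    Columns are Dirichlet draws sharpened so each signature concentrates on
    a few channels, loosely mimicking the peaked shape of real SBS
    signatures.  Labelled SYN1..SYNn: these are not COSMIC signatures.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for i in range(n_signatures):
        w = rng.dirichlet(np.full(96, concentration))
        cols[f"SYN{i + 1}"] = w
    return pd.DataFrame(cols, index=SBS96_CHANNELS)


def refit_weights(profile, catalog: pd.DataFrame, subset=None) -> pd.Series:
    """Non-negative least-squares decomposition of a profile over a catalog.

    The profile is normalised to sum 1 and fitted against the catalog's
    columns (optionally restricted to ``subset``); weights are renormalised
    to sum 1.  Raises on an all-zero profile.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape[0] != 96:
        raise ValueError("profile must have 96 channels")
    if p.sum() <= 0:
        raise ValueError("cannot refit an all-zero profile")
    cat = catalog[list(subset)] if subset is not None else catalog
    w, _ = nnls(cat.to_numpy(), p / p.sum())
    total = w.sum()
    if total <= 0:
        # pathological fit: fall back to uniform over the catalog
        w = np.full(len(cat.columns), 1.0 / len(cat.columns))
        total = 1.0
    return pd.Series(w / total, index=cat.columns, name="weight")


def summarize_weights(weights: pd.Series, min_weight: float = 0.01) -> pd.Series:
    """Collapse signatures below ``min_weight`` into an 'Others' entry."""
    major = weights[weights > min_weight]
    others = 1.0 - major.sum()
    out = major.sort_values(ascending=False)
    if others > 1e-12:
        out = pd.concat([out, pd.Series({"Others": others})])
    return out


def absence_pvalue(reference_weights: pd.Series, n: int,
                   catalog: pd.DataFrame, target_sig: str,
                   reps: int = 999, rng: np.random.Generator | None = None,
                   threshold: float = 0.0) -> float:
    """Probability that ``target_sig`` would receive weight ≤ threshold in a
    refit of n mutations drawn from the reference mixture.

    Profiles of size n are resampled from the mixture implied by
    ``reference_weights``, refitted by NNLS, and the fraction with target
    weight ≤ threshold is returned with an add-one correction, so the
    smallest reportable value is 1/(reps + 1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if target_sig not in catalog.columns:
        raise ValueError(f"unknown signature {target_sig!r}")
    rng = rng or np.random.default_rng()
    w = reference_weights.reindex(catalog.columns, fill_value=0.0).to_numpy()
    if w.sum() <= 0:
        raise ValueError("reference weights are all zero")
    w = w / w.sum()
    ti_ref = list(catalog.columns).index(target_sig)
    if w[ti_ref] <= threshold:
        # the null mixture itself lacks the target: its absence is certain
        return 1.0
    mix = catalog.to_numpy() @ w
    mix = mix / mix.sum()
    hits = 0
    A = catalog.to_numpy()
    ti = list(catalog.columns).index(target_sig)
    for _ in range(reps):
        prof = rng.multinomial(n, mix).astype(float)
        fit, _ = nnls(A, prof / prof.sum())
        s = fit.sum()
        if s <= 0 or fit[ti] / s <= threshold:
            hits += 1
    return (hits + 1) / (reps + 1)
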