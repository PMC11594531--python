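# Methods

This note documents the model, the estimators, the numerical choices and
the known limitations of `tumevo`, in the spirit of the methods sections of
simulation-backed inference packages.

## Growth model

Cells are hard spheres of radius `cell_radius` (default 0.5, so the cell
diameter is the length unit). The state is the set of live cell centres
plus a genotype tree. Three event types drive the dynamics:

* **Division** at per-cell rate b(ρ) = b₀·max(0, 1 − ρ/ρ_c), where ρ is the
  local density around the mother. The daughter appears at contact distance
  2r in a uniformly random direction; mother and daughter each draw a
  Poisson(μ) number of brand-new mutations (infinite sites — every mutation
  id is globally unique, no back-mutation). A non-zero draw creates a new
  genotype-tree node; the node records its creation time and the population
  size at creation (used for the population-size-at-origin analysis).
* **Death** at constant per-cell rate d, removing the cell.
* **Pushing.** After a division the daughter may overlap neighbours.
  Overlaps are resolved width-first: the new cell pushes each overlapped
  neighbour along their connecting axis to distance 2r + margin
  (margin default 0.05·r, a buffer against many tiny recurring overlaps),
  the pushed cells are enqueued FIFO, and their neighbourhoods are resolved
  in turn until the queue is empty; neighbourhood order is shuffled so no
  direction is systematically preferred. A cascade budget (10⁵ pushes)
  guards against non-termination and has never been reached in practice.

Events are scheduled by an exact Gillespie algorithm: total rate
Σᵢ b(ρᵢ) + N·d, exponential waiting times, event chosen proportionally.
Per-cell birth rates are cached and recomputed only for cells whose density
window contains a changed position (a birth, a death, or any pushed cell);
the cached total is re-summed every 1024 events to cancel floating-point
drift. Simulations stop at `n_max` cells, at extinction (flagged, so
callers can retry with a derived seed — analyses are conditioned on
surviving tumours, mirroring how death rates were chosen to keep extinction
probabilities comparable between growth modes), or at an optional time or
event budget.

**Density estimator.** ρ at a cell is the number of *other* cell centres
within `density_radius` (default 3r) divided by the window's area/volume.
The estimator is windowed, so its value on a close-packed lattice is not
the analytic close-packing density: the surface-growth preset therefore
sets ρ_c to the windowed estimate evaluated on a contact-distance
hexagonal (2D) or FCC (3D) lattice (0.849 cells per unit area in 2D with
the defaults). Defining ρ_c analytically would leave b(ρ) positive
everywhere and silently disable surface growth.

**Neighbour search** uses a dense uniform grid with bucket edge 2r, giving
exact (not approximate) fixed-radius queries; the hot paths (grid
maintenance, push cascades, density updates, brute-force geometry
validation) are numba-compiled. 2D populations of 5,000 cells simulate in
a few seconds on one CPU.

**Units.** Rates are per unit time (b₀ = 1 defines the time unit); lengths
are in cell diameters; μ is per daughter genome per division.

## Sampling

`SamplePlan` mimics multi-region designs: evenly spaced sample discs on a
honeycomb (triangular) or square lattice clipped to the occupied region —
the lattice spacing is found by bisection so the requested number of
samples fits, and the n closest to the centroid are kept, deterministically
— or verbatim positions from a file, to reuse a real tumour's geometry.
3D populations can first be cut to a 2D cross-section slab. Within a disc,
a mutation's frequency is carriers/cells. Detection applies a within-sample
frequency threshold (default 0.05) and optionally a whole-tumour frequency
floor (1/40 in the resolution-limited analyses, emulating genotyping
panels built from a subset of sequenced samples). Read counts, when
requested, are Poisson(depth) totals with Binomial alt counts at the cell
fraction (or half of it under the diploid VAF convention). Empty discs are
kept with zero cells so gappy real grids are representable.

The packaged `data/honeycomb285_synthetic.tsv` is a synthetic 285-position
honeycomb grid (spacing 2) standing in for a planar multi-region design; it
is reproduced bit-exactly by `honeycomb_positions(285, spacing=2.0)`.

## Growth-mode diagnostics

**Direction angles.** For a child mutation and its parent, θ is the angle
between (centre → parent position) and (parent position → child position);
signed in 2D, unsigned in 3D. Parent–child relations on data come from
frequency containment: the parent of m is the mutation with the smallest
carrier set containing m's carriers (tolerance ε = 0.05 in frequency),
ties broken by total frequency. The same reconstruction is applied to
simulated tables in every comparison, so convention bias largely cancels.

Clone positions are carrier-frequency-weighted centroids. The default
estimator is *centroid mode with the parent's full frequencies*: using the
background f_parent − f_child instead makes the parent position
anti-correlated with the child whenever the parent clone is spread over
much of the tumour, which biases θ toward ±180° even under isotropic
growth; both alternatives (`background="subtract"`, `mode="pairwise"`)
remain available. Uniformity is tested with a weighted KS statistic against
the flat null in 2D and the sin-weighted isotropic null in 3D (uniform
direction in 3D is not flat in θ). Contributions of one clone are
correlated, so the effective sample size is computed over clone-level
weight totals (each clone's weights sum to 1), and the asymptotic
Kolmogorov distribution supplies the p-value.

**Radial burden.** The per-sample burden is the sum of detected mutation
frequencies — the mean number of detected mutations per cell — which is
insensitive to how full the sample disc is; samples with fewer than half
the median cell count (clipped edge discs) are excluded. The burden-vs-
radius Spearman correlation is ≈ 0 under volume growth and strongly
positive under surface growth, where rim lineages have divided more.

**Dispersion σ.** For a mutation carried by ≥ 2 samples, the numerator is
the carrier-weighted (frequency × cell count) mean pairwise distance
between carrying samples; the denominator is the mean pairwise distance of
the clone's estimated cell count arranged in the tightest disc/ball
(closed forms 128R/45π and 36R/35; cross-checked against Monte-Carlo
integration in the tests). The clone's cell count is the carrier-weighted
sample sum rescaled by the sampled fraction of the section's cells; the
per-cell cross-section at close packing is √3/2·D² (2D) or D³/√2 (3D).
σ is scale-invariant under joint rescaling of coordinates and cell size.
A deliberately compact clone painted onto a close-packed simulated tumour
measures σ ≈ 1.13 — the ~10 % excess over 1 reflects the looser-than-
hexagonal random packing and the quantisation of distances to the sample
grid, which is why the compact reference band is stated as 1 ± 0.2.

## Turnover inference

Two genealogical metrics are defined on the true genotype tree: clone
turnover (fraction of extant non-root genotypes whose parental genotype has
no living cells) and clade turnover (fraction of extant clades identical
to their ancestral clade). Both increase with d/b; the clone turnover is
far more sensitive to μ. Because the model lets the *mother* mutate at
division, a parental genotype can disappear without any death, so clone
turnover at d = 0 is small but non-zero (≈ 12 % at μ = 0.3, the extinction
probability of a branching process with conversion); clade turnover at
d = 0 is exactly 0, since erasing a clade difference requires actual death.

On sampled data the pipeline is: re-threshold the table at within-sample
frequency ≥ 0.5, so a sample's genotype is its *consensus* mutation set
(the union over all cells in a disc would make every parental-set match
impossible and pin clone turnover at 1); collapse mutations with identical
frequency vectors into events (mutations gained at one division are carried
by exactly the same cells, so their sampled frequencies agree exactly);
build the event tree by carrier-set containment with frequencies breaking
ties. Then

* clone turnover = fraction of events whose parent's implied mutation set
  is not observed as any sample's exact consensus set;
* clade turnover = fraction of mutations whose event shares its carrier
  sample set with its parent event (same samples, different frequencies —
  the footprint of a converted parental lineage), truncal events counting
  as coinciding with the whole-tumour root clade.

These two observables alone do not identify (d/b, μ) on sampled tables —
the observed clade turnover also rises with μ — so the inversion table
stores four statistics per grid point: both turnovers, the mean per-sample
consensus burden, and the mutations-per-event multiplicity. The table is
built by seeded simulation on a (d/b, μ) grid (defaults: d/b up to 0.9,
μ ∈ [0.1, 1], volume growth, n_max = 3,000, 2D, 280-sample honeycomb — the
sizes keep a full build under a minute while the turnover statistics are
already size-stable), each grid point averaging a few replicates, with the
identical sampling and estimation pipeline as the data. Inversion is
nearest-statistics lookup on a bilinearly interpolated fine mesh, each
statistic standardised by its table range (burden and multiplicity on log
scales); estimates landing on the mesh boundary are flagged as
extrapolation. Confidence intervals are percentile bootstrap (1,000
replicates) over mutations, with the statistics recomputed as draw-weighted
means of per-unit indicators frozen on the original table — recomputing on
a literal multiset would let a duplicated mutation coincide with its own
copy and inflate clade turnover mechanically. Subsample robustness
re-infers on random mutation subsets (fractions 0.5–0.9) with μ and the
absolute-scale statistics rescaled by 1/fraction. In recovery experiments
at (d/b, μ) = (0.4, 0.3) and (0.8, 0.3), the 90 % CIs cover the true values
in ≥ 80 % of replicates; the bootstrap does not capture run-to-run
genealogy noise, so coverage is near, not above, nominal.

`population_size_at_origin` implements N = 1/f for a mutation of final
whole-tumour frequency f; `detected_origin_sizes` returns the true
population sizes at which a simulated table's detected mutations arose,
quantifying the spatial-sampling and stochastic-growth corrections to the
deterministic rule. `per_site_rate` divides μ by an effective site count
and an explicit ploidy factor — the per-nucleotide vs per-diploid-site
convention is deliberately not hard-coded.

## Capture and signatures

Capture analysis counts the mutations detected in a random k-subset of
samples relative to all detected mutations; the migration filter drops,
for a given subset, every mutation whose maximum frequency inside the
subset is strictly below its maximum outside (ties kept — "migrated in"
requires a strictly higher peak elsewhere). Read-support filtering
(alt ≥ 5 at coverage ≥ 150) composes upstream. The 95-percentile band is
taken over subset draws only.

SBS96 profiles use the pyrimidine-reference convention (purine-reference
substitutions map to the reverse-complement channel; channel order is the
six substitution types × 4×4 flanking bases). Refitting is non-negative
least squares on the normalised profile, weights renormalised to 1, with
sub-1 % weights reported under "Others". The clonal/subclonal split calls
a mutation clonal when detected in ≥ (1 − τ) of non-empty samples
(τ = 0.05). The absence p-value resamples multinomial profiles of size n
from a reference mixture, refits, and reports the add-one-corrected
fraction with target weight exactly 0; when the reference itself lacks the
target, absence under the null is certain and the p-value is 1 by
definition. The packaged catalog generator produces labelled synthetic
signatures (Dirichlet draws concentrated on few channels) for tests and
examples; real analyses should supply a COSMIC-format TSV.

## What the synthetic data do and do not emulate

The simulator generates the spatial and genealogical structure the
estimators are designed for: pushing-driven clone dispersal, density-
dependent division, neutral infinite-sites mutation, survival-conditioned
growth. It does not model selection (a neutral model throughout), adhesion
or active motility, sequencing error or contamination, copy-number changes
(frequencies are cell fractions; the diploid VAF convention is a fixed
factor), or the read-depth heterogeneity of real exomes. Passing tests
therefore demonstrate that the estimators recover the truth under the
model's assumptions at the stated sizes — not that those assumptions hold
in any particular tumour. Study sizes in the tests and the acceptance
script (5,000-cell 2D tumours for growth-mode contrasts, 3,000-cell
tumours for the inversion table, 10–20 replicates) are scaled-down
choices that keep full runs in minutes while leaving every qualitative
contrast decisively detectable.

## Degenerate inputs and tie-breaks

Zero-length direction vectors (clone centroid at the tumour centre, or
coincident parent/child positions) skip the contribution with a warning
path rather than fabricating an angle. Coincident cell centres during a
push cascade are separated in a random direction. σ is undefined (and
excluded) below two carrying samples. Containment ties are broken by total
frequency then id, making every reconstruction deterministic. All
randomness flows from explicit integer seeds; identical seeds reproduce
identical populations, tables and inferences bit-for-bit.
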