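# Methods

## Model

`fgmsim` simulates a population of tumour cells adapting in a changing
tumour microenvironment (TME), using an extension of Fisher's geometric
model. A cell is a point `z` in an n-dimensional Euclidean trait space
(n = 2 by default); the TME supplies a phenotypic optimum `z_opt(t)` and
fitness is Gaussian in the displacement:

    w(z, t) = exp( -(z - z_opt(t))^T S^-1 (z - z_opt(t)) )

`S` is an n×n symmetric positive-definite selection matrix. The
isotropic case `S = σ² I` (σ² = 10 by default) corresponds to universal
pleiotropy; anisotropic `S` encodes correlated selection across traits.
The average landscape width is the geometric mean of the eigenvalues of
`S`, `det(S)^(1/n)`. The selection coefficient of any phenotypic change
is `s = w(z')/w(z) − 1` against the same optimum.

The optimum moves only along the first trait, in one of six regimes:
directional (`v₁ t`), random (fresh `N(0, δ²)` each generation, not a
random walk), directional-plus-random, cyclic
(`(A/2)[1 + sin(2πt/P − π/2)]`, period `P = 360` generations by
default), constant, and sudden (a one-off jump at generation τ). A
piecewise-constant `schedule` regime supports sequential / cyclic
therapy dosing. The optimum stream has its own random generator, so a
TME realization is reproducible independently of what the population
does.

## Spatial life cycle

Cells live on a bounded `G³` cubic lattice (one cell per site, 26-site
Moore neighbourhood, absorbing walls) and reproduce in discrete,
non-overlapping generations:

1. the optimum advances to its value at generation t;
2. each cell survives viability selection with probability `w(z, t)`;
3. each survivor divides: daughter 1 keeps the parent's site, daughter 2
   takes a uniformly random empty Moore-neighbour site if one exists and
   the population cap `N_max` allows. A survivor with no empty
   neighbour produces one daughter (surface growth; no pushing).

Survivors compete for cap headroom in uniformly random order. The
implementation processes them in random-priority chunks with iterative
proposal rounds (conflicted sites go to the highest priority; losers
re-propose among the remaining empties), which reproduces the sequential
random-order semantics at vectorized cost. Tie-breaking details beyond
uniformity are not part of the model's claims.

Populations are initialized with `K` cells filling central lattice
shells in deterministic order, either at an explicit phenotype `z0` or
at the phenotype whose fitness equals a requested `w0` (displaced along
trait 1). Time is reported in years assuming a 24 h doubling time by
default.

## Genetics

Each cell carries `L = 5` loci with `c = 2` homologous copies. Every
copy holds an allele; alleles form per-locus multifurcating trees rooted
at a zero-effect ancestral allele. During each replication every copy
mutates independently with probability `u = 4 × 10⁻⁵` (the per-locus
rate per genome replication), drawing a displacement from `MVN(0, M)`
that adds to the phenotype. Chromosome instability (CIN) acts per locus
per daughter with probability `r_c`: one homolog, chosen uniformly,
overwrites the other (copy-neutral LOH; ploidy is preserved).

A driver mutation (adaptive step) is recorded the first generation its
branch of the allele tree is the sole survivor at its locus — every
live copy descends from it. Steps are never retracted, even if the
optimum later moves and the fixed driver becomes deleterious. The
selection coefficient attached to a step is the effect of the allele's
own displacement on the mean population phenotype against the optimum
at the fixation generation, `w(z̄)/w(z̄ − r) − 1`; the model does not
single out any other background as canonical.

Two structural consequences of this genetic model are worth stating
because they shape every experiment:

- **CIN is the fixation mechanism.** In an asexual diploid, a mutation
  on one homolog can never reach the sister copy by descent, so with
  `r_c = 0` the ancestral allele survives at every locus forever and
  strict fixation is impossible. Experiment profiles therefore use
  `r_c = 0.01` per locus per daughter — an LOH timescale of ~100
  generations, well inside run lengths and slow enough not to dominate
  drift. `r_c` defaults to 0 in `SimConfig` (CIN off unless requested).
- **Fixation requires the mutation-limited regime.** At `N_max = 10⁴`
  adaptation proceeds by spatially structured soft sweeps with
  recurrent mutational origins; locus-wide coalescence does not occur
  within 2000 generations and subclones coexist for long periods.
  Driver-fixation and genotypic-landscape experiments therefore use
  `N_max ≈ 300` (G = 30), where sweeps are hard and drivers fix;
  mean-fitness and extinction experiments use `N_max = 10⁴` (G = 50).

## Mutational input

The covariance of mutation effects is `M = σ_m² I` with σ_m = 0.5 trait
units by default. The magnitude is a package choice: it makes single
mutations able to traverse a meaningful fraction of the trait distances
that arise in therapy-scale optimum shifts (selection coefficients of
order 1–30 for rescue mutations), which is the regime the model's
evolutionary-rescue behaviour requires; much smaller effects make
rescue impossible at any mutation rate because populations crash within
a few generations of a large shift. σ_m (or a full `M`) is
configurable.

## Phylodynamics

Every division appends a node to a lineage record. Serially sampled
trees take a subsample of extant cells as tips every sampling interval
(default 100 generations); the record is pruned to the induced subtree,
unifurcations are suppressed with branch lengths (cell divisions)
summed across them. A sampled cell whose lineage is itself ancestral to
later tips is attached as a zero-length leaf at its division node.
Sparse subsampling (tens of tips per sample point, as in practice) is
the intended regime: under dense all-cell sampling essentially every
tip of a slowly evolving population is such a zero-length sampled
ancestor, which hides the long terminal branches that distinguish a
static TME.

Tree imbalance is summarized by the normalized Sackin index — total
topological tip depth in edges divided by tip count, exactly as defined
here, with no Yule-style renormalization — and the number of cherries.
Trees serialize to standard Newick with labels `cellid@generation`.

## Epistasis and genotypic landscapes

For drivers i, j with effects `r_i, r_j` fixed when the optimum sat at
`o_i, o_j`, the epistasis coefficient is
`e_ij = log(w_ij w_0 / (w_i w_j))` with the double mutant at
`z0 + r_i + r_j` facing the additive optimum `o_i + o_j`; expanding the
quadratic form gives the exactly equivalent bilinear form
`e_ij = −2 (r_i − o_i)^T S^-1 (r_j − o_j)`, which the test suite holds
to 1e-10 on random anisotropic instances.

Genotypic landscapes assign each of the `2^k` combinations of k
selected drivers (k = 4 by default; the first four fixed when a run
yields more) the fitness of the summed phenotype against the summed
optimum. Sign epistasis is classified per locus pair per background
with a 1e-12 neutrality tolerance on fitness effects (simple: one
partner's effect flips sign; reciprocal: both). The roughness-to-slope
ratio is the RMS residual of the least-squares additive fit divided by
the mean absolute additive coefficient, computed on raw fitness by
default (a log-fitness switch exists, under which multiplicative
landscapes are exactly additive).

## Therapy

Treatment is a sudden optimum shift of magnitude Δ along trait 1 at
generation τ, optionally with a new landscape shape, following the
sudden-change regime. Cure means extinction; relapse means
post-treatment recovery to a configurable fraction (default 1.0) of the
pre-treatment population size. Resistance mechanisms: polygenic
resistance (more loci, e.g. L = 50 — most informative when present from
the start of the run, so standing variation exists at treatment time;
a mid-run L expansion is also supported), an elevated mutation rate
(e.g. 100×), and relaxed selection (σ² = 40). Post-treatment fixed
drivers are tagged de novo (allele origin ≥ τ) or pre-existing.

The packaged therapy experiments burn in to the cap under a static
optimum and treat at τ = 100. On the σ² = 10 landscape the shift grid
Δ ∈ {2, 4, 6} spans post-shift fitness 0.67 / 0.20 / 0.027 — from
guaranteed relapse (growth factor 2w > 1) through contested outcomes to
near-certain cure — and rescue comparisons run at Δ = 4, where the
control population declines at ≈ 0.4×/generation, leaving a window of a
few dozen generations in which a large-effect mutation can establish.
These operating points follow from the closed-form fitness arithmetic
above, not from fitting.

## Numerical choices

- Fitness that underflows double precision (quadratic form ≳ 709) is 0:
  certain death. Selection-coefficient queries from a zero-fitness
  parent raise instead of returning infinity.
- Symmetry/PSD checks on `S` and `M` use a 1e-12 relative tolerance;
  `M` may be singular (sampling uses an eigendecomposition factor).
- Mutation events per daughter batch are drawn as a binomial total
  scattered over distinct copies — the same joint law as independent
  per-copy Bernoulli trials, at vectorized cost; likewise CIN.
- One master seed spawns three child streams per run (cell events, TME
  trajectory, tip sampling), so recording a genealogy or sampling tips
  never perturbs the dynamics, and a fixed seed reproduces summary
  output byte for byte.
- Sweep and replicate seeds derive from (master seed, grid point,
  replicate index) via SHA-256, all below 2³¹.

## What the experiments do and do not show

All packaged experiments are desk-scale (N_max ≤ 10⁴, G ≤ 50, ≤ 2000
generations, 10–20 replicates) rather than the 10⁷-cell, 300³ regime
the model is designed to reach on a cluster. The qualitative
behaviours — stabilizing-selection neutrality, speed-ordered fitness
decline and extinction, LOH-driven driver fixation, terminal-branch
shortening under fast TME change, therapy monotonicity and
rescue — are robust at this scale, but absolute numbers (fixation
counts, extinction times, cure fractions) shift with population size
and lattice geometry. The simulator also idealizes: a single moving
optimum shared by all cells (no spatial TME heterogeneity), no
cell–cell pushing, no recombination, and copy-neutral CIN only.

## Known limitations

- Populations above ~10⁵ cells with lineage recording are
  memory-hungry; record genealogies only at phylodynamic scales.
- The strict fixation definition makes adaptive steps rare outside the
  mutation-limited regime; analyses that need drivers should use the
  small-cap profile.
- Therapy cure fractions near 0 or 1 saturate quickly in Δ; the
  informative region on the default landscape is roughly Δ ∈ [2.6, 5].
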