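# Methods

`cycadrisk` implements a phylogeny-aware extinction-risk analysis of the kind
applied to the cycads, the most threatened major plant lineage: species-level
EDGE prioritization, scenario-based pruning of the tree of life against
randomization nulls, phylogenetic signal of threat status, diversification
model selection on branching times, and gridded diversity mapping with
hotspot and protected-area gap analysis.  This note records the models, the
conventions behind every numerical choice, and what the synthetic data do and
do not establish.

## Tree conventions

Trees are rooted, with branch lengths in Myr, stored as read and never
rescaled.  Node ages are computed from tip depths with all tips at age 0; a
tree is treated as ultrametric when all root-to-tip depths agree within a
relative tolerance of 1e-6 (required only by the diversification
likelihoods, which consume node ages).

Two conventions propagate through every downstream quantity:

* **Root-path retention.**  The phylogenetic diversity (PD) of a species
  subset is the summed length of the minimal spanning subtree *including the
  path to the original root*, and a pruned tree keeps that path.  This makes
  three conservation laws exact rather than approximate: the fair-proportion
  ED values sum to total PD, per-cell weighted endemism sums to species
  richness, and per-cell phylogenetic endemism sums to total PD.  The test
  suite uses all three as oracles on every synthetic dataset (relative
  tolerance 1e-6).
* **Deterministic polytomy resolution.**  Polytomies are stored as read;
  operations that need binary trees (the D statistic's sister contrasts)
  resolve them into zero-length ladders with children ordered by their
  smallest descendant label, so results are reproducible irrespective of
  input ordering.

Newick parsing is delegated to dendropy (unquoted labels, underscores
preserved, no comment support); serialization uses shortest round-trip float
representation so write-then-parse is exact.

## Species scores

Fair-proportion evolutionary distinctiveness divides each branch length
equally among its descendant tips; global endangerment (GE) codes the IUCN
category as LC=0, NT=CD=1, VU=2, EN=3, CR=4; and

    EDGE = ln(1 + ED) + GE * ln 2,

with ED in Myr.  Data-deficient species are excluded before scoring (and
never belong to threat scenarios).  Ranking ties are broken by species label.

## Loss scenarios

Five standard scenarios prune (1) the top-k ED species (default: half the
tips; the cycad analysis used 165 of 339), (2) all threatened species
(VU+EN+CR), and (3–5) each threatened category alone.  Each observed
remaining PD is compared with the remaining PD after pruning the same number
of tips uniformly at random (default 100 randomizations, matching the
original analysis; configurable upward for calibration).  The test is
one-tailed in the "more loss than random" direction, with the add-one
estimator

    p = (1 + #{null <= observed}) / (reps + 1),

which cannot return 0 at finite replication.  z = (observed − null mean)/null
sd is reported alongside; a degenerate null (sd = 0, e.g. a star tree) yields
z = NaN with p still valid.  An exhaustive mode enumerates all C(n, k) losses
on small trees and is tested against the sampled null.  Under null losses the
p-values are uniform up to the estimator's 1/(reps+1) grain
(Kolmogorov–Smirnov check in the suite).

## Phylogenetic signal (D statistic)

The observed trait-change sum d is computed by estimating node values
tips-to-root as unweighted child means and summing |left − right| over
internal nodes (over all unordered child pairs at polytomies, though the
statistic itself resolves to binary first).  D rescales d between two
simulated references on the same tree:

    D = (d_obs − mean d_BM) / (mean d_rand − mean d_BM),

where d_rand comes from prevalence-preserving tip permutations and d_BM from
Brownian liabilities (sigma = 1) thresholded to the observed prevalence;
1000 draws each by default (the cited method's convention), so the
Monte-Carlo error of D shrinks as 1/sqrt(B).  P_rand is the fraction of
permutation d-values ≤ d_obs (departure from random), P_BM the fraction of
Brownian d-values ≥ d_obs (departure from Brownian clumping); add-one
smoothed versions are reported alongside the raw fractions because a raw
count of zero is otherwise indistinguishable from rounding.  Because the
same node-value estimator is used for the observed tree and both nulls, the
construction is self-normalizing; internals may still differ from other
implementations in the node estimator, which is why the package calibrates
itself: over replicate simulated trees, mean D is ≈1 under random traits and
≈0 under Brownian-threshold traits (both within 3 standard errors in the
suite).  ED-vs-threat group comparisons use classical one-way ANOVA.

## Diversification models

All six models condition on two lineages at the root age and treat the
reconstructed process as piecewise constant between lineage-addition events:
with k lineages and per-lineage rate lambda, an interval contributes
−k·lambda·dt and an event ln(k·lambda).  The event constants (summing to
ln (N−1)!) are retained in every model — including the Nee et al. birth–death
form, which reduces exactly to the pure-birth likelihood at extinction
fraction a = 0 — so AIC values are comparable across models.  Free-parameter
counts are pureBirth 1 (r), bd 2 (r, a), DDL 2 (r0, K), DDX 2 (r0, x),
yule2rate 3 (r1, r2, shift), yule3rate 5 (three rates, two shifts).

* **pureBirth** has the closed-form ML rate (events)/(lineage-time
  integral), checked against the numeric optimum.
* **bd** maximizes the conditioned birth–death likelihood over r > 0,
  0 ≤ a < 1 with L-BFGS-B and ten seeded random restarts.
* **DDL/DDX** make the per-lineage rate a function of the standing diversity
  k (r0·(1 − k/K) with K > N, and r0·k^(−x)); r0 is profiled out in closed
  form and the remaining hyperparameter optimized by grid scan plus bounded
  refinement.
* **yule2rate/yule3rate** place era boundaries on a candidate set and use
  closed-form per-era rates.  Candidates are the union of a 10-point equally
  spaced age grid and the deciles of the observed event ages, with at least
  max(2, min(5, events/10)) events per era and a minimum era duration of 2%
  of the root age.  The coarse, partly density-adaptive candidate set is a
  deliberate design choice: unrestricted boundaries let sliver eras bracket
  a few near-simultaneous branchings, inflating the likelihood without
  bound, and a purely uniform grid starves old eras of events on
  coalescent-like trees (old genus stems, young crowns) where branchings
  concentrate near the present.  Under this convention, measured over
  simulation replicates: on constant-rate Yule trees (n = 200) the
  rate-constant family wins the AIC contrast in the majority of runs; on
  two-era trees (rates 0.2 → 0.02, n = 300) the rate-variable family wins in
  ≥ 90%; and three-era simulations recover the rate ordering in ≥ 80% of
  runs.

Model choice reports delta_AIC_rc = AIC(best rate-constant) − AIC(best
rate-variable); positive values favor rate variability and ties favor the
simpler family.

The clade rate comparison contrasts branch-length distributions: branch
lengths inside a focal clade and outside it are modeled as exponential (ML
rate = 1/mean), and twice the log-likelihood gain of separate rates over a
pooled rate is referred to chi-square with 1 df.  A clade is flagged "hot"
when its rate exceeds the outside rate at the chosen level (default 0.05).
The chi-square reference is asymptotic; the suite verifies p is uniform
under equal rates at 50 branches per side.  Whole-tree topological shift
statistics are out of scope; this branch-length contrast covers the
hot/cold-clade labeling.

## Grid metrics and hotspots

Occurrences are binary presences on an abstract equal-area lattice of
nominal 100×100 km cells (no projections, coastlines, or polygon geometry).
Per occupied cell: SR (count), PD (Faith PD of the occupants), WE (sum of
1/range over occupants), CWE = WE/SR, PE (each branch contributes
length/|range| to every cell of its range, the range being the union of its
descendants' cells), and mean EDGE over scored occupants (DD species are
invisible to this map; a cell occupied only by DD species is unoccupied for
it).  CWE rather than raw WE feeds the hotspot analysis, following the
richness-corrected definition of the endemism metric this analysis cites;
the WE map is still emitted.  Mean (not summed) EDGE per cell follows the
way the corresponding map is described.

Hotspots are the richest cells of each metric among *occupied* cells only
(richness percentiles over empty ocean cells would be meaningless):
ceil(p/100 · n_occupied) cells at p = 2.5 and 5 by default, ranked by value
descending with ties broken by ascending cell id — hence membership is
invariant under monotone transforms of the metric.  Overlap is reported as
exclusive Venn region counts (which partition the union), cumulative extent
as |union| × 10,000 km² and as percent of occupied cells (the denominator is
stated because "percent of range" is otherwise ambiguous).  A cell is
protected iff its protected fraction is ≥ 0.5, and a hotspot set with
coverage < 1 is flagged as a protection gap.

## Synthetic data

The generators define the study conditions; their defaults are fixed, not
tuned per run:

* **Trees.**  Forward Gillespie birth–death simulation from two lineages,
  extinct lineages pruned, retried (cap 1000) on total extinction.
  Conditioning on n tips stops the simulation when the extant count first
  reaches n and places the present at the time the next event would have
  occurred — a simple stopping rule, adequate for the recovery experiments
  here, though not the full generalized sampling approach.  Piecewise rates
  (shift times in forward time from the root) supply the two- and three-era
  recovery targets.  The pure-birth growth law E[N(T)] = 2·exp(rT) is
  verified against the simulator over 800 replicates.
* **Cycad-like trees.**  339 species in 11 monophyletic genera by default.
  Genus stems attach to a ladder backbone at ages uniform in 40–300 Myr;
  crowns radiate at ages uniform in 2–13 Myr as rescaled Yule trees — the
  decoupling of old origins from late-Cenozoic radiations that makes the
  cycad tree coalescent-like, with the calibration scale of its dated
  phylogeny.  Genus sizes are multinomial on the observed genus-size profile
  (Cycas 113 … Microcycas 1), each genus guaranteed one species.
* **Threats.**  Default category frequencies reproduce the observed
  marginals — VU 78, EN 70, CR 67 of 339 (215 threatened); the nonthreatened
  remainder is split LC 94 / NT 30 (the source gives only the total of 124;
  roughly three-quarters LC matches the flavor of the group) and DD defaults
  to 0 so all 339 species are scored.  `iid` mode draws categories
  independently; `clustered` mode (the default) simulates one Brownian
  liability on the tree and cuts it at the category quantiles, giving exact
  marginal counts and, by construction, the Brownian-threshold null of the D
  statistic — the self-consistent calibration target.
* **Occurrences.**  Lognormal range sizes (log-mean 1.8, log-sd 1.0: median
  ~6 cells, right-skewed) grown as contiguous random-walk patches around
  niche centers on a 40×20 lattice; centers evolve by 2-D Brownian motion on
  the tree (sigma 1 cell/sqrt(Myr), reflected at the borders) so sister
  species overlap more than random pairs — verified by permutation
  comparison.
* **Protection mask.**  A Gaussian random field smoothed at ~1/8 of the
  short grid axis, rank-uniformized and raised to the power (1−f)/f, which
  has mean f exactly for uniform ranks while staying patchy; f defaults
  to 0.3.
* **Grafting.**  Species without molecular data are attached uniformly at
  random to a branch inside their genus crown (the stem for a monotypic
  genus) at an age uniform on that branch — a single-draw stand-in for
  posterior taxonomic imputation, preserving ultrametricity, genus
  monophyly, and all original tip relationships.  A replicate count is the
  caller's choice; nothing assumes a single completed tree.

What passing tests on these data establish: the estimators hit their nulls
and recover known parameters under the assumed generative models.  What they
do not establish: robustness to spatial sampling artifacts, synonymy noise,
range-size error, non-Brownian threat clustering, or dating uncertainty —
all properties of real occurrence and assessment data that the generators
deliberately idealize.

## Pipeline and reproducibility

The pipeline consumes either four files (Newick tree; species,category TSV;
species,cell_id TSV; cell_id,protected_fraction TSV) or a simulation
configuration — never both.  Outgroups, when listed, are dropped before the
diversification stage only (their role elsewhere is left to the caller, who
can prune beforehand).  Species present in occurrences but absent from the
tree are a hard error; tips without threat status are a hard error; softer
inconsistencies are reported by the validator.  Every stochastic stage draws
from a stream spawned from the single pipeline seed, so a configuration
yields a byte-identical output bundle (manifest aside, which echoes the
output path).  Per-genus clade-rate tables are derived from tip-label
prefixes (Genus_species naming).

Problem sizes used by the test suite and the acceptance script — 339-tip
default runs; 100–200 replicate calibrations on 100–200-tip trees with
150–200 Monte-Carlo draws inside each D statistic; 500-replicate scenario
calibration; 100-replicate recovery experiments at n = 200–300 — were chosen
as the smallest sizes at which the Monte-Carlo standard errors are clearly
inside the tolerances being asserted.
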