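# Methods

## Model

All likelihoods are built on a time-reversible nucleotide substitution
model (HKY85 by default, GTR optionally) with the rate matrix calibrated
to one expected substitution per site at stationarity, so branch lengths
are in substitutions/site. Base frequencies are the observed frequencies
in the alignment being fitted (with a 0.5 pseudocount); κ, or the six
GTR exchangeabilities, are estimated by maximum likelihood. Column
likelihoods use Felsenstein pruning with transition matrices obtained
from the symmetric similarity transform `S = D^{1/2} Q D^{-1/2}`
(D = diag(π)), eigendecomposed once per model. `N` and `-` are both
treated as missing data (a partial-likelihood vector of ones); gaps are
never a fifth state, and there is no among-site rate variation in the
neutral model — the selection mixture below is the only site
heterogeneity.

The selection test compares a query alignment against a proxy-neutral
reference on a shared tree. Reference sites evolve neutrally on every
branch. Query sites fall into categories defined by two multipliers
(background branches, foreground branch):

| category | weight (null) | weight (alt) | bg | fg |
|---|---|---|---|---|
| purifying | b1(1−Δ) | b1(1−Δ1) | ζ₁ | ζ₁ |
| relaxed (null) | b1Δ | — | ζ₁ | 1 |
| selected, ex-purifying | — | b1Δ1 | ζ₁ | ζ₃ |
| neutral | b2 | b2(1−Δ2) | 1 | 1 |
| selected, ex-neutral | — | b2Δ2 | 1 | ζ₃ |

with b2 = 1 − b1, ζ₁ ∈ (0,1), ζ₂ ≡ 1, ζ₃ > 1. There is no
neutral→purifying switch in either model. The likelihood-ratio statistic
2(lnL_alt − lnL_null), clamped at zero, is referred to χ² with one
degree of freedom even though the alternative has two extra nominal
parameters; this under-counts and makes the test conservative, which
matches how the p-values are used (nominal p < 0.05, no FDR correction
by default; Benjamini–Hochberg is available for batch output because
repeated testing of the same query should be adjusted).

The reported effect size is the mixture-weighted mean foreground rate
under the alternative MLE,
ζ = b1(1−Δ1)ζ₁ + b1Δ1ζ₃ + b2(1−Δ2) + b2Δ2ζ₃, which equals
K_query/K_reference on the foreground branch under the fitted model. A
single number is reported per test because the mixture parameters
themselves are weakly identified on 300 bp of data, while their weighted
mean is stable.

## Optimization

`TestConfig.mode` selects one of two fitting schemes.

**joint (default).** Branch lengths and mixture parameters are
optimized together, so the null can trade reference likelihood against
query likelihood — in particular it can stretch the foreground branch
slightly to absorb a chance excess of foreground substitutions, at a
cost paid on the reference. Implementation: (1) a reference-only fit
("stage 1") estimates branch lengths, π and κ; (2) fixed-tree restarts
(`n_restarts`, default 20; random b1, Δ ~ U(0,1), ζ₁ ~ U(0.05, 0.95),
ζ₃ ~ LogU(1.05, 20)) locate the mixture basin cheaply; (3) L-BFGS-B
refines all branch lengths (log scale, bounds [1e-8, 10]) jointly with
the mixture from that basin, with π and κ pinned at their stage-1
values — a 3 kb reference determines them essentially exactly, and
pinning them keeps the eigendecomposition out of the inner loop; (4) a
Nelder–Mead polish of the mixture at the refined tree finishes the fit
(quasi-Newton stalls on the mixture's flat ridges; the simplex step
reliably walks to the mode). The alternative model is additionally
refined from the null's joint solution with ζ₃ at its lower bound, which
reproduces the null inside the alternative's parameter space and
guarantees lnL_alt ≥ lnL_null up to optimizer noise; residual negative
differences (≲1e-7) are clamped to zero.

**two_stage.** Branch lengths stay fixed at the stage-1 estimates and
only the mixture is optimized (same restart scheme, simplex polish of
the three best restarts). Roughly twice as fast, and adequate when the
reference is long; but because the null cannot flex the foreground
branch, its false-positive rate under relaxation-of-constraint
simulations runs one to two points above the joint fit's. The joint
mode is therefore the default and the mode used by the acceptance
study.

Parameter bounds: ζ₁ ∈ [1e-4, 1−1e-4], ζ₃ ∈ [1+1e-4, 50] (the finite
cap prevents divergence on saturated columns), fractions in [0,1].
Alignments are collapsed to site patterns before any likelihood work.
An alignment with no variable site yields zero branch lengths and a
warning flag rather than an error.

One identifiability note: under a reversible model the root position is
arbitrary — only the *sum* of the two root-adjacent branch lengths is
estimable, and the optimizer splits it arbitrarily. Consumers of fitted
trees (including the recovery tests) should compare that pair by its
sum. Relative branch lengths, total tree length and all likelihoods are
unaffected.

## Proxy-neutral pipeline

Candidate windows (default 300 bp, non-overlapping, drawn in seeded
random order) come from a genome alignment in which every functionally
annotated column has been masked to N. A window is discarded if it
contains any masked column, or if any species has more than 20% missing
cells (threshold configurable; the cited annotation sources do not pin
it down). Each survivor is fitted for branch lengths; then, in order:

1. **Minimum-rate floor** — drop windows where *any branch's* relative
   branch length is below 0.001. The rule's source phrasing is ambiguous
   ("relative substitution rate < 0.001 for any of the sites"); we read
   "sites" as sampled regions and "any" as any branch, since near-zero
   branch rates are the artifact being removed. A foreground-only
   variant is available via `foreground_only=`.
2. **Interquartile filter** — keep windows whose foreground relative
   branch length lies within [Q1, Q3] of the pool (linear-interpolation
   quantiles, inclusive band, so ties survive deterministically). The
   percentile bounds are configurable; tightening them trades
   sensitivity for conservativeness.

References are concatenations of k = 10 windows sampled without
replacement (seeded); local references instead concatenate all pool
windows within 100 kb of the query midpoint and raise a distinct error
when none exist, since in annotation-dense regions local proxies are
frequently unavailable — the motivation for the genome-wide pool.

## Synthetic data

`simulate_alignment` evolves independent columns down the tree from a
stationary root draw (only leaf rows are emitted; no indels, no rate
variation). The default simulation model is HKY85 with
π = (0.30, 0.20, 0.20, 0.30) and κ = 4 — a typical primate-like
composition and transition bias.

The four study regimes express selection as branch scalings of an
otherwise neutral tree: neutral (all ×1); relaxation of constraint
(every background branch ×0.1, foreground neutral); positive selection
(foreground ×7); and positive selection with a confounder (foreground
×7 plus the gorilla background branch ×10). "Background" includes
internal branches. Per replicate one neutral tree is drawn, the
reference is simulated on it unchanged (3 kb) and the query on its
scaled copy (300 bp).

Neutral trees come from a parametric sampler: a template 5-taxon
catarrhine tree whose human branch is 0.0072 substitutions/site (the
mean neutral human branch observed for filtered genome-wide
nonfunctional regions) with the remaining branches at literature-typical
primate proportions (total length ≈ 0.096), each branch jittered
independently by a median-preserving lognormal, σ = 0.3. An empirical
table of fitted trees can be substituted (`TreeSampler(empirical=...)`).
What the generator does **not** emulate: indels and alignment error,
CpG hypermutability and other rate heterogeneity along the sequence,
incomplete lineage sorting, and correlated branch-length variation
across the tree. Passing calibration/power tests on these simulations
therefore demonstrates correctness of the statistical machinery under
the stated generative model, not robustness to those real-data
complications.

## Study sizes and determinism

The acceptance study runs 300 replicates per regime with 5 restarts per
fit — enough for ~1-point binomial precision on the false-positive
rates while keeping a full run under ten minutes on a single core.
Every random draw (tree sampling, sequence simulation, restart
initialization) descends from one seed; per-replicate and per-window
seeds are derived through `SeedSequence`, so identical inputs reproduce
byte-identical outputs, including across sliding-window scans where
duplicate intervals derive their seeds from their coordinates.

## Known limitations

* The χ²₁ calibration is conservative on average but not exact; with
  ~2 expected foreground substitutions per 300 bp query the LRT is
  discrete, and the alternative's ability to concentrate Δ₂ on single
  columns at the ζ₃ cap makes the extreme tail slightly heavier than
  χ²₁ predicts. Empirically the false-positive rate stays below the
  nominal 5% in both negative regimes.
* Queries much shorter than ~150 bp carry too few substitutions for
  useful power; the enforced minimum is 50 bp.
* The gorilla-acceleration confounder regime is detected through the
  foreground signal; the background acceleration itself is not modelled
  (no per-branch background rates), which is intentional — it is the
  robustness scenario, not an estimation target.
* MAF reading assumes plus-strand reference rows (minus-strand blocks
  are reverse-complemented on read) and stitches blocks in reference
  coordinate order; overlapping blocks are not reconciled.
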