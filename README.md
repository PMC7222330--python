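# adaptiphy

Branch-specific likelihood-ratio tests for **positive selection in
noncoding DNA**, using filtered, concatenated "proxy neutral" reference
alignments.

Most of the genome is noncoding, and regulatory elements (enhancers,
promoters, open-chromatin regions) have no reading frame, so the classic
ω = dN/dS machinery cannot be applied to them. This package implements
the noncoding analogue: the evolutionary ratio

```
ζ = K_query / K_reference
```

the substitution rate in a query region relative to the rate in a
putatively neutral reference that shares the same phylogeny. ζ plays the
role of ω; ζ > 1 on a chosen *foreground* branch (e.g. human) indicates
lineage-specific acceleration consistent with positive selection.

## The test

Given a query alignment, a reference alignment and a foreground branch,
two site-category mixture models are fitted by maximum likelihood (HKY85
or GTR substitution model, Felsenstein pruning, shared branch lengths;
reference sites always evolve neutrally on every branch):

* **Null model** — a fraction *b1* of query sites is under purifying
  selection at relative rate ζ₁ < 1 on all branches, the rest neutral
  (ζ₂ = 1); a fraction Δ of the purifying sites may evolve neutrally on
  the foreground (relaxation of constraint).
* **Alternative model** — additionally, fractions Δ₁ (of purifying) and
  Δ₂ (of neutral) sites may evolve at ζ₃ > 1 on the foreground
  (positive selection).

Significance comes from `LRT = 2(lnL_alt − lnL_null)` referred to a χ²
distribution with **one** degree of freedom — deliberately conservative.
The reported ζ is the mixture-weighted mean foreground rate under the
fitted alternative model.

Proxy-neutral references are built from the non-functional fraction of a
masked genome alignment: non-overlapping 300 bp windows free of any
functional annotation are fitted for branch lengths, windows with any
relative branch length below 0.001 are dropped, windows whose foreground
relative branch length falls outside the pool's interquartile range are
dropped, and surviving windows are concatenated (10 per reference by
default, ≈3 kb — references of 3–9 kb are recommended).

## Worked example

```python
import adaptiphy as ap

tree = ap.read_newick(ap.DEFAULT_PRIMATE_NEWICK)   # human..macaque, 5 taxa

# a neutral 3 kb reference and a query whose human branch runs 7x faster
ref   = ap.simulate_alignment(tree, ap.DEFAULT_SIM_MODEL, 3000, seed=1)
query = ap.simulate_alignment(tree.scaled("human", 7.0),
                              ap.DEFAULT_SIM_MODEL, 300, seed=2)

res = ap.test_selection(query, ref, "human",
                        ap.TestConfig(n_restarts=5, seed=7, mode="joint"))
print(f"LRT={res.LRT:.2f}  p={res.p:.2e}  zeta={res.zeta:.2f}")
```

prints

```
LRT=9.93  p=1.62e-03  zeta=4.25
```

The LRT of 9.9 on one degree of freedom rejects the null (p ≈ 0.0016),
and the fitted ζ ≈ 4.3 estimates the human-branch rate in the query at
roughly four times its neutral rate — within the sampling noise a 300 bp
region allows on the simulated 7-fold acceleration. Running the same
test with a neutral query (seed 3) prints `LRT=0.00 p=0.997 zeta=0.94`:
the alternative collapses onto the null and ζ sits at 1.

The same functionality is exposed on the command line:

```bash
adaptiphy simulate --regime fg_positive --n 5 --seed 1 --outdir sims/
adaptiphy test --query sims/fg_positive_0000_query.fa \
               --reference sims/fg_positive_0000_ref.fa --mode two_stage
adaptiphy prepare-neutral --maf genome.maf --species human,chimp,gorilla,orangutan,macaque \
               --region chr1:0-5000000 --features functional.bed --outdir pool/
adaptiphy scan --maf genome.maf --species human,chimp,gorilla,orangutan,macaque \
               --region chr4:178000000-178100000 --reference pool/reference.fa --out scan.tsv
```

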