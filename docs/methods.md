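# Methods

## Quantification model

Input is per-CpG methylated/unmethylated call counts.  Two dialects are
read: Bismark coverage (1-based, `start == end`) and bedGraph-with-counts
(0-based half-open); the dialect is auto-detected from the first data row.
CpGs are palindromic, so by default the reverse-strand record at `pos+1`
is folded onto the forward-strand C, doubling effective depth; the merge
is switchable off for inputs that are already strand-collapsed.
Internally every coordinate is 0-based half-open; 1-based dialects are
converted at the parser boundary and nowhere else.

Bins are fixed-phase 200-bp tiles anchored at coordinate 0 (no sliding
windows, no special casing of chromosome ends beyond natural truncation).
A site at `pos` belongs to bin `floor(pos / 200)`.  The bin level is the
percentage of methylated calls among all calls pooled over the bin's
CpGs; the coverage filter (`n_cpgs >= 2 and total_calls >= 10`) is read on
the same pooled quantity, because the level itself is defined over pooled
calls.  Uncovered bins are omitted rather than set to 0 — absence of
evidence is not hypomethylation.  Global methylation defaults to *site*
mode (pooled calls, so each call counts equally); *bin* mode (unweighted
mean of bin levels) is retained because the global significance test uses
bins as observations.

## DMR calling

The profiles compared are pooled-sample methylomes without biological
replicates, so DMR calling is a deterministic threshold rule: a bin
passing the filter in both profiles is differential iff its level changes
by strictly more than 15 percentage points (absolute difference, not
relative change).  No p-value is attached to individual bins.  Adjacent
same-direction bins are *not* merged by default — counting is at bin
resolution — though `merge_adjacent_dmrs` is available for region-level
reporting.

### The noise floor of threshold calling

A 15-point cutoff on a difference of two binomial proportions is only as
clean as the coverage allows.  With per-profile bin coverage *n* calls,
background methylation *p*, and per-CpG beta-binomial overdispersion ρ at
depth *d*, the difference has standard deviation

```
sd(Δ) = sqrt( 2 · p(1−p) · (1 + (d−1)ρ) / n ) · 100   (points)
```

At the synthetic default (p = 0.75, d ≈ 20, ρ = 0.05, n = 50–100 calls)
this is ~10–13 points, so |Δ| > 15 occurs for roughly a tenth of null
bins; even pure binomial noise (ρ = 0) at 20× gives a few percent.  The
acceptance suite measures this honestly (~11% on null bins with ≥ 50
calls in both profiles, alongside ~98% recall of planted |Δ| = 30 bins);
driving it below 1% requires on the order of 60× coverage with no
overdispersion.  Real studies blunt the effect with deeper coverage,
region-level merging, or dispersion-aware tests; those are deliberately
outside this package's scope, which reproduces the plain threshold rule.
The consequence to keep in mind when reading the eight-group tables at
desk scale: the low-coverage non-CGI compartment carries a symmetric
noise load on top of any planted asymmetry, while the CpG-dense CGI
compartment (~20 CpGs per bin, ~400 calls) is essentially clean.

## Region classification

Gene models come from refFlat tables.  Isoforms of a gene are collapsed
to the union of their exons (outermost transcript and CDS bounds) before
classification; "first" and "last" exon are taken in transcription
orientation on the collapsed model.  Per overlapping gene, a bin gets
exactly one category:

- **3′** — last exon ∪ 3′ UTR;
- **5′** — `promoter_span` bases upstream of the TSS ∪ first exon ∪ 5′ UTR;
- **gene body** — the rest of the transcript span;
- **intergenic** — no gene (nor promoter window) overlapped.

`promoter_span` defaults to 2000 bp, a common convention; it is exposed
(0 disables the upstream extension) because the 5′ extent is a genuinely
open choice.  Bins straddling sub-regions are resolved by the precedence
3′ > 5′ > body, chosen so that 3′-end signal — the biologically loaded
category here — is never diluted into the gene body; the precedence is a
constructor argument.  A bin overlapping several genes is assigned to
every one of them: region distributions count bin–gene assignments, not
unique genes.  CGI status is binary overlap (≥ 1 bp, half-open semantics)
against a load-time-merged island list.

## Statistics

- **Global proportion test.**  Each mutually passing bin contributes one
  Bernoulli observation (success = profile *a* higher; ties dropped), and
  the sign test against p = ½ is exact (binomial) for n ≤ 500, else a
  continuity-corrected normal approximation.  The bin is the unit of
  observation; because the phrase "test for proportions" does not pin the
  statistic, a pooled two-proportion z test over summed calls is also
  provided (`method="pooled_z"`), with the sign test as default since it
  respects bins as the observations.
- **Enrichment.**  Per term a 2×2 table (in-set/out-of-set ×
  DMR/non-DMR) restricted to the supplied universe; two-sided Fisher p by
  the minimum-likelihood rule (sum of hypergeometric probabilities not
  exceeding the observed table's — conventions differ between toolchains,
  so this is stated explicitly and tested against full enumeration);
  Bonferroni over the terms actually tested.  Gene sets are plain GMT
  files, so there is no web-service dependency.
- **t tests** default to pooled-variance Student (Welch by flag),
  two-tailed.
- **Regression.**  `expression ~ 1 + methylation + age` by OLS, age in
  days as a continuous covariate (log1p(age) by flag; the parameterisation
  is an open choice).  Requires ≥ 4 observations and a design condition
  number ≤ 1e8 after column scaling — methylation collinear with age is a
  degenerate design, reported as such rather than fitted.
- **BH FDR** is the standard step-up with enforced monotonicity, input
  order preserved.  Note it is *not* idempotent (re-adjusting adjusted
  values re-applies the n/rank scaling); the tests check monotonicity and
  agreement with an independent step-up implementation instead.
- **Clustering.**  Agglomerative, Euclidean distance, average linkage by
  default (the choice is recorded in run output since it is not forced by
  anything); rows can be z-scored first (off by default — panels are on a
  common percent scale).  Leaf order is deterministic, with distance ties
  broken by original item index; a constant matrix clusters without error
  under that tie-break.

## The synthetic study generator

The generator emulates the statistical structure the pipeline assumes,
not sequence-level reality.  Defaults describe a desk-scale study that
runs in seconds on one CPU:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 2 Mb | minutes-scale end-to-end runs |
| genes / CGIs | 200 / 300 | CGIs placed preferentially at gene 5′ and 3′ ends so 3′-CGI DMRs exist to plant |
| CpG spacing | 100 bp background, 10 bp in CGIs | ~1 CpG per 100 bp genome-wide with ~10× CGI densification, the mammalian pattern |
| coverage | Poisson, mean 20 calls/CpG | a 20× WGBS design |
| noise | beta-binomial, ρ = 0.05 | real WGBS is overdispersed; ρ = 0 recovers pure binomial for analytic checks |
| baselines | 75% non-CGI, 10% CGI | hypermethylated genome, hypomethylated islands |
| planted Δ | ±30 points | comfortably above the 15-point cutoff |
| differentiated-cell shift | −3 points (non-CGI) | small global hypomethylation of progeny relative to stem cells; below the DMR threshold by design |

Maturation plants shift every age after the first in *both* cell types
(so they cancel in the differentiation contrast); differentiation plants
shift the differentiated cell type at *all* ages (so they cancel in the
maturation contrast).  The planted composition follows the direction
structure the pipeline is meant to detect: CGI gains concentrated at
gene-body/3′ islands, non-CGI losses at island shores, and far fewer
differentiation plants than maturation plants.  Two constructions deserve
a note: CGIs planted to *lose* methylation start from an elevated 55%
baseline in all samples (a −30 shift from the 10% island floor would be
meaningless), emulating tissue-specific methylated islands; and non-CGI
*gains* use +20 rather than +30 because the 75% background leaves only 25
points of headroom.

Expression series couple a gene's output to its 3′-CGI methylation:
methylation follows a saturating postnatal rise `base + Δ·age/(age+τ)`
(τ = 7 days — most of the gain inside the suckling period), and
expression is `intercept + coupling·methylation + age-slope·age + noise`,
divided by a simulated reference-gene factor so values are on a
relative-to-housekeeping scale.  Uncoupled control genes share the
age term but not the methylation term.

CpG panels (site × sample percent matrices) carry gain/loss/stable
trajectories over three ages with small within-age noise; under the
germ-free condition a planted block of gain rows stalls at its birth
level, and two constant high-methylation rows emulate generic repeat
elements (Line1, IAP) whose maintenance is condition-independent.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: no read-level artefacts (M-bias,
conversion failure, mapping error), no spatial autocorrelation beyond the
planted regions, no CNVs/SNPs, no replicate-level biological variation
between animals (samples are pools, as in the emulated design), and a
gene/CGI density ~8× the genome-wide mammalian average (desk-scale
compression), which is why synthetic global methylation (~43%) sits far
below a real colon methylome (~70–74%): the CGI compartment carries a
far larger share of CpGs here.  Truth-recovery results therefore
demonstrate correctness of the machinery under the stated noise model,
not field performance on any particular organism.

## Numerical choices

- True per-CpG levels are clipped to [0.5, 99.5]% before sampling so
  beta parameters stay strictly positive.
- Sign-test ties are dropped, not split.
- The exact-vs-normal switch for the sign test sits at n = 500, where the
  continuity-corrected normal is accurate to ~1e-3 of the exact p.
- `fisher_exact` tables are built after restricting both the gene list
  and every term to the universe; terms empty after restriction are not
  tested and do not inflate the Bonferroni factor.
- Undefined quantities (means over empty passing sets, tests with < 2
  informative observations, zero-variance t tests with unequal means)
  raise a dedicated error type rather than returning sentinel values.
- All generator randomness derives from `numpy` seed sequences
  `[seed, stream]`, so each output family (layout, CpG placement, counts,
  expression, panels) is independently reproducible and byte-identical
  across runs for a fixed seed and configuration.

## Scale of the shipped analyses

The drivers, tests and the acceptance script run the default 2 × 2 Mb
study (4 samples, ~68k CpGs each), 5-seed truth-recovery replicates,
1000-replicate regression calibrations, and 20-seed panel clustering —
sizes chosen so the complete suite executes in well under five minutes on
a single CPU while leaving every measured rate with enough trials to be
stable to a point or two.

## Known limitations

- The threshold caller's false-positive floor at 20× (discussed above) is
  a property of the method being reproduced, not removable here without
  changing the method.
- Enrichment is flat over user-supplied terms: no ontology-hierarchy
  propagation or parent–child correction.
- No smoothing/HMM DMR detection, no replicate dispersion modelling, no
  mixed-effects regression, and no normality screening of candidate-gene
  data (input scale is trusted).
- The "7% (41/517)" style overlap statistic floors to an integer percent
  by construction; it is a reporting convention, not a test.
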