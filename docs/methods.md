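# Methods

## State space and frequency model

A locus inside a common CNV is described by an allele-specific copy-number
(ASCN) state: the unordered multiset of A and B alleles an individual
carries, with total copy number CN ∈ {0, …, 4}. There are 15 such states
(1 + 2 + 3 + 4 + 5), with the zero-copy state written NULL. States are
phase-free: no distinction is made between, say, B|BB and BB|B — the model
assumes the disease risk of a state does not depend on how its copies are
distributed over the two chromosomes. Consequently CN > 4 (which would
require a chromosome with more than two copies) and multi-allelic SNPs are
out of scope.

Control-population frequencies arise from random mating over three
chromosome classes — deleted (0 copies), normal (1), duplicated (2) — with
frequencies `f(del) + f(norm) + f(dup) = 1`. A population carries deletions
only (`f(dup) = 0`), duplications only (`f(del) = 0`), or both with equal
frequency `f(del) = f(dup) = (1 − f(norm))/2`. Total copy number is the sum
over a random chromosome pair; conditional on CN = c, the B-allele count is
Binomial(c, f(B)). The two copies on a duplicated chromosome are treated as
two independent allele draws; nothing in the frequency construction requires
them to match, and the binomial structure is the simplest model consistent
with combining per-copy allele frequencies. (A shared-draw variant would
concentrate mass on homozygous high-CN states; it is not implemented.)

## Risk model and case frequencies

Risk is multiplicative with reference state AA:

    RR(state) = RR_CN^(CN − 2) · RR_allele^(#B)

Case-state frequencies are the risk-tilted control frequencies,
`P_case(g) = P_ctrl(g)·RR(g) / Σ P_ctrl·RR`. Under case-control sampling
with a logistic link this makes the per-state log-odds-ratio versus AA
exactly `log RR(state)`, which is linear in (CN, #B) — so the joint
regression below is correctly specified and recovers both effects without
bias, a property the estimator-recovery tests exercise directly.

The formula applied at CN = 0 gives the NULL state RR_CN^(−2). This is a
uniform-extrapolation choice, not an empirical fact about zero-copy
genotypes; `RiskModel(null_rr=...)` overrides it.

The study grid crosses `f(norm) ∈ {0.8, 0.5, 1/3}`, the three CNV types and
`f(B) ∈ {0.05, 0.20, 0.35, 0.50}` (36 frequency scenarios) with
`RR_CN, RR_allele ∈ {1, 1.2, 1.5, 2}` (16 risk scenarios including the
double null).

## Association strategies

All five strategies are logistic regressions tested with an LRT against the
intercept-only model, p-values from the asymptotic chi-square (no
small-sample correction). Phenotype is coded 0 = control, 1 = case. NULL
individuals are included everywhere (CN covariate 0, B-count covariate 0,
own indicator in the codominant model).

The joint model uses the sum S = A+B and difference D = A−B of allele
counts. Substituting S = c and D = c − 2b into the risk predictor
`(c−2)·log OR_CN + b·log OR_allele` gives β₁ = log OR_CN + ½ log OR_allele
and β₂ = −½ log OR_allele, hence the back-transformation
`OR_allele = exp(−2β₂)`, `OR_CN = exp(β₁ + β₂)`.

Fitting runs on state-aggregated case/control counts (at most 15 covariate
patterns), with a Newton/IRLS solver written for this package: the study
engine fits on the order of 10⁵ regressions per run and per-fit overhead
dominates with a generic GLM routine. The solver uses step-halving to
guarantee likelihood ascent, declares convergence when the log-likelihood
changes by < 1e-10 (max 60 iterations), and flags rank deficiency or
(quasi-)separation — any coefficient beyond ±30 on these 0–4-range
covariates — as non-converged, in which case no p-value is reported and the
study engine counts the replicate as failed rather than dropping it
silently. The test suite cross-checks coefficients and log-likelihoods
against statsmodels GLM and against a dense grid-search oracle on tiny
cohorts.

The codominant model, having one indicator per observed state, is the
saturated model on state categories; its maximized log-likelihood is
computed in closed form from per-state case fractions (cells with only
cases or only controls contribute 0 via the 0·log 0 limit, which is the
finite limit an iterative fitter approaches). Its df is the number of
observed states minus 1; the reference is AA, falling back to the most
frequent observed state (flagged) if AA is absent. Empty-cell coefficients
are ±inf and flagged, but the LRT and p-value remain valid and are always
reported — this sparse-cell regime is precisely where the codominant test
over-rejects under the null.

The bi-allelic strategy excludes missing calls and requires non-missing
calls in both phenotype groups. When every individual has CN = 2 and no
calls are missing it coincides exactly with the multi-allelic trend test.

QC on bi-allelic calls: missing-call fraction, and Hardy–Weinberg
equilibrium in controls via an exact test (two-sided in the standard
sum-of-less-probable-outcomes sense, computed with log-gamma arithmetic;
monomorphic samples return p = 1 by convention). A chi-square variant is
available by option.

## Simulator

Cohorts are drawn i.i.d. from the analytic control and case distributions
via multinomial sampling. Two degradation layers emulate array reality:

**Bi-allelic calling.** Each state maps to a call (AA/AB/BB/missing) by a
15×4 row-stochastic table. The default table shipped with the package is a
synthetic stand-in expressing the qualitative behaviour reported for
Illumina-type arrays — faithful calls with ≤1% missingness at CN 1–2, ≥50%
missingness at CN 0/3/4 with the residual mass on allele-compatible calls,
and asymmetric missing rates for the heterozygous 3- and 4-copy pairs
(AAB 60% vs ABB 70%; AAAB 65% vs ABBB 75%), reflecting the dye bias that
makes those states call asymmetrically. It is a data file
(`data/call_table_default.tsv`) intended to be replaced by an empirically
estimated table when one exists; conclusions that depend on the precise
default values (notably the bi-allelic strategy's power) should be read as
qualitative.

**CNV calling errors.** True carriers (CN ≠ 2) go undetected with
probability 1 − sensitivity (study defaults 0.2 or 0.5), collapsing to AA or
BB if single-allele, AB if heterozygous, uniform over {AA, AB, BB} from
NULL. True two-copy individuals are falsely flagged with probability
1 − specificity (default 0.99): a wrong CN is drawn uniformly from
{0, 1, 3, 4} and the state remapped compatibly (AA→A/AAA/AAAA,
BB→B/BBB/BBBB, AB→{A,B}, {AAB,ABB} or {AAAB,AABB,ABBB}; wrong CN 0 → NULL).
Where several outcomes are listed, they are taken equiprobable — stated
explicitly for some branches and adopted uniformly for the rest.

The simulator works at the state level; it does not generate Log R ratio or
BAF signal, so upstream CNV-caller behaviour (segmentation error,
probe-level noise correlation) is represented only through the two summary
error rates. Passing tests therefore demonstrate the statistical properties
of the strategies under this generative model, not the end-to-end behaviour
of an array pipeline on real intensities.

## Study engine

`run_study` crosses scenarios × risks, runs the pipeline per replicate and
aggregates rejection fractions at the chosen significance level (default
0.05), Monte-Carlo standard errors `sqrt(p̂(1−p̂)/n)`, and the
median/mean/MSE of the transformed joint odds ratios over converged
replicates, with failed counts reported alongside. Rejection denominators
use converged replicates. Randomness flows from one master seed through
`SeedSequence` spawning per cell and per replicate, so results are
bit-identical regardless of evaluation order; every stage (simulation,
degradation, error injection) gets its own substream. The full-study preset
is 10,000 replicates per cell; the desk preset is 1,000, which bounds the
Monte-Carlo SE of a power estimate by ~1.6 percentage points. The packaged
reproduction script uses 1,000 replicates for the power and relative-power
quantities and 10,000 for the null-inflation scan, whose target is a
maximum over eight cells and benefits most from replication.

## Real-data path

ASCN states are reconstructed per (SNP, sample): the copy number comes from
the overlapping `.rawcnv` segment for that sample (2 where none overlaps;
coordinates 1-based inclusive; conflicting overlapping segments raise an
error rather than being resolved arbitrarily, since no principled
resolution exists at this layer), and the state is the one whose expected
BAF b/CN is nearest the observed BAF. For CN = 1 this is exactly the
BAF < 0.5 → A rule; for higher CN the nearest-expected-BAF bins with
midpoint boundaries are a documented stand-in for a "most probable state"
rule, with ties broken toward the lower B count. Per-individual CNV
boundaries may differ across samples, so CN is always resolved per (SNP,
sample), never per region.

SNPs are retained when MAF ≥ 0.05 (computed from non-missing bi-allelic
calls), the SNP lies in a CNV region, and the frequency of abnormal copy
number is ≥ 5%; the bi-allelic strategy additionally requires < 5% missing
calls. Group 1 is coded as cases, group 2 as controls. Bonferroni
corrections use each strategy's own test count; for the copy-number trend
strategy the count is the Li–Ji-style effective number of tests
`Meff = Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)]` over the eigenvalues of the
SNP×SNP correlation matrix of copy numbers (constant columns dropped),
rounded up.

## Known limitations

* Phase-aware risk models are excluded by construction.
* The default call table is qualitative, not estimated from data.
* No covariate adjustment, no missing-call imputation, and no analytic
  power formulas — power is always simulated.
* The codominant model's closed-form fit reports an LRT even with empty
  cells; the chi-square reference is then an approximation, which is the
  very mechanism of its null inflation in sparse scenarios.
* The A↔B relabeling symmetry of the multi-allelic trend test holds only on
  constant-CN cohorts: with varying CN the relabelled covariate CN − #B
  leaves the one-covariate model space. The copy-number and joint tests are
  exactly relabeling-invariant.
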