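# Methods

`sgesim` simulates a closed pig-breeding nucleus for a trait with social
genetic effects (SGE) and reproduces the analysis pipeline such a study
needs: trait simulation on a simulated genome, pen allocation, BLUP
evaluation under models with and without SGE, AI-REML variance estimation,
and optimum-contribution selection (OCS) under a pedigree rate-of-inbreeding
constraint.

## Trait model

Each animal carries two genetic effects: a direct effect `u_D` on its own
phenotype and a social effect `u_S` on the phenotype of each of its pen
mates.  With constant pens of `n = 12`,

    y_i = u_D(i) + sum_{j in pen(i), j != i} u_S(j)
          + c_pen + c_litter + e_i .

The defaults are the reference full-scale conditions: `var(u_D) = 1`,
`var(u_S) in {0.001, 0.01}`, correlation `r_DS in {-0.5, 0, 0.5}`,
`var(pen) = var(litter) = 0.25`, `var(e) = 2.5`.  With a constant group
size a social *environmental* effect is completely confounded with the pen
effect and is not simulated separately.  The total breeding value of an
animal is `u_TBV = u_D + (n - 1) u_S`, with heritable variance
`s2_TBV = s2_D + 2(n-1) s_DS + (n-1)^2 s2_S`.

## Genome and gene dropping

The genome is 18 autosomes totalling 30 Morgan with biallelic markers and
QTL placed uniformly (default counts 54,218 and 2,000; every count is
overridable).  Founders are drawn in linkage equilibrium with allele
frequencies `Uniform(0.05, 0.95)`; meiosis uses Poisson crossover counts
per chromosome (Haldane map, no interference).  Raw QTL effect pairs are
bivariate normal at the target genetic covariance and then jointly linearly
transformed (target Cholesky times inverse realized Cholesky) so the
*realized* founder covariance of `(u_D, u_S)` equals the target exactly —
the base population starts at precisely the stated parameters.  Effects
stay constant; only allele frequencies move under drift and selection.
Each founder haplotype carries an immutable integer label per locus;
identity of an animal's two labels at a locus is identity by descent, and
the true inbreeding coefficient is the labelled fraction averaged over all
simulated loci.

What the generator deliberately does not emulate: base-population linkage
disequilibrium (founders are in LE), mutation, dominance and epistasis,
sex chromosomes, variable litter or pen sizes.  Conclusions that hinge on
realistic LD — notably absolute genomic-prediction accuracies — transfer
only qualitatively.

## Breeding program

Generation 1 is the founder parent set (30 sires, 600 dams at full scale;
the desk scales in the tests keep 20 dams per sire, litters of 6 with 3 of
each sex, and pens of 12, and shrink only the number of sire families).
Parents of generation 3 are drawn at random from generation 2.  From
generation 3 on, each cohort is phenotyped, evaluated by BLUP on all data
from generation 2 up to the current one, pre-selected on EBV (top 1/6 of
males, top 1/4 of females), and parental contributions are optimized.
Breeding schemes: `SGM_TBV` and `SGM_DGE` evaluate with the social model
and select on predicted TBV or predicted DGE; `CGM_DGE` evaluates with the
classical model (no social term).  Relationships are either pedigree (`A`)
or genomic (`G`, VanRaden method 1 centered at the known base frequencies,
blended `0.99 G + 0.01 A` for invertibility); the OCS coancestry constraint
always uses `A`.

### Mixed-model equations and solver

Henderson MME with generation means as fixed effects (indicator columns
without an intercept are full rank, so no explicit constraint is needed),
one or two correlated genetic effect vectors with prior covariance
`G0 (x) U`, and pen and litter random effects.  The solver is a Jacobi-
preconditioned conjugate gradient on the assembled normal equations
(relative residual below 1e-8 within 2000 rounds; the generation-mean
block is diagonal, so the diagonal preconditioner contains the whole fixed
block).  Non-convergence is logged and the solution used as-is rather than
discarding the replicate.  Estimated genetic matrices can sit on the boundary
of the parameter space; their inverses are formed with an eigenvalue floor
of 1e-8 so the equations remain solvable.

### AI-REML

Variance components are estimated once per replicate, at generation 3,
with the pedigree model, and reused for all later evaluations.  The
implementation works in observation space: `V = sum_i theta_i V_i` with
basis matrices for the direct, direct-social and social genetic blocks
(built from A and the pen-mate incidence), pen, litter and residual.
Updates are average-information steps safeguarded by backtracking
step-halving plus projection of the genetic 2x2 block onto the PSD cone
(eigenvalues clipped at 1e-8), which makes the restricted likelihood
non-decreasing by construction.  Convergence: update-vector norm below
1e-7 within 200 iterations; non-converged fits are flagged and used.
Starting values are the simulation truth perturbed multiplicatively by
`Uniform(0.5, 2)` per component (the correlation, not the covariance, is
perturbed so the start stays inside the parameter space).

### Optimum-contribution selection

Each selected dam is mated exactly once; the 600 dams are the highest-EBV
pre-selected females.  Sire contributions `c` (summing to 1/2) maximize
`c' EBV` subject to the group-coancestry cap `x'Ax/2 <= 1 - (1 - dF)^t`
with `dF = 0.01` and `t` counted from the founder cohort.  For a fixed
multiplier the stationarity system is linear; the cap becomes a quadratic
in the inverse multiplier, solved in closed form per active set, with
iterative removal of negative contributions and KKT-based re-admission of
dropped sires (the classic removal heuristic alone can end one active set
short of the optimum; the re-entry step closes that gap, verified against
a sequential-quadratic oracle).  The continuous solution is rounded to
integer mating counts by largest remainder; if rounding breaks the cap the
problem is re-solved at a slightly tighter cap until the realized integer
coancestry satisfies the original one.  If even the minimum-coancestry
point violates the cap (which happens in the first OCS round of strongly
scaled-down programs, where drift through generations 1-3 is faster than
at full scale), the minimum-coancestry solution is used and flagged; the
cap binds from the next round on, which is why the realized inbreeding
*rate* still tracks 1% per generation.

## Randomness and reproducibility

Every stream is keyed by (master seed, replicate, purpose, generation), so
replicates are bit-reproducible.  With the common-random-numbers option the
keys omit the scenario cell for founder, meiosis, trait, grouping and
random-selection streams: scenarios differing only in scheme share
identical populations until the first EBV-dependent decision, enabling
paired comparisons.  `run_replicate` can share the generation-3 REML fit
across such paired runs via an explicit cache.

## Desk-scale choices in the shipped tests

The full factorial (36 + 20 scenarios x 100 replicates on 54k markers) is
far outside a test budget; the suite and the acceptance script instead run:

* analytic panel and expected within-pen relationships — closed form plus
  Monte-Carlo pen draws (the four-family expectation evaluates to 0.0974
  under the no-avoidance quartet construction; the printed full-scale
  value 0.096 likely reflects a slightly different pairing expectation,
  and the check carries that tolerance);
* OCS inbreeding rate — 10 sires x 120 dams, 10 generations, 10
  replicates.  The rate is the regression estimate over cohorts born from
  cap-binding rounds: the realized mean inbreeding of a cohort is the
  mating-pair kinship, which oscillates around the capped group-coancestry
  trajectory (the optimizer can temporarily favor sires less related to
  the dams while within-sex coancestry accumulates), so a short window is
  a noisy estimate of the controlled rate, and the first round of a
  strongly scaled program is excluded because it is infeasible there (the
  cap is not operative);
* REML recovery — 8 sires x 160 dams, two phenotyped generations
  (320 litters, 1920 records), 20 replicates, on the full-length 30-Morgan
  map with 1000 QTL.  The map density matters here: with a toy 6-Morgan,
  200-QTL genome the realized genetic covariances deviate enough from A to
  bias the mis-specified classical model's pen variance well below its
  large-sample value (0.35, which we verified independently by solving the
  expected-score equations of the mis-specified model at this scale);
* generation-4 accuracy/bias and response orderings — 6-8 sire families.
  Here one scale effect cannot be removed within any reasonable budget:
  the generation-3 estimation data are ~1/4 of full-scale size, so the
  sampling noise of the social (co)variance estimates is of the order of
  the parameters themselves and drowns the between-scheme contrasts, a
  regime the full-scale study does not enter.  The accuracy/bias *values*
  are therefore checked in the estimated-components mode (where they
  reproduce), while the TBV-versus-DGE contrasts are checked on
  true-component cells for the social model — cells the full-scale design also includes,
  with the same qualitative pattern — and the classical model uses its own
  estimates, the only mode defined for it.  Two of the directional claims
  are below desk-scale resolution altogether and their checks can fail on
  an unlucky seed: the small response advantage of the social over the
  classical model under selection on direct effects (the full-scale
  accuracy gap is 0.347 vs 0.341), and the slightly larger family/random
  response ratio under pedigree than under genomic relationships (1.103 vs
  1.074 at full scale).  Repeated pilots show their signs flip across
  seeds at feasible replication; the corresponding assertions are kept
  as stated rather than loosened, and a failure there should be read as a
  desk-scale power limit, not a machinery defect.

Passing these tests shows the machinery reproduces the reference design's mechanisms
at reduced scale; it does not certify absolute full-scale values, in
particular genomic accuracies under realistic LD.

## Known limitations

* The exact EVA objective and its dam-selection rule are not public; the
  Lagrangian OCS used here is the canonical algorithm but need not match
  EVA's discretization in edge cases.
* Pedigree relationship matrices are kept dense; fine up to a few tens of
  thousands of animals, wasteful beyond.
* REML basis matrices are dense in the number of records, practical to a
  few thousand records per estimation dataset.
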