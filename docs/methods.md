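# Methods

## Model

`hapclean` treats the observed allele read counts of a mapping population as
the output of a hidden Markov chain over *descendent haplotypes*. A
population of N_o offspring derives from N_f ≥ 2 founders; founders are
either all inbred (each contributes one distinct ancestral chromosome,
K = N_f) or all outbred (two each, K = 2·N_f). The hidden state of offspring
*i* at marker *m* is the ordered ancestor pair h = (h₁, h₂) ∈ {1..K}²;
ordered pairs are kept distinct — (1,2) ≠ (2,1) — because collapsing them
buys nothing and complicates indexing, while the model's probabilities are
symmetric anyway. Founder genotypes are phased pairs x = (x₁, x₂) ∈ {0,1}²,
restricted to homozygotes for inbred founders. The per-marker
founder-genotype *combination* (one phased genotype per founder) is a free,
non-Markovian sequence coupled to the offspring chains through the emission;
combinations in which every founder carries an identical genotype are
excluded (the marker would be monomorphic by design), and a discrete uniform
prior is placed on the rest. Chromosomes are processed independently.

### Emission

Reads at a cell follow binomial kernels per *observable* genotype x′:

* P(y | x′=0) ∝ (1−e_seq)^y_ref · e_seq^y_alt
* P(y | x′=1) ∝ (1−w_m)^y_ref · w_m^y_alt
* P(y | x′=2) ∝ e_seq^y_ref · (1−e_seq)^y_alt

w_m is the probability that a read drawn at a heterozygous site carries the
alternative allele — the *allele read bias* (0.5 when amplification is
even). If any of the three raw kernels is exactly zero (including numerical
underflow at extreme depth, which we deliberately treat the same way), 0.005
is added to all three before normalizing, so no genotype class is ever
impossible. Mismapping then mixes observable into true genotypes with the
3×3 matrix whose rows (true 0, 1, 2) are [1−e_ref, e_ref, 0], [0, 1, 0],
[0, e_alt, 1−e_alt]: extra reads of either allele leave a het observable as
het, while a homozygote with mismapped opposite-allele reads is observed
het. The offspring genotype itself is fully determined by the two inherited
ancestral alleles, so the emission reduces to one entry of the mixed kernel.

Founder emissions multiply per-founder genotype likelihoods (same mixture).
Each founder's likelihood triple is normalized over the three genotype
classes and entries below 0.01 are set to exactly zero; the normalization
scope (three classes, not just the founder's admissible classes) is chosen
so that a supposedly-inbred founder with strongly heterozygous reads prunes
*both* homozygote classes — such a marker then carries no founder
information and the combination distribution falls back to uniform (logged).

### Transition

Lineages switch ancestors as an exchangeable continuous-time Markov chain:
each of the two lineages independently leaves its current ancestor at rate ρ
per Morgan and jumps uniformly to one of the other K−1; simultaneous jumps
have rate zero. So Q has ρ/(K−1) for one-coordinate neighbors and −2ρ on the
diagonal; T_m = exp(Q·d_m) (scipy's Padé scaling-and-squaring) with
d_m = 10⁻⁶(p_m − p_{m−1})·E^d Morgans. The initial distribution is the
stationary law obtained from the leading left eigenvector (uniform 1/K² for
this exchangeable chain). ρ is one interpretable knob in place of
pedigree-specific junction-theory rates: defaults are ρ=1 for single-meiosis
designs (F2 per gamete, outbred F1) and ρ=1.5 for 8-way RILs, where repeated
selfing expands the effective map. Exponentials are cached per distinct
distance (evenly spaced maps need only one).

### Decoding and calling

The integrated Viterbi recursion co-estimates the founder sequence: at each
marker the score of a candidate combination given the previous one is the
previous combination's founder likelihood times, over offspring, the *sum*
over current haplotype states of the best-predecessor path score; the
previous combination is committed per candidate (backpointer ψ^f), and the
offspring trellises follow that choice. Two consequences worth stating
plainly:

* the algorithm is a max/sum hybrid and **not** an exact maximizer of the
  joint probability — on small random instances with weak data the decoded
  sequences can have lower joint probability than the exhaustive optimum
  (on unambiguous data the two coincide, which the tests pin down);
* founder decisions early in a forward pass are made before most of the
  chromosome's evidence has been seen. The standard remedy is the two-round
  scheme: a reverse-direction pass anchored on the forward pass's last-marker
  founder estimate (a point mass at the reverse pass's first marker; no other
  marker is constrained), merged by taking 1-based markers m ≤ floor(M/2)
  from the reverse round and the rest from the forward round.

All dynamic programming is in log space with per-offspring max subtraction
(argmax-invariant). Ties in any argmax are broken uniformly at random from
the run's single seeded generator, so runs are reproducible. Combinations
with zero founder likelihood at a marker are excluded from that marker's
maximization, which bounds cost sharply when founders are well covered.

Genotype posteriors are computed per offspring by scaled forward–backward
conditional on the merged founder sequence; the reported call is the
Viterbi-implied genotype, masked as missing when its posterior is below
P_call.

## Iterative parameter optimization

Cycle 1 runs with w = 0.5 and (e_ref, e_alt) = (0.005, 0.005) everywhere
(cycle count 1 therefore *is* the no-IPO configuration). Each later cycle
re-estimates, from the previous cycle's calls over founders and offspring:

* **Bias** — E^ref is the observed reference-read count per reference allele
  copy (homozygotes contribute two copies, hets one of each); E^alt likewise;
  ŵ = E^alt/(E^ref + E^alt). Markers with an empty copy denominator carry the
  previous value forward. ŵ is clamped to [0.02, 0.98]: a marker at w = 1
  would make heterozygotes unobservable in every later cycle.
* **Mismap** — the fraction of samples called homozygous whose reads alone
  support "heterozygous" with normalized probability > 0.99 (computed with
  the cycle's current w), separately for the two homozygote classes;
  empty denominators carry forward.

Four cycles by default; there is no convergence test (fixed cycle count),
and soft EM-style updates are deliberately out of scope. Flags can freeze
either update (`--fix-bias`, `--fix-mismap`).

Two consistency choices deserve emphasis. First, w means "alternative-read
probability at a het" *everywhere* — emission, simulator, and estimator; an
orientation mismatch between the bias estimate and the emission would make
IPO converge to 1−w. Second, the copy counts weight homozygotes twice and
hets once per allele; this is the only weighting for which E^ref equals the
per-copy read rate under per-copy read generation, i.e. for which ŵ is a
consistent estimator of w.

## Simulator

The simulator emulates the bundled study conditions: 620 evenly spaced
markers on a 50-Mb chromosome with a 2-Morgan map (E^d = 0.04 Morgan/Mb;
1 Mb = 4 cM), founders at 5×, offspring depths on a 0.1–20× grid. Scenarios:
two-way F2 from inbred founders carrying opposite homozygotes at every
marker; outbred F1 (each of four founder chromosomes drawn Bernoulli(½) per
marker, conditioned on segregation); 8-way RILs via a three-round pairwise
funnel and selfing to F6, with founder alleles drawn conditioned on both
alleles being present. Meioses place Poisson(map length) crossovers
uniformly on the genetic map — no interference, consistent with the Poisson
double-crossover analytics in the evaluator.

Reads are generated **per allele copy**: each reference copy contributes
Poisson(depth·(1−w_m)) reads and each alternative copy Poisson(depth·w_m).
At w = 0.5 every cell's total is exactly Poisson(depth); at biased markers a
het read is alternative with probability w_m *and* homozygote totals skew
with the favored allele — the amplification mechanism that generates the
bias in real libraries, and what makes w estimable from homozygote read
totals at all. Mismapping flips each homozygote read to the opposite allele
with the marker's rate. In "nonzero" mode every founder cell receives one
guaranteed true-allele read plus Poisson(depth−1) extras, mimicking
pipelines that drop markers without founder reads; "allowzero" uses plain
per-copy Poisson sampling.

Error-prone markers default to a 30% fraction with true w ~ Beta(0.3, 0.3)
(heavy tails near 0 and 1) and a 10% mismap-prone fraction with rates
~ Uniform(0.05, 0.3). These knobs stand in for an empirical bias profile;
real panels differ in at least: spatial clustering of error-prone markers,
marker-density variation from restriction-site layout, depth correlation
between samples on a sequencing lane, and ascertainment of the marker panel
itself. Passing closed-loop tests therefore demonstrates correctness of the
machinery under the stated generative model, not performance guarantees on
any particular real library.

## Evaluation

Per-offspring correct/miscall/missing call fractions (which partition to 1)
and accuracy = correct/(correct+miscall). For data without truth, the
masked-call concordance protocol: naive read-based calls (0/2 when only one
allele observed, 1 when both, missing at zero reads) define per-marker
missing rate and minor allele frequency; calls supported by strictly more
than 6 reads at markers with missing rate < 0.20 and MAF > 0.40 have their
reads zeroed, estimation is re-run, and concordance is the fraction of
masked cells whose estimate matches the pre-mask naive call. Cells the
estimator leaves missing count as discordant and are also reported
separately. Recombination breakpoints are midpoints between adjacent
nonmissing markers with different genotypes; segments (chromosome ends
included) are tabulated in 0–1 and 1–2 Mb bins, with heterozygous segments
flanked by identical homozygotes counted as double crossovers. Segregation
distortion per marker is the 1:2:1 chi-square divided by the nonmissing call
count — an effect size invariant to sample size — summed per chromosome.
The analytic check: P(≥2 crossovers in d Morgans) = 1 − e^{−d}(1+d), ≈ 0.078%
for d = 0.04.

## Parameters at a glance

| parameter | meaning | default | notes |
|---|---|---|---|
| e_seq | global sequencing-error rate | 0.0025 | typical short-read substitution rate; user-overridable |
| E^d | Morgans per Mb | 0.04 | "1 Mb = 4 cM"; used for d_m |
| P_call | posterior call threshold | 0.9 | below → missing |
| w_m | alt-read probability at het | 0.5 init | IPO-estimated, clamped [0.02, 0.98] |
| e_ref, e_alt | mismap rates | 0.005 init | IPO-estimated |
| cycles | IPO cycles | 4 | 1 = no IPO |
| ρ | lineage switch rate /Morgan | 1.0 (1.5 RIL) | map-expansion knob |
| quantile | overrepresented-read filter | 0.90 | type-7 quantile per sample per allele; both counts zeroed |

## Numerical and degenerate-input choices

Log-space DP throughout; per-marker, per-offspring max subtraction; the
0.005 emission floor triggers on exact zeros *and* underflow; founder
pruning threshold 0.01 on the 3-class-normalized per-founder triple; markers
where all combinations prune fall back to uniform; empty chromosomes are
no-ops; a single-marker chromosome skips transitions entirely (posterior =
normalized emission mixed with the initial law); all-zero read datasets
decode to an arbitrary admissible sequence whose calls are then masked by
P_call. Missing AD in a VCF is (0,0) — the model's native missing state —
and input GT fields are ignored. Multiallelic records are dropped, not
split. The overrepresented-read filter zeroes *both* counts of an offending
call (reads that abundant are usually paralogous contamination, so the whole
call is suspect); note the operation is not idempotent in the strict sense,
since re-filtering recomputes quantiles over the already-zeroed counts.

## Problem sizes used by the test suite and acceptance script

Closed-loop checks run the full study marker count (620) with 100 offspring
for the headline numbers, and smaller populations (10–60 offspring, 25–400
markers) for unit-level properties; the Viterbi-vs-enumeration comparison
uses ≤3 markers and ≤2 offspring where exhaustive enumeration is feasible;
IPO comparisons average 10 seeded replicates. These sizes are the package's
own choice of test conditions and are stated here so results can be
reproduced exactly.

## Known limitations

* The integrated Viterbi is approximate (see above); reported genotypes are
  additionally protected by the forward–backward posterior mask, which is
  exact given the estimated founder sequence.
* The transition chain is exchangeable and stationary — no inbreeding drift
  along the chromosome, no pedigree-derived junction rates, no X chromosome
  or polyploidy.
* Genotype likelihood fields (PL/GL) are ignored; only AD drives the model.
* The simulator's bias profile is a parameterized surrogate, not an
  empirical distribution from any particular library.
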