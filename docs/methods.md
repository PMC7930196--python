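# Methods

## Data model

A sample is a set of rCRS-relative variant calls (1-based positions in
1..16,569) plus metadata: calibrated age in years BP (present = 1950, so
moderns collected 2000 AD sit at −50 BP), a haplogroup label, and a
macrohaplogroup (M, N, R or L-other, derived from the label's first letter
by a configurable map). Distances are symmetric-difference counts of
variant sets, which makes them symmetric, zero on identity and triangular,
but counts recurrent or parallel hits twice when the same position mutated
independently in both lineages — a known upward-bias source, since
hierarchical mapping of recurrent mutations onto the mtDNA tree is out of
scope here.

### Site exclusions

The default policy removes indel calls inside three homopolymeric /
AC-repeat windows — 303–315, 513–524, 16,180–16,195 (closed intervals
around the classic instability anchors 309, 522 and 16,193) — and **every**
call at the 16,519 hotspot, transitions and transversions alike. Both
choices are configurable; the windows are deliberately explicit rather than
anchor-only so users can widen or narrow them. Exclusion is idempotent and
is applied inside every distance computation, so unfiltered profiles are
safe inputs everywhere.

Deletions spanning several columns are recorded at their first position
with the full deleted string: one mutational event, one call.

## Period analysis

Ancients are binned by age, either at user-supplied half-open boundaries or
into equal-count quantile bins. Each ancient is paired with the modern(s)
sharing the longest haplogroup-label prefix within the same
macrohaplogroup; by default one best match per ancient (ties broken by
sample id for determinism), with an exhaustive cross-pair mode available.
Labels are the only practical equivalence key once tree-aware matching is
declared out of scope; prefix length is a reasonable proxy for
phylogenetic proximity under standard mtDNA nomenclature.

A period's mean age weights each ancient by the number of pairs it
participates in (a plain mean is a switch away); the same weights give the
reported age sd. Per-macrohaplogroup difference means combine into the
pooled mean by pair-count weighting, and homogeneity across groups is
checked with a Welch t-test between the two most divergent groups (group
sizes and variances are far too unequal for the pooled-variance test).

The expected-differences column is a strict-clock extrapolation anchored on
the youngest period: expected_k = (pooled_mean₁ / T₁) · T_k, linear in age.
On the packaged summary table this rule reproduces the printed expected
values for all ten periods to ~0.005 (one cell appears truncated rather
than rounded). One packaged pooled cell (period 4) is inconsistent with its
own group entries by 0.02; the recombination arithmetic is followed, not
the cell.

## Rate estimation

θ = Σd/(nT) per genome per year, θ_site = θ/L. L defaults to the full
16,569; no single L reconciles the per-genome values implied by the pooled
difference table with the headline per-site rates in the packaged rate
table (4.33 × 10⁻⁸ youngest, 1.91 × 10⁻⁸ oldest), so both scales are always
reported and the headline per-site values are treated as fixture constants,
not as quantities this estimator should reproduce from the difference
table. The CI is the exact Garwood interval on the Poisson count Σd,
rescaled — counts are genuinely Poisson under the model, the interval is
parameter-free, and its coverage is verified at 93–97% in the suite. The
modern tips' own age (−50) is not added to T.

The time-dependency regression is unweighted OLS of θ_site on T with a
two-sided slope test. With ten periods and a smoothly decaying rate the
linear fit is deliberately simple; even noiseless, curvature caps |r| well
below 1, which the tests account for.

## Persistence model

2Nₑ (haploid) or 4Nₑ (diploid) generations, times the generation length
(default 25 yr). The genome mutation-success rate λ = 1.947 × 10⁻⁴/yr is a
configured constant kept verbatim for reproducibility: dividing it by the
mean of the two germline per-site rates implies ~12,200 sites, which
matches no standard mtDNA partition, so the package exposes the transparent
alternative `genome_rate()` (mean site rate × L = 2.64 × 10⁻⁴ at the full
length) and lets the user choose. Poisson probabilities use the exact pmf.

## Rho dating

ρ is the mean root-to-tip count over a clade's tips; σ = √(ρ/n), the
star-genealogy standard error, exact when tips are independent Poisson
draws and an underestimate on structured trees (no trees are built here, so
the tree-partitioned variance is unavailable by design — a documented
limitation). Age = ρ × years-per-mutation; the two packaged clocks are
3624 yr (corrected modern calibration) and 2454 yr (mean ancient-DNA
calibration), so ages under the two clocks always sit in the fixed ratio
1.477. Root haplotypes are inputs; ancestral-state inference is out of
scope.

Most-divergent selection first drops counts above the Tukey fence
Q3 + 1.5·IQR ("clear outsiders" — contamination, misassigned lineages),
then keeps either the tips at the remaining maximum (`max`) or at/above the
remaining 75th percentile (`upper_quartile`). The quartile mode is the
practical choice: the maximum of n Poisson draws overshoots the mean by an
extreme-value bias, while the top-quartile mean partially cancels the
shortening caused by persistent and late-branching lineages.

## Synthetic generator

The generator's defaults are the study conditions: L = 16,569;
μ = 1.6 × 10⁻⁸/site/yr (midpoint of the recent germline estimates); 25-yr
generations; female effective size 5,000 through prehistory growing
exponentially to 50,000 over the last two millennia; sampling tiers from
−50 BP to 45,000 BP.

**Genealogy mode** emits one ancestral profile of age T and modern tips:
with probability `persistent_fraction` a tip is an exact unmutated copy of
the ancestor; otherwise it branches off the persistent ancestral line at
time b and carries K ~ Poisson(μ·L·b) private substitutions at fresh,
previously unused positions (finite sites with collision avoidance, so
pairwise counts are exact). Branch times are either all T (`star`) — the
configuration under which the θ estimator is provably unbiased and its CI
coverage is checked — or Uniform(0, T) (`uniform`), the persistent-ancestor
scenario in which lineages sprout from the ancestor throughout its
lifetime. The uniform mode is what makes plain ρ dating underestimate T
(expected ρ ≈ (1−p)·μLT/2) and is used for the shortening-correction
demonstrations; with branch times fixed at T the shortening reduces to the
persistent fraction alone and top-quartile selection would overcorrect at
low mutation supply.

**Coalescent mode** draws a serial-sample haploid genealogy with msprime
under the piecewise-exponential demography (sizes interpolated
exponentially between breakpoints, constant beyond the oldest), then
scatters mutations on branches as Poisson(branch-years × μ × L); each event
picks a uniform position and a uniform non-reference base, and a tip's
state is the last event per position on its root-to-tip path, so recurrent
hits collapse — a slight undercount mirroring recurrent mutation in real
data. Child subtrees of the root become labelled clades (haplogroup
stand-ins cycling through M/N/R prefixes) whose root haplotypes go into the
truth record. Mutations are substitutions only: the analyses exclude
indels, heteroplasmy, sequencing error and ancient-DNA damage are not
modelled, and there is no selection or recombination. Passing tests on this
generator therefore demonstrates the estimators' behaviour under clean
neutral serial-coalescent data, not robustness to damage, contamination or
recurrent-hotspot saturation.

Everything is reproducible from (config, seed): one `numpy` Generator
drives all draws and seeds msprime, and written fixtures (aligned FASTA,
metadata CSV, clade-roots table, truth JSON with seed and config hash) are
byte-identical across runs.

## Problem sizes in the test suite

The stochastic guarantees run at sizes chosen to make the checks sharp but
quick: 200 genealogy replicates of 50 tips for CI recovery, 100 coalescent
replicates of 60 tips for the recent-vs-old rate comparison, 200 replicates
of 50 tips for the shortening correction, 2,000 Poisson draws for CI
coverage, 1,000 Welch replicates for the type-I error, and 4,000 two-tip
coalescent replicates against the closed-form E[d] = 2μL·Nₑ·g. The whole
suite completes in well under a minute.

## Known limitations

Raw symmetric-difference counting double-counts recurrent/parallel
mutations; haplogroup-prefix matching is a label heuristic, not a tree
distance; σ = √(ρ/n) understates uncertainty on structured clades; the
packaged reference is a synthetic coordinate stand-in, so packaged fixtures
cannot be compared base-by-base against real rCRS-aligned data (variant
tables, which carry their own ref alleles, interoperate fine).
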