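# Methods

## The inference problem

Two hybridizing bear species, one admixed island population. Three
observations must be explained jointly: (1) polar bears are genetically
homogeneous (pairs differ at ~4 sites per 10 kb) and show no excess
derived-allele sharing with brown bears; (2) the ABC Islands brown bear
shares excess derived alleles with every polar bear, weakly on autosomes
(D ≈ 0.016) and strongly on the X (D ≈ 0.22, ~6.5% ancestry); (3) all ABC
brown bears carry the polar-bear mtDNA haplotype. The package implements
the three instruments that resolve this: the D-statistic machinery (who is
admixed, and how much, per genomic compartment), the fragment-replacement
simulation (in which direction), and the demographic models (by what kind
of gene flow). Everything runs on synthetic genomes whose statistical
structure is calibrated to the bear panel, so the full chain is testable
without the original reads.

## Synthetic genome generator

Each scaffold is simulated as one multispecies coalescent (msprime,
`ploidy=1`: one composite haplotype per individual, matching the
pseudo-haploid data model) with binary (0/1) mutations and within-scaffold
recombination; scaffolds are independent.

**Calibration.** Targets are per-site expected distances: within-taxon
diversity and a clock-like between-taxon matrix. All internal (ancestral)
populations share one size `NA` (haploid scale; pairwise coalescence rate
1/N). Then for lineages in different species E[T] = t_split + NA exactly,
so split times are `t = d/(2μ) − NA`. Terminal sizes solve

    E[T_within] = N (1 − e^{−t/N}) + NA e^{−t/N}

numerically (Brent), where the second term is the probability the pair
fails to coalesce before its species' split — the incomplete-lineage-
sorting mass that later produces ABBA/BABA-informative sites. With μ =
1e-8 per site per generation and NA = 80,000 the bear preset gives
t(brown,polar) = 40,000 generations, t(black) = 120,000, t(panda) ≈
1.12 M, polar N ≈ 15,300, brown N ≈ 97,900; a polar pair escapes its
species branch 5.7% of the time. Expected distances are exact in
expectation for any recombination rate; direct simulation recovers the
scaled-ratio matrix within a few percent at 20 Mb.

**Defaults and units.** Mutation rate 1e-8 /site/generation (a scaling
choice; only products μ·t and μ·N matter). Within-scaffold recombination
defaults to 5e-9 /bp/generation, dropped to 2e-9 when the deep outgroup is
sampled (its long root branch makes dense recombination expensive) and
raised in the diversity-preset runs (polar 5e-8, brown 2e-8) where a
single 50-Mb realization must estimate the preset mean to ±0.2/10 kb —
higher r speeds genealogy turnover and shrinks the genealogical variance
of the mean without moving it. The scaled test genome is 20 × 5 Mb
autosomes + 3 × 2 Mb X scaffolds; direction-test runs use 12 × 2 Mb X
scaffolds (the real X complement is 12 scaffolds, ~74 Mb; keeping the
scaffold count and scaling the length preserves the window-count
resolution the verdict needs). A full-scale layout exists but is not run
by default.

**What the generator does and does not emulate.** It reproduces marginal
site-pattern frequencies, realistic window-to-window genealogical variance
(we deliberately simulate linked genealogies within scaffolds rather than
independent sites: the direction test's baseline spread and the D-decay
profiles need linkage), and tract-structured admixture. It does not model
mutation-spectrum detail, indels, sequencing error, postmortem damage, or
X-specific effective-size scaling in the *neutral* panel (the ¾ factor
enters only in the demographic models, where it matters for the ratio
bound). Passing tests therefore validate the statistical machinery, not
robustness to real-data artifacts.

**Pulses.** A pulse places `n = round(f·L/ℓ)` tracts (half-up rounding)
of length ℓ uniformly over the class-restricted genome, overlaps
permitted, truncated at scaffold ends; the realized unique fraction
(expectation `1 − (1 − ℓ/L)^n ≈ 1 − e^{−f}`) is reported. `f ≥ 1` is
special-cased as whole-scaffold replacement. The haploid `apply_pulse`
copies donor calls verbatim; the diploid-minded `simulate_replacement`
follows the zygosity rule: sites covered by one tract are heterozygous
(donor allele with probability ½ per site, the pseudo-haploid pick), sites
under overlapping tracts are homozygously introgressed. Tract length
converts from a gene-flow time as `ℓ = 1/(r · t/g)` (r = 1e-8, g = 10 y:
50 kya → 20 kb).

## D-statistics

A site is informative for an ordered quartet (I1, I2, I3, O) when all four
are called, at most two alleles segregate, and the derived allele (≠ O's
call) is carried by exactly {I2, I3} (ABBA) or {I1, I3} (BABA). Standard
errors use a weighted block jackknife over 5-Mb genome-coordinate blocks
(weights = per-block informative counts; pseudovalue form `τ_j = h_j θ̂ −
(h_j − 1) θ̂_{−j}`, `h_j = n/m_j`), which reduces to the classic delete-one
formula at equal weights; X and autosomes are always jackknifed
separately. Block size is a convention (the source analysis does not state
its choice); 5 Mb comfortably exceeds both tract length and genealogical
correlation scales. f̂ uses the ratio of ABBA−BABA excesses with the test
individual replaced by a second donor-population individual; its SE is a
delete-one block jackknife of the ratio. A transversions-only mode is not
needed for the binary generator and is out of scope here.

## Direction test

For a candidate direction donor→recipient, 100 replicates (default)
replace f = 6.5% of the recipient's X in 20-kb tracts and re-window the
(recipient, conspecific) pair — the pair maximizing informative sites.
The statistic is the count of high-diversity windows (>10 differences/
10 kb). The default verdict is effect-size based: "inconsistent" when the
replicate median exceeds the observed count by more than 10%. The margin
exists because of a structural double count: when the tested direction is
the *true* one, the observed pair already contains the admixture, and
replicates stack simulated tracts on top of real ones, inflating their
counts by a few windows (~1% here); a pure rank test at fixed α would flag
that inflation rather than the direction, while the wrong direction
produces a 25–40% excess. The mid-rank empirical p and an optional α-rule
are reported alongside, plus a total-variation distance between observed
and pooled replicate rate histograms as a diagnostic.

## Sex-bias models

**Recursion.** Expected donor-allele frequency per generation with male
immigrant fraction `m` and female fraction `R·m` (immigrant ancestry 0):
autosomes average the two parental pools; a female's X averages the
maternal-X and paternal-X pools, a male's X is maternal only; mtDNA
follows females, Y follows males. With R = 0: `p_auto(t) = (1 − m/2)^t`,
mtDNA stays at 1 forever, and the X:autosome ratio increases without
bound — the population-conversion signature. The default rate m = 0.0083
is the documented island immigration figure.

**Forward simulator.** Two-sex Wright–Fisher, N individuals (half each
sex), immigration applied to the adult pools before random mating. Two
representations: unlinked point loci (vectorized; used for trajectory
checks at N = 2000) and recombining ancestry tracts per scaffold (males
hemizygous on X; breakpoint lists per haplotype), whose sampled females
can be painted into pseudo-haploid calls using one donor and one
immigrant reference haplotype from the generator — a deliberate
single-reference simplification (islanders carry no within-species
variation beyond the mosaic), adequate for D-statistic checks. Mean
trajectories agree with the recursion within ~1.6% (10 × N = 2000 runs);
single runs drift a few percent.

**Pulse model.** Four populations (mainland recipient, island recipient,
donor, outgroup) with a mass-migration pulse donor→island at `t_gf`;
defaults anchor to the generator's calibration (N3 = 15,000, N12 =
60,000, N123 = 80,000; t_p2 = 20,000, t_p3 = 40,000, t_out = 120,000
generations; f = 0.065). D is computed in the low-mutation (branch-length)
limit: P(ABBA) ∝ expected length of the branch subtending {island, donor},
P(BABA) ∝ {mainland, donor}. The default engine is a vectorized
replicate-genealogy sampler written for this model (it exploits the fact
that before `t_p3` only one specific pair can coalesce, and that the
post-`t_p3` pools share one size, leaving exponential races and uniform
pair choices); msprime runs the identical demography as an independent
cross-check in the tests. The X differs by the ¾ effective-size factor
and, for female-mediated pulses, an admixture fraction inflated by 4/3
(females carry 2 of the population's average 1.5 X copies). Across a grid
of joint size scalings {0.25, 0.5, 1, 2}× and pulse times across
(0, t_p2), the X:autosome D ratio stays below ~2 — far from the observed
~13.75, which the continuous model reaches after ~1,900 generations of
male-only immigration at m = 0.0083. The exact parameter grid behind the
published single-pulse bound is not available; ours spans the scaled
anchors and reproduces the bound's substance (ratio bounded near 2–3 vs
unbounded under continuous migration).

## Calibration

Scaled distances (reference comparison = 1) propagate anchors linearly by
endpoint scaling; a mutation-rate anchor converts the reference's absolute
per-site distance to time via `T = d/(2μ)`. The panda anchor (8–16 Mya)
and the 1e-9 /site/year rate anchor reproduce the published table exactly
on the self-consistent rows (black/brown 1.34–2.67 and 2.00 Mya;
brown/polar 0.80–1.60 and 1.20 Mya). Two printed values do not follow the
arithmetic and are reported as computed rather than forced: the
black/brown-anchored brown/polar lower endpoint (printed 2.43 vs 0.6 ×
3.90 = 2.34) and the rate-anchored polar-population row (printed 0.19 vs
0.1 × 2.00 = 0.20, likely a rounding of scaled 0.097). Display rounding is
two decimals in Mya.

## Numerical and reproducibility choices

All randomness derives from one integer seed via `SeedSequence` streams
keyed by (seed, operation, replicate), so any replicate reproduces
independently; msprime receives derived 31-bit seeds. Windows and blocks
are 0-based half-open genome-coordinate tiles (1-based only in VCF);
windows below 10,000 callable sites of 50,000 are flagged and excluded
from rates (a callability floor the source leaves unstated). Degenerate
inputs fail loudly: empty layouts, unknown samples/taxa, unplaceable
tracts (`f·L < ℓ/2`), fewer than two non-empty jackknife blocks (SE
omitted), non-positive denominators in f̂ (flagged NaN). Pipeline outputs
serialize floats at fixed precision with sorted JSON keys and no
timestamps, so a fixed config + seed is byte-reproducible.

## Problem sizes

Replication runs are desk-scaled: 50 Mb two-sample genomes for the
diversity presets, 6 Mb X complements × 20 seeds for f̂ recovery, 30 Mb ×
20 seeds for the null-D calibration, 24 Mb X × 20 runs × 50 replicates
for the direction asymmetry, 400,000 replicate genealogies per pulse-model
grid point, and N = 2000 × 200 generations × 8 seeds for the forward
decay check. At these sizes the full test suite and the acceptance script
each complete in minutes on one core.

## Known limitations

Pseudo-haploid VCF ingestion assumes biallelic SNVs and full-scaffold
callability unless a mask is attached. The generator's X is not ¾-scaled,
so X-vs-autosome *diversity* contrasts in the neutral panel are flat by
construction (the contrasts of interest are admixture-driven). The
forward tract simulator is pure Python and meant for hundreds, not
thousands, of individuals; the point-locus mode covers large-N checks.
The direction test's 10% verdict margin is a fixed convention calibrated
to the double-counting inflation, not an estimated quantity.
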