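# Methods

## The scientific question

Mutator genotypes (m-fold elevated genomic mutation rate, typically from loss
of a proofreading or repair gene) thrive during adaptation but carry an
elevated deleterious load, and are eventually vulnerable to invasion by
*antimutator* alleles that restore the wild-type rate. The classical
Haldane–Muller argument predicts the antimutator's advantage to be roughly the
excess deleterious rate, (m−1)·u_d, independent of the per-mutation cost s_d.
But different mutators elevate different *spectra* of point mutations
(mutY⁻: G:C→T:A; mutT⁻: A:T→C:G; mismatch-repair⁻: both transitions), and
different spectra produce amino-acid changes of systematically different
severity depending on the genome's codon usage — hence its GC content. This
package implements the two engines needed to study that interaction:

1. a stochastic serial-passage simulator measuring the effective selection
   coefficient s_eff of an antimutator allele invading a mutator population,
   with a spectrum-bias factor κ;
2. a genome scorer that enumerates every codon substitution accessible to a
   mutational spectrum and averages its protein-disruption score (Grantham
   distance, BLOSUM100) across a panel of coding genomes spanning a GC
   gradient.

## Invasion simulator

### Model

A class-based model of strictly asexual bacteria under an LTEE-style serial
transfer: deterministic growth by discrete non-overlapping generations from
the bottleneck size N_b to the threshold N_max, then a random sample of N_b
individuals (defaults N_b = 10⁷, N_max = 10⁹: the 1/100 daily dilution;
recovery takes ≥ 7 generations since ⌈log₂ 100⌉ = 7). Individuals are grouped
by background (mutator/antimutator) and deleterious-mutation count n. Per
generation:

* **growth** — class abundance multiplies by r = 2 − n·s_d (antimutator) or
  r = 2 − κ·n·s_d (mutator), clamped at 0. We store the cost s_d as a
  positive magnitude and subtract it: a fitness cost must reduce growth. κ>1
  means mutator-made mutations are more harmful than antimutator-made ones,
  κ<1 milder. A `kappa_target` switch routes κ to the deleterious effect
  (default), to the lethal rate, or to both; the lethal experiments are run
  as a separate arm with κ·m·u_l in the mutator background.
* **mutation** — new deleterious hits per individual are Poisson with mean
  m·u_d (mutator) or u_d (antimutator); a class-n individual acquiring k hits
  moves to class n+k. Multi-hit moves matter because m·u_d reaches 1.6 at
  the extreme grid corner. Implementation draws, for every (class, k), a
  Poisson number of movers with mean a_n·pmf_k, truncating the kernel where
  the tail mass drops below 10⁻¹²; expected abundance is conserved exactly
  and the draw is vectorised over the whole class array.
* **lethality** — per-capita Poisson removal at rate u_l (antimutator) or
  m·u_l, optionally κ-scaled (mutator).
* **bottleneck** — one multinomial draw of N_b individuals over all classes
  (hypergeometric correction is negligible at a 100-fold dilution);
  abundances are real-valued during growth and integerised only here and at
  allele introduction, so drift enters through sampling, as it should in a
  model with deterministic reproduction.

Class counts are truncated at λ + 10√λ + 20 (λ = deterministic balance mean);
overflow pools in the top class. With linear (not geometric) fitness in n,
the per-mutation selection intensity per generation is s_d/2 relative to the
baseline growth of 2, so the balance mean is ≈ 2·m·u_d/(κ·s_d) — the package
computes the exact stationary distribution of its own deterministic recursion
rather than relying on the Poisson(U/s) approximation, and the test suite
checks it against an independently coded recursion.

### Invasion protocol

An invasion starts with one antimutator individual inside a mutator resident
of size N_b and ends at fixation, loss, or a generation cap (censored). Two
choices here are substantive:

* **Starting state.** By default the resident starts mutation-free and
  accumulates its load during the run (`naive_resident`), as in a serial
  transfer founded from a clone. The alternative — a resident pre-equilibrated
  at mutation–selection balance (`equilibrate`, deterministic stationary
  initialisation plus stochastic burn-in cycles) — is available, but note a
  structural fact of asexual genetics: an antimutator arising on a *random*
  background of a balanced resident has zero expected advantage, because it
  can never shed its inherited load while the balanced resident no longer
  declines. Invasions in that variant are driven purely by lucky low-load
  founders. The Haldane–Muller-scale advantages that motivate this analysis
  (and all published serial-passage treatments of it) correspond to the
  default protocol.
* **Founder pricing.** The founder is a randomly sampled resident and keeps
  its deleterious load n₀; seeding at n=0 would fabricate an instant
  advantage. Its inherited mutations were generated under the mutator
  spectrum, so they keep their κ-scaled cost (a fixed growth offset of the
  lineage); only mutations acquired after the switch cost s_d. A repair
  allele does not change the effects of mutations already present.

### s_eff estimation

Per replicate, s_eff is the least-squares slope of ln(p/q) against
generation (p, q = antimutator and mutator frequencies) over the window
where the antimutator count is ≥ 10 and its frequency ≤ 0.9 — the two-point
evaluation of the endpoint formula log((p_g/q_g)/(p₀/q₀))/g is the special
case of this regression, which is more robust to endpoint noise. The
reported value is the mean over replicates that reach frequency 0.1;
replicates lost earlier are counted but excluded from the mean (conditioning
the *start* of the window on reaching a threshold leaves the subsequent
slope unbiased; the estimator protocol is recorded in the output metadata).
Fold change of s_eff between κ endpoints is the ratio
s_eff(κ=4)/s_eff(κ=0.25), flagged undefined if either endpoint mean is ≤ 0.

Per-replicate RNG streams derive from (base seed, cell index, replicate
index) via `SeedSequence`, making sweep cells reproducible and independent
of execution order or chunking.

### Problem sizes

Full-scale runs (N_b = 10⁷) are supported but expensive; the package's own
analyses, tests and the acceptance script use a reduced demography
(N_b = 10³, N_max = 10⁵, same 1/100 dilution) with 200 replicates per
condition — the same replicate count as the full-scale protocol, which keeps the windowed
estimator defined in weak-selection cells where fewer replicates can leave
no qualifying trajectory. The Haldane–Muller anchor ((m−1)·u_d at m=30,
s_d=0.064), κ-monotonicity at m=1000, fold-change ordering across u_d, and
the neutral control (fixation fraction 1/N_b at u_d=u_l=0) are all verified
at this demography; a demographic-sensitivity preset exposes N_b and N_max
as sweep axes.

## Genome scoring

For every codon of every coding sequence, each directed nucleotide change of
a spectrum is applied at each position; outcomes are classified synonymous /
missense / nonsense / stop-affected. Missense changes are scored with the
Grantham physicochemical distance (higher = more disruptive) or BLOSUM100
log-odds (lower = less conservative); the per-genome mean is over *all
spectrum-consistent missense substitutions across all included codons*
(codon-occurrence-weighted, not per-gene means of means). Synonymous changes
are excluded from the mean — a distance matrix has no meaningful diagonal,
and mixing a zero diagonal (Grantham) with a positive one (BLOSUM100) would
make the two panels incomparable — as are nonsense and stop-affected
changes, which neither matrix defines. Terminal stop codons are never
enumerated; internal stops are flagged and skipped; codons containing
ambiguity codes (N, R, Y, …) are excluded and counted. Translation uses the
bacterial code (table 11) with start codons treated as ordinary codons:
disruption concerns the encoded residue, not initiation. Since there are
only 64 codons, genome scoring reduces to codon counting against a
precomputed per-codon table.

Spectra are strand-symmetric pairs applied on the coding strand (G:C→T:A ⇒
{G→T, C→A}); complementing every directed change leaves each built-in
spectrum invariant. GC content is computed over the analysed CDS nucleotides
(ambiguous symbols excluded from numerator and denominator); whether one
uses CDS-only or whole-genome GC only shifts the x-axis, and only CDSs are
loaded here. Default analyses restrict to COG categories H, J, M (enriched
in essential genes, where non-synonymous changes are most likely harmful);
the qualitative spectrum ordering is unchanged on whole genomes.

The Grantham matrix is bundled as the published 1974 table (AAindex-style
triangular entry). Every pair was verified against the original
composition/polarity/volume formula (ρ ≈ 50.79): 189/190 agree within
rounding; the printed Asp–Trp value (181, formula ≈ 191) is kept as
published. BLOSUM100 is bundled in the NCBI square text format; the loader
ignores B/Z/X/* rows and columns and verifies symmetry.

## Synthetic genome panel

The scorer needs coding genomes spanning GC ≈ 0.25–0.70. The generator
emulates how real genomes conform to compositional bias: codon usage is the
stationary outcome of GC-biased mutation pressure opposed by purifying
selection on the encoded residue.

* Each site prefers an amino acid drawn from a typical bacterial proteome
  profile (Leu 10%, Ala 9%, …, Trp/Cys ≈ 1%).
* A codon c at a site preferring a₀ has weight
  θ^(GC₃(c) + γ·GC₁₂(c)) · exp(−cost(a₀ → aa(c))), with γ = 0.25: GC
  pressure acts far more strongly on synonymous third positions than on the
  constrained first/second positions, as in real bacteria where GC3 varies
  much more than GC12.
* Exchange costs come from coarse biochemical classes (aliphatic AVLIM,
  aromatic FWY, polar STNQP, positive KRH, negative DE, special GC): 1.0
  within a class, 4.0 across, plus a 6.0 surcharge for replacing the
  classically low-exchangeability residues W, C, G. These classes are
  deliberately independent of the Grantham/BLOSUM matrices being evaluated.
* θ is solved by bracketed root finding so the expected CDS GC hits the
  target (calibration error < 10⁻⁶ in expectation; realised GC within
  ±0.02 — in practice ±0.003 — at ≥ 10⁵ codons).

This is the simplest mechanism that concentrates the residual G/C of AT-rich
genomes (and residual A/T of GC-rich genomes) in hard-to-replace residues.
A plain neutral tilt θ^GC(codon) (provided as `calibrate_codon_weights`)
controls GC equally well but produces *no* spectrum-by-GC interaction: it
downweights all G/C-containing codons equally, so every spectrum's mean
disruption simply rises with GC. The selection-aware model reproduces the
qualitative pattern seen in real panels: mismatch-repair (transition-only)
least disruptive everywhere; mutY disruption falling and mutT rising with
GC, swapping rank along the gradient, under both matrices.

Genes are ATG + body codons drawn i.i.d. from the calibrated weights + a
uniform stop (TAA/TAG/TGA), so internal stops are impossible; lengths are
Poisson around 300 codons (floor 10); COG labels are drawn from fixed
proportions (H 0.10, J 0.15, M 0.10, other 0.65 — only the presence of
H/J/M matters for the filter path). Everything is byte-reproducible from
the seed.

### What the synthetic panel does and does not show

The panel has realistic GC-dependent codon usage and amino-acid composition,
but no operons, no intergenic DNA, no gene-length or expression-level
structure, no phylogenetic covariance among genomes, and its
selection-vs-bias calibration is a stylised two-parameter cost model.
Passing the qualitative pattern here shows the *scorer* correctly extracts
spectrum-by-composition interactions from codon usage; it does not by itself
validate the magnitudes expected on real genomes. The scorer accepts real
CDS FASTA + COG TSV input unchanged.

## Numerical and design notes

* Population abundances are float64; exact conservation is enforced in the
  mutation step; infinitesimal negative residues from rescaling are clamped.
* The deterministic stationary distribution is cached per (U, cost, cap).
* Spearman rank correlations are used for all orderings vs GC (6-point
  panels; no distributional assumptions).
* Undefined cell means (no qualifying replicate) are reported as NaN with a
  `s_eff_defined` flag, never dropped.
* Known limitations: no beneficial or compensatory mutations, no
  recombination, no physiological cost of fidelity, haploid asexual
  demography only; mismatch-repair mutators' excess indels/recombination
  are not modelled, so their disruption scores are an underestimate by
  construction.
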