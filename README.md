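# mutspectra

Do different bacterial mutators fall to antimutator alleles at different
rates because of *what kinds* of mutations they make? Mutator genotypes
(m-fold elevated mutation rate) carry an inflated deleterious load; the
classical Haldane–Muller expectation gives an invading antimutator (an
allele restoring the wild-type rate) an advantage of roughly

    s_eff ≈ (m − 1) · u_d        (valid when s_d ≫ m·u_d)

independent of the per-mutation cost s_d. But mutator classes elevate
different point-mutation spectra — mutY⁻: G:C→T:A, mutT⁻: A:T→C:G,
mismatch-repair⁻: the two transitions — and the severity of the amino-acid
changes a spectrum can make depends on the genome's codon usage, hence its
GC content. `mutspectra` provides the two computational engines to study
this interaction:

* **`mutspectra.invasion`** — a class-based stochastic simulator of serial
  passage (LTEE-style growth 10⁷ → 10⁹, 1/100 dilution; growth rate
  r = 2 − n·s_d with n accumulated deleterious mutations, Poisson mutation,
  multinomial bottlenecks). A spectrum-bias factor κ makes mutator-made
  mutations milder (κ<1) or harsher (κ>1), applied to the deleterious effect
  size or to the lethal rate. The effective selection coefficient of the
  invading allele is measured from its trajectory as the slope of ln(p/q)
  per generation.
* **`mutspectra.scoring`** — genome-wide enumeration of every codon
  substitution accessible to a spectrum, scored for protein disruption with
  the Grantham physicochemical distance and BLOSUM100 (both bundled),
  stratified by COG category and genome GC.
* **`mutspectra.synthetic`** — a generator of coding-genome panels spanning
  GC 0.25–0.70 with selection-realistic codon usage, so the scoring
  analyses run without any downloads.
* **`mutspectra.experiments`** — parameter-grid orchestration (s_eff
  surfaces over m, s_d, κ, u_d, u_l; fold changes; GC-panel scoring) with
  per-cell reproducible seeding.

The numbered scripts under `analysis/` run the package's standard analyses
and write tidy tables under `results/`; `docs/methods.md` documents the
model, estimator, and generator in detail.

## Worked example

Invasions at a reduced demography (bottleneck 10³, threshold 10⁵), m = 300,
s_d = 0.064, u_d = 2×10⁻⁴:

```bash
$ mutspectra simulate --m 300 --s-d 0.064 --u-d 2e-4 \
    --n-bottleneck 1000 --n-max 100000 --replicates 50 --seed 0 --out runs/m300
mean s_eff = 0.05396 over 21 qualifying replicates (fixation fraction 0.420)
```

The antimutator advantage ≈ 0.054 sits close to the Haldane–Muller value
(m−1)·u_d ≈ 0.06 — s_d = 0.064 ≫ m·u_d = 0.06 puts this run at the edge of
the regime where the advantage depends only on the rate excess. Over half
the replicates still lose the allele to drift (it starts as a single copy);
`runs/m300/trajectories.tsv` holds every trajectory and `summary.json` the
estimator protocol.

Scoring the mutational spectra across the synthetic GC panel:

```bash
$ python analysis/04_genome_disruption.py
mean Grantham score by genome GC (H/J/M genes):
spectrum      MMR   mutT   mutY  unbiased
gc_content
0.250796    72.79  76.52  93.35     76.80
0.349078    73.79  80.23  89.46     78.04
0.448954    74.44  83.16  87.85     78.86
0.549253    75.00  86.60  87.28     79.87
0.647466    75.61  91.11  87.71     81.08
0.695559    76.00  93.98  88.68     82.08

Spearman rho of disruption vs GC (Grantham):
spectrum  spearman_rho_vs_gc
    mutY                -0.6
    mutT                 1.0
     MMR                 1.0
unbiased                 1.0
```

Read the table row-wise: in the AT-richest genome (GC 0.25) the mutY⁻
spectrum makes by far the most disruptive changes (93.4 vs 76.5 for mutT⁻),
because the few remaining G:C sites sit in hard-to-replace residues; in the
GC-richest genome the ranking flips (94.0 for mutT⁻ vs 88.7). The
transition-only mismatch-repair spectrum is the most conservative
everywhere. The same conclusions hold under BLOSUM100 once its direction
(higher = more conservative) is inverted.

Other entry points: `mutspectra sweep --preset kappa-grid --scale scaled`,
`mutspectra make-panel`, `mutspectra score-genome --fasta your_cds.fasta
--annot your_cogs.tsv --spectrum mutY --cogs H,J,M`.

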