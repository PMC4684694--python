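# polarix

Consequence analysis of exonic SNPs polarized by ancestral state.

Rare variants are usually treated as one class, but a rare minor allele can
be either the evolutionarily *derived* allele (new, not yet purged by
selection) or the *ancestral* one (an old allele whose derived partner has
nearly fixed). `polarix` implements the full analysis around that split:
it filters and polarizes a VCF cohort into minor-allele-frequency (MAF) and
derived-allele-frequency (DAF) coordinates, quantifies each variant's
consequence at three biological levels — protein (Grantham chemical
distance, |ΔH| hydrophobicity change, BLOSUM62), mRNA secondary structure
(Boltzmann-ensemble relative entropy, |ΔΔG_MFE|, base-pair-probability
distance), and translation (codon-optimality change |ΔO_codon|) — and
contrasts the cohort against random point mutations matched to the
observed transition/transversion ratio per transcript region. A synthetic
cohort generator plants the expected population-genetic structure
(effect-dependent DAF, expression-dependent codon bias, age–frequency
coupling with injected outliers) so every claim the statistics make can be
verified against ground truth.

## The model in brief

* **Polarization.** For a biallelic site with ancestral allele annotated
  (INFO `AA=`), DAF = frequency of the non-ancestral allele and
  MAF = min(DAF, 1 − DAF). Any score monotone decreasing in DAF is
  therefore *negatively* correlated with MAF on the derived-minor stratum
  (MAF = DAF) and *positively* on the ancestral-minor stratum
  (MAF = 1 − DAF) — the sign flip is an identity, and the pipeline
  recovers it from data.
* **RNA structure.** Secondary structures are nested pair sets with a
  minimum hairpin loop of 3; the energy is pair-additive (GC/CG −3,
  AU/UA −2, GU/UG −1, any other pair +8, reduced units). For a 150-nt
  window around a SNP the package computes, exactly, the partition
  function Z, the MFE gap between alleles, the base-pair probability
  matrices and their Euclidean distance, and the Kullback–Leibler
  divergence D(wt‖mut) between the two Boltzmann ensembles via the closed
  form `D = ln(Z_mut/Z_wt) + β Σ p_wt(i,j) [e_mut(i,j) − e_wt(i,j)]`
  (sum over pairs touching the mutated site). An exhaustive-enumeration
  oracle validates every quantity on short windows.
* **Codon optimality.** O_c is the odds ratio of codon usage within its
  synonymous family between the top-20% and bottom-20% expressed genes
  (geometric-mean expression across tissues; Haldane–Anscombe ½
  pseudocounts); |ΔO_codon| = |O_wt − O_mut| for a synonymous change.
* **Statistics.** DAF-binned means ± SEM (8 bins, the top two being
  (0.99, 0.999] and (0.999, 1)), right-continuous ECDFs, Spearman
  correlations per stratum, Wilcoxon rank-sum and Welch t contrasts, and
  age×DAF corner classification (quick-running: age < 300 ky and
  DAF > 0.8; slow-running: age > 700 ky and DAF < 0.2).

## Worked example

`examples/02_sign_flip.py` simulates 20,000 SNPs whose DAF follows
Beta(α₀, α₀ + s·x) with planted effect x ~ Exp(1), attaches a
conservation-like score (5 − 3·DAF + noise), polarizes the cohort and
prints the stratified correlations:

```
Spearman correlation of the conservation-like score:
        stratum     n    rho         p
  derived_minor 17528  -0.27  9.9e-291
ancestral_minor  2472  0.437 9.27e-116
     pooled_daf 20000 -0.464         0
```

The same score correlates with MAF in opposite directions on the two
strata while the pooled DAF correlation is monotone — which is why DAF,
not MAF, predicts variant consequence. The other scripts in `examples/`
cover cohort simulation and filtering, per-variant structure scoring with
the enumeration cross-check (`D("GAAAC"→"GAAAA") = 7.4301` by both
routes), codon-optimality recovery, and the ts/tv-matched background plus
age×DAF corners.

A thin CLI chains the stages for shell use:

```bash
polarix simulate --seed 7 --out sim/
polarix score --vcf sim/snps.vcf --fasta sim/transcripts.fasta \
    --regions sim/regions.tsv --expression sim/expression.tsv --out scored.tsv
polarix report --fasta sim/transcripts.fasta --regions sim/regions.tsv \
    --scored scored.tsv --out report/
```

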