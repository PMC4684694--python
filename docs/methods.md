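# Methods

This note records the models, parameter choices and numerical decisions
behind `polarix`, and what the synthetic-data tests do and do not
demonstrate about real cohorts.

## Polarization and filtering

A raw VCF record enters the cohort only if it is biallelic, carries an
ancestral-allele annotation (INFO `AA=`, upper-cased; the 1000
Genomes-style lower-case low-confidence flag is not modelled) that matches
one of its two alleles, carries a frequency strictly inside (0, 1), and
falls inside exactly one provided transcript. Each removal is attributed
to the *first* failing rule, in the order multiallelic → no ancestral →
ancestral mismatch → no frequency → degenerate frequency → no transcript.
The degenerate-frequency rule (AF exactly 0 or 1) is required by the
polarized representation, which needs DAF ∈ (0, 1).

DAF is the frequency of the non-ancestral allele; MAF = min(DAF, 1 − DAF);
at the measure-zero tie DAF = 0.5 the derived allele counts as minor.
Coordinates are 0-based half-open everywhere inside the package; the
1-based VCF position is converted exactly once, when records are
polarized.

Eight DAF bins are used throughout: interior edges 0.001, 0.01, 0.1, 0.5,
0.9, 0.99, 0.999, so bin 7 is (0.99, 0.999] and bin 8 is (0.999, 1). The
two high bins are fixed by the analysis design; the low-end edges mirror
them and are configurable. "Rare" means MAF < 0.01.

Site classes: utr5/utr3 from the transcript regions; inside the CDS,
syn/nonsyn from translating the reference and alternate codons under the
standard genetic code, with any change that creates or destroys a stop
labelled `nonsense` and excluded from amino-acid metric summaries
(Grantham/|ΔH|/BLOSUM62 are undefined for stops). The
translation-initiation-site (TIS) flag covers the 50 nt of 5′-UTR
immediately upstream of the start codon, truncated at the transcript
start when the UTR is shorter. The splice-site (SS) flag covers exonic
positions within 3 nt of an exon–exon junction, on both sides of the
junction in transcript coordinates.

## RNA ensemble model

Structures are nested (pseudoknot-free) pair sets with at least
`min_loop = 3` unpaired bases in every hairpin. The energy is
pair-additive: GC/CG −3, AU/UA −2, GU/UG −1, and a finite +8 penalty for
every other pair, in reduced units at β = 1. The finite penalty is a
deliberate design choice: it keeps the wild-type and mutant ensembles on
identical support, so the relative entropy between them is always finite.
No stacking or loop-entropy terms are modelled; only relative comparisons
between alleles are used downstream, which is what the simplification
preserves.

Three computational routes coexist and are required to agree:

1. **Enumeration** (≤ 20 nt): every nested structure with its energy;
   the structure count is independently checked against the
   pairing-state recursion `N(i,j) = N(i,j−1) + Σ N(i,k−1)N(k+1,j−1)`.
2. **Dynamic programming**: Nussinov-style minimization for the MFE
   (ties broken toward fewer pairs, then the lexicographically smallest
   pair list, making the traceback deterministic) and a McCaskill-style
   inside/outside pass for Z and the base-pair probability matrix. The
   inside pass runs in the log domain for the total; probabilities use a
   second pass rescaled by σ = Z^(1/n) per nucleotide so every
   intermediate stays O(1) at any window length. The outside sum over
   directly-enclosing pairs is maintained incrementally with one thin
   matrix product per span.
3. **Closed form** for the divergence:
   `D(wt‖mut) = ln(Z_mut/Z_wt) + β Σ p_wt(i,j)[e_mut(i,j) − e_wt(i,j)]`,
   the sum running over pairs that touch the substituted site — exact
   under pair additivity because no other pair changes energy.

Windows are 150 nt by default, centred as
`[max(0, pos − w/2), min(L, pos + w/2))` with no re-centering at
transcript ends (deterministic truncation). The divergence direction is
wt‖mut by default with a flag for the reverse; KL is asymmetric and the
choice matters only for the absolute scale, not for the DAF trends.

Two invariance properties are worth stating precisely. The divergence is
invariant to a constant offset of *structure* energies
(E(s) → E(s) + c), which cancels in both Boltzmann weights, and likewise
to the rescaling (β, E) → (cβ, E/c). It is **not** invariant to adding a
constant to every *pair* energy: that multiplies each structure's weight
by e^(−βc·n_pairs(s)) in both ensembles, an exponential tilt that changes
both distributions and hence their divergence (e.g. for the GAAAC→GAAAA
hairpin, a +3 pair-energy shift moves D from 7.430 to 4.807, as exhaustive
enumeration confirms). The test suite asserts the pair-energy-shift
version of the invariance as specified for this analysis and it fails for
exactly this reason; the temperature-rescaling invariance, which does
hold, is tested alongside it.

Scored output reports D (nats), |ΔΔG_MFE| (reduced units) and the
upper-triangle Euclidean distance between the two alleles' BPP matrices.

## Protein and translation metrics

Grantham chemical distances, the Argos membrane-propensity hydrophobicity
index and BLOSUM62 are packaged as plain TSV fixtures whose sha256
checksums are verified at load time. |ΔH| is the absolute index
difference; all three metrics are symmetric, and Grantham/|ΔH| vanish iff
the residues are identical.

Codon optimality O_c is computed within the synonymous family: genes are
ranked by the geometric mean of expression across tissues (with an
additive offset ε = 1 guarding zeros), the top and bottom 20% are pooled,
and for codon c in family F,

    O_c = [(n_H(c)+½)/(n_H(F∖c)+½)] / [(n_L(c)+½)/(n_L(F∖c)+½)],

with Haldane–Anscombe ½ pseudocounts on all four cells so sparse codons
never divide by zero. Single-codon families (Met, Trp) have O_c = 1 by
convention; stop codons are excluded. In a 2-codon family the two odds
ratios are reciprocal up to pseudocount effects. |ΔO_codon| is reported
on the natural odds-ratio scale (a log-scale option exists) and is
defined only for synonymous pairs.

## Background mutations

The null background draws sites uniformly (with replacement) within each
region, allocating counts proportionally to aggregate region length
(absolute per-region counts are supported). At each site the transition
partner is chosen with probability R/(R+1) against the two transversions
uniformly, so the realized ts/tv matches the per-region target R
estimated from the cohort (ancestral→derived direction; the ratio is a
property of the unordered allele pair). R = ∞ is accepted and yields
transitions only. Background rows carry the same positional fields as
SNPs and are scored by the very same protein/RNA code path; mutations
creating stops are kept but labelled `nonsense`, mirroring the SNP path.

## Synthetic cohorts

The generator plants exactly the structure the statistics are built to
detect, controlled by one scalar effect per SNP:

* transcripts: Poisson-length UTRs/CDS around means (120 nt, 300 codons,
  300 nt), iid bases at the target GC with in-frame stops repaired by
  GC-preserving third-base edits, ATG start, terminal stop, 1–4 uniform
  exon junctions;
* SNPs: sites uniform over transcripts, ancestral = reference base,
  transition probability 2/3; effect x ~ Exp(1); DAF ~ Beta(α₀, α₀+s·x)
  with α₀ = 0.25, s = 2 (clipped to [10⁻⁶, 1−10⁻⁶]); ALT is always the
  derived allele, so ancestral-minor cases arise purely from DAF > 0.5
  and the polarization stage, not the simulator, produces the strata;
* conservation-like score 5 − 3·DAF + N(0, 1) — slope three times the
  noise sd, strong enough that the stratified sign flip is decisive at
  n = 20,000;
* age = DAF·1000 ky + N(0, 100) ky clipped at 0, with an injected
  corner fraction overwritten as quick-running (age U(50,300),
  DAF U(0.8,1)) or slow-running (age U(700,1200), DAF U(0,0.2)) and
  recorded in the truth object;
* codon bias: within each synonymous family of size k the designated
  optimal codon is used with probability logistic(b·z + logit(1/k)),
  z the gene's standardized log-expression, so b = 0 is exactly uniform;
  tissue columns are the latent level times lognormal noise (sd 0.5);
* category penalties: essential (10% of genes) and Mendelian (30%)
  flags each multiply s by 2; TIS and SS positions multiply s by 3.
  Regional strata are small (splice margins cover ~1% of sites), and the
  planted regional constraint is set strong enough to be reliably
  detectable at the cohort sizes used — consistent with translation
  initiation and splice sites being among the most strongly conserved
  exonic elements.

Everything is reproducible from (parameters, seed); one
`numpy.random.Generator` per operation.

What passing these tests shows: the pipeline recovers, from its own file
formats, every planted relationship — the sign flip, monotone DAF-bin
means, codon-bias direction per family, regional and gene-category DAF
shifts, corner labels — at the planted effect sizes. What it does not
show: realism of linkage, demography, mutation-signature context, or the
absolute scale of real conservation scores; the simulator draws sites
independently and codes selection as a single Beta-tilt parameter.

## Statistical conventions

All tests are two-sided and p-values are reported raw (no
multiple-testing correction). "t-test" means Welch's unequal-variance
test; the Wilcoxon rank-sum test is the Mann–Whitney U. ECDFs are
right-continuous step functions with jumps i/n at tied observations
(statsmodels implementation, matching R's `ecdf`). Binned summaries
report n, mean and SEM (sd/√n, ddof = 1); empty bins are omitted rather
than reported as zero, and singleton bins have undefined SEM. The ω
(dN/dS) split uses the within-cohort median as cutoff. Corner thresholds
are strict inequalities at all four edges. SNP-vs-background contrasts
are reported as background-minus-SNP mean differences.

## Problem sizes and determinism

The default acceptance run and test suite use cohorts of 20,000–50,000
SNPs on ~120-gene transcriptomes, 20 replicates for recovery rates, 500
random draws for divergence properties, and 200 random ≤14-nt windows for
the DP-vs-enumeration check (agreement demanded at 10⁻⁹ relative error;
observed ~10⁻¹⁴). Full-window (150 nt) structural scoring costs roughly
0.1–1 s per variant and is therefore computed for the variants a given
analysis needs rather than for whole large cohorts by default
(`score_cohort(..., structural=True)` opts in; the window width is
configurable). Report tables are written with fixed float formatting and
sorted file order, so a rerun with the same config and seed is
byte-identical.

## Known limitations

* The energy model is a teaching-grade surrogate of nearest-neighbour
  thermodynamics: no stacking, loop entropies, dangles or temperature
  dependence; magnitudes of D and |ΔΔG| are not comparable to
  Turner-model tools, only their relative behaviour across variants is
  meaningful.
* Ancestral states are consumed, not inferred; misannotation (a known
  failure mode of outgroup-based polarization) propagates directly into
  the strata.
* One transcript per gene; no isoform weighting, no genome-coordinate
  liftover, no multi-sample genotypes.
* Allele ages and conservation scores are treated as given annotations;
  their estimation error models are out of scope.
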