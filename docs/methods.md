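# Methods

This note documents the models, conventions and design choices behind
`synsplice`, in the order the pipeline applies them. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Coordinates and site classes

All genomic coordinates are 1-based inclusive (the VCF convention); BED
input is converted from 0-based half-open at the reader. Within an exon,
distances are transcript-oriented: `dist_to_acceptor` counts from the 5'
exon boundary and `dist_to_donor` from the 3' boundary, both starting at
1, with the invariant `dist_to_donor + dist_to_acceptor = exon_len + 1`.
A variant is a splice-site-consensus variant (VSS) when
`dist_to_donor <= 3` or `dist_to_acceptor <= 1` — i.e. the last three
exonic bases before the donor junction or the first exonic base after the
acceptor — and a variant-in-internal-exon (VIE) otherwise. Variants are
assumed to be pre-filtered synonymous SNVs; an optional codon-table check
(`genomic.is_synonymous`) is available but off by default. For genes with
several isoforms, features are computed per supplied transcript and the
caller chooses one transcript per gene.

## RBP binding models

A PWM of counts `n[i][j]` (k positions × ACGT, U collapsed onto T) with
pseudocounts `c[i][j]` (default 0.25 per cell, matching the 0.25 uniform
background) defines the PSSM

    s_ij = log2( ((n_ij + c_ij) / (N + sum_j c_ij)) / 0.25 )

where `N` is the number of validated binding sites (defaulting to the
largest per-position count total when the motif file omits it). A k-mer's
matching score is the sum of its PSSM entries. Score distributions are
Gaussian with moments

    M_s = sum_ij f_ij s_ij
    V_s = sum_ij [ f_ij s_ij^2 - (f_ij s_ij)^2 ]

using `f_ij = 2^{s_ij}/4` for binding events and `f_ij = 0.25` for
non-binding events. The variance formula is implemented literally, term by
term; since the implied `f_ij` need not sum to 1 per column when count
totals deviate from `N`, the deviation is exposed as a diagnostic
(`pwm.column_frequency_sums`) and logged, never silently renormalised.
Degenerate (zero-variance) models — e.g. from a uniform PWM — raise
`DegenerateVariance` in the ratio-based quantities; the panel summariser
treats such RBPs as uninformative (M = 0, posterior = 0).

The magnitude of a variant's effect on one RBP is

    M = log2{ [Phi_B(S_A) (1-Phi_NB(S_R))] / [Phi_B(S_R) (1-Phi_NB(S_A))] }

with Phi_B, Phi_NB the Gaussian CDFs of the binding and non-binding score
models, parameterised by mean and *variance* (sigma = sqrt(V)). CDF values
are clamped to [1e-300, 1 - 1e-16] before logs so extreme scores produce
large-but-finite magnitudes; this is a deliberate finite-arithmetic
deviation from the idealised formula. M is antisymmetric under allele swap
and zero at equal scores; the tests verify it against an independent
quadrature oracle to 1e-6 over 1000 random models.

The flip posterior integrates the prior binding probability B over a Beta
distribution whose mode is 0.05 — default Beta(2, 20), the smallest
integer shape pair with that mode, both parameters configurable:

    P = E_B[ B(1-B) (g_B(S_R) g_NB(S_A) + g_NB(S_R) g_B(S_A))
             / ( (B g_B(S_R) + (1-B) g_NB(S_R)) (B g_B(S_A) + (1-B) g_NB(S_A)) ) ]

The marginal densities in the denominator are the prior-weighted mixtures
evaluated inside the integral. Integration is a fixed 2001-point composite
Simpson rule on [0, 1] — deterministic by construction; non-finite results
raise `IntegrationFailure` rather than being clipped. In the uninformative
limit (binding and non-binding densities equal) the posterior reduces to
the Beta moment `2(E[B] - E[B^2])`, which the tests check to 1e-6.

**Window policy.** The method does not pin down how the k-mer window is
anchored around the variant. Default (`mode="best_ref"`): score all
k-windows overlapping the variant at identical offsets for ref and alt,
and report the pair at the offset maximising the reference score. A
symmetric alternative (`mode="best_either"`, offset maximising the larger
of the two alleles' scores) is selectable; exact M-antisymmetry under
allele swap at the scan level holds only for the symmetric mode.

Per variant, the RBP block emits: maximum matching score of each SR
factor (SFRS1/2/5/6) on the wild and the mutated exon sequence (8
features), the largest |M| across the panel, and the number of RBPs with
flip posterior > 0.5.

## Splice-regulatory features

**Junction strength** is the PSSM matching score of the donor window
(last 3 exonic + first 6 intronic nt) and the acceptor window (last 20
intronic + first 3 exonic nt); the windows are configurable and the site
PWMs are an input file (the canonical matrices are published externally
and not bundled). When the variant falls inside a window, the alt-minus-
ref score difference is emitted; otherwise the delta is 0.

**ESE/ESS cluster score.** Libraries of 6-mers are exact-matched against
the exon. Overlapping hits (sharing >= 1 bp) union-merge into motif sets,
scored `2^(N_m - 1)`. Sets separated by <= 6 strictly-intervening bp chain
into clusters; gaps <= 3 bp are short intervals (I_s), gaps of 4-6 bp long
intervals (I_l); adjacency (gap 0) counts as short. Each cluster scores
`(2 I_s + I_l + #sets) + sum of member set scores`. Conventions the source
formula leaves open, fixed here and configurable where noted:

* log base: 2 (consistent with every other logarithm in the model);
* the trailing set-score term sums over all member sets (reduces correctly
  to the single-set case);
* multiple clusters per exon: cluster scores are summed before the log
  (monotone in motif burden, defined for any exon);
* an exon with no hits scores 0; a lone set is a cluster of one.

The exon score is `log2(total) / (exon_len / 100)`; the variant feature is
the alt-minus-ref difference, computed separately for the ESE and ESS
libraries.

**RNA secondary structure.** The variant ±50 nt of pre-mRNA (configurable)
is folded for both alleles; features are the average single-strandedness
of the central ±7 nt of the reference structure and a distance between
the two structures. The provider is pluggable: ViennaRNA MFE folding via
its python bindings when importable (structure distance = base-pair
distance), else a bundled deterministic Nussinov maximum-pairing folder
(minimum loop 3; GC/AU/GU pairs; ties broken toward the unpaired branch
and the smallest pairing partner) with Levenshtein distance between
dot-bracket strings. The Nussinov fallback is a maximum-pairing
approximation, not a thermodynamic model: its pairing indicator is 0/1
rather than a probability, so the "single-strandedness" it yields is the
unpaired fraction of the MFE-like structure.

## Protein features

Per-residue tracks are consumed, never predicted here; the TSV schema
(`protein_id, residue_index, asa, disorder, p_helix, p_sheet, p_coil`) is
the integration contract with upstream predictors. The exon's residue
range includes every residue with >= 1 coding nucleotide in the exon, so
junction-spanning codons belong to both flanking exons. Features: ASA
avg/min/max; twelve disorder features (min/max/avg over all residues,
category averages, run switch count, and avg/max/min run lengths for
disordered and structured runs) with a 0.5 disorder cutoff by default
(conventional for the upstream predictor; configurable); twelve
secondary-structure features (stats of the winning-class probability,
argmax ties broken helix > sheet > coil, plus per-class stats); Pfam
overlap fraction; PTM sites per 100 aa. When an exon has no residue of a
category, the corresponding run features are 0 with a companion presence
indicator, keeping the matrix rectangular. Missing whole tracks are
median-imputed with a `protein_track_missing` indicator.

## Cohort construction

Filters, in order: optional exclusion list (e.g. overlap with an external
clinical database), removal of first/last-exon variants (their inclusion
is governed by promoter/polyadenylation choice), one variant per exon
(uniform seeded choice; a deterministic first-by-position mode is
provided), and strict minor-allele-frequency floors for neutral variants
(> 0.03 for VSS, > 0.10 for VIE; boundary equality excluded because the
criterion is "greater than"). Neutral variants without a MAF are kept
with a warning. Balancing downsamples neutrals to the positive count;
the 2/3–1/3 train/test split is stratified by label (round-to-nearest on
the train side) after balancing (the alternative order is a caller
choice), and exon disjointness between partitions is asserted.

## Classifier and evaluation

`DiseaseProbabilityClassifier` wraps a scikit-learn random forest with the
method's fixed hyperparameters: 51 trees and 35 candidate features per
node, capped at the schema width with a logged warning when a reduced
schema is narrower. No feature selection precedes training. The split
criterion is Gini by default (entropy selectable); the original tooling
predates a stated choice. Separate VSS and VIE models are trained; the
VSS schema deliberately omits the junction-proximity feature, which would
trivially encode the class definition. The feature schema is hashed at
fit time and checked at predict time. MCC uses a 0.5 vote threshold (the
majority convention); AUC uses midrank tie handling; K-S compares the
class-conditional score distributions. The MAF analysis uses 20
right-closed bins of width 0.05 (0 falls in the first bin), drops empty
bins, and fits an ordinary least-squares line to the per-bin means.

## Synthetic data: what it emulates and what it does not

The generator emits every input format the pipeline reads: a single-
chromosome genome with alternating-strand multi-exon genes (canonical
GT/AG introns, CDS padded to a codon multiple), splice-site PWMs counted
from the generated junctions themselves, a 20-PWM RBP panel (four SR
factors plus 16 others; one dominant base per column, 14/20 consensus
counts), ESE/ESS libraries of 60/40 distinct random 6-mers, per-residue
tracks, domain/PTM annotations, and a Gaussian conservation track.
Default study conditions: 200 disease + 200 neutral VIE variants across
50 genes × 10 exons (exons 75–150 nt, introns 80–200 nt), one variant per
internal exon.

Planted disease-vs-neutral contrasts follow the directions the method was
designed around: 90% of disease variants disrupt either a planted ESE
motif (the alternative allele chosen so no library hit survives at the
locus) or a planted SR-factor consensus site; their host exons get ASA
lowered by 18 Å² (buried), disorder lowered by 0.18 (structured), extra
Pfam coverage (+0.45 probability of a covering domain over a 0.25 base
rate), +1.5 PTM sites per 100 aa, and +1.5 conservation in the variant's
±7 bp. Disease MAFs are Beta(0.5, 30); neutral VIE MAFs are uniform above
the 0.10 floor. The synthetic library sizes and effect magnitudes are
this package's own choices, frozen once in `SimConfig`: library sizes
keep the background hit density low on toy exons, and the effect sizes
give near-ceiling recovery at n = 200 per class so the recovery check is
a sharp pass/fail on the machinery rather than on statistical power.
`SimConfig.null()` zeroes every planted effect, making the classes
exchangeable — the negative control.

What passing these tests shows: the feature extractors read the formats
correctly, compute the documented quantities, and the forest recovers
class signal carried through those features, with chance-level AUC when
no signal exists. What they do not show: performance on real variants.
Real PWMs are longer and softer, real ESE/ESS libraries are denser
(thousands of hexamers), real effect sizes are far smaller and
correlated, MAFs are drawn rather than evolved, and protein tracks come
from predictors with structured errors — none of which the generator
models.

## Numerical choices and limitations

* Posterior integration: fixed 2001-point Simpson grid; Beta endpoint
  singularities (shape < 1) are zeroed, which is exact because the
  B(1-B) factor vanishes there.
* Gaussian CDF clamps: [1e-300, 1 - 1e-16].
* All floating-point output is printed at 6 significant digits; every
  output file carries a version/seed/config-hash header.
* All randomness flows through seeded numpy Generators; reference and
  cohort generation use independent streams spawned from one seed.
* Default problem sizes in the test suite (6–20 genes for unit tests,
  the full 50-gene default for recovery) keep a complete run to about a
  minute on one CPU.
* Features are computed on the annotated (naturally spliced) isoform
  only; structural features of the exon-skipped product are out of scope.
* Gene-family homology de-duplication beyond one-variant-per-exon is
  supported only via the exclusion-list hook (pass a precomputed list);
  no clan/family clustering is performed.
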