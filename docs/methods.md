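# Methods

## Model

Translesion synthesis (TLS) bypasses a DNA lesion with a low-fidelity
polymerase. Two mutagenic outcomes are modelled. (1) *Erroneous bypass*:
a primary mutation arises at the lesion, recognisable by
treatment-specific triplet classes; the TLS polymerase may additionally
misinsert on the undamaged template within a few tens of base pairs,
producing a close mutation pair. (2) *Error-free bypass*: no primary
mutation, but the same nearby misinsertion can occur, leaving a solitary
collateral mutation beside an "invisible" lesion. Because DNA polymerises
5'→3', a polymerase switch at the lesion puts the collateral downstream
of it: in upper-strand coordinates 5' of an upper-strand lesion and 3' of
a lower-strand one. A minority of events (observed ≈20%) have the reverse
orientation, consistent with switching upstream of the lesion (e.g. in
post-replicative gaps).

## Definitions and conventions

- Coordinates are 1-based, fully closed, VCF-style; distances are
  absolute position differences on one chromosome.
- **DBS merging.** Runs of directly adjacent substitutions (distance 1)
  are collapsed into one multi-nucleotide event and excluded from all
  pair statistics: such events arise in a single mutagenic step.
- **Close pairs.** Same-sample substitutions chained by single linkage at
  ≤100 bp (inclusive). Size-2 clusters are close pairs; clusters of ≥3
  are reported separately and omitted from pair-level analyses, while
  their members still count as close mutations. The accounting identity
  n_close = 2·pairs + Σ omitted-cluster sizes is the package's
  definition. CMR = n_close / n_total, pooled over the clones of a group;
  per-clone values are computed for plotting.
- **Expected CMR.** Each null simulation draws as many uniform positions
  from the eligible regions (chromosomes minus runs of ≥10 N bases) as
  the sample has mutations, computes the close fraction, and divides by 2
  so that only same-strand coincidences are counted; the ÷2 correction is
  applied per simulation. One seeded generator per batch.
- **96-channel spectra.** Contexts are pyrimidine-normalised (purine
  reference ⇒ reverse complement with flanks swapped); channel order is
  C>A, C>G, C>T, T>A, T>C, T>G by substitution, then 5' and 3' flank
  alphabetically. N in the ±1 context excludes a record from
  context-dependent analyses only.
- **Schemes.** Built-in primary classes: DT40 cisplatin {N[C>A]Y,
  N[T>A]C, C[T>A]N} with upper-strand lesion alleles {G>T, A>T}; DT40
  UVC {Y[C>T]N, Y[T>A]N} with {C>T, T>A}; human cisplatin close-pair
  {N[C>A]C} and burden {N[C>A]C, C[C>T]N, C[T>A]N}. User schemes load
  from YAML. A proper pair is orientation-consistent when an upper-strand
  lesion's primary is the 3' member, or a lower-strand lesion's primary
  the 5' member.
- **Slippage.** The collateral's comparison base is its immediate
  neighbour on the side facing the primary, in upper-strand coordinates
  (strand-consistent by complementation). (copy, non-copy) counts are
  tested two-sided by Fisher's exact test against the 1:2 split expected
  from random misinsertion at equal total. All Fisher tests in the
  package are two-sided.
- **Motif profile offsets.** Dinucleotide positions around a mutation are
  indexed by signed nearest-base distance: a motif at offset d<0 occupies
  (pos+d−1, pos+d), at d>0 (pos+d, pos+d+1); motifs overlapping the
  mutated base have no offset. This indexing is exactly symmetric under
  reverse complement (CC↔GG, d→−d), so the directional excess is
  invariant under strand swap. Background = per-motif median per-offset
  frequency over the ±window (pooled across samples), averaged over the
  two motifs; expected count = background × k × n_sites × 2; the
  enrichment test is Fisher's exact on observed vs rounded expected out
  of 2·k·n_sites slots. Lowess smoothing of profiles is cosmetic only.
- **Burden arithmetic.** collateral-per-erroneous-bypass rate =
  pairs/primaries per genome; invisible lesions = directional excess per
  genome ÷ that rate; % correctly bypassed = invisible/(invisible +
  primaries); collateral share of non-primary burden =
  (pairs + excess)/non-primary. These identities hold to machine
  precision by construction.
- **Attribution purity** = 1 − (mock primary-class average)/(treated
  average). With the published inputs this yields 94.5% (cisplatin,
  1 − 12/219.6) and 99.5% (UVC, 1 − 8/1503.7); the package reports its
  own arithmetic.

## Signature analysis

Spectra are factorised with Frobenius-objective multiplicative-update
NMF (scikit-learn), best of n_starts=50 seeded random restarts, tolerance
1e-6, max 5000 iterations; signature columns are normalised to sum to 1
with exposures rescaled into mutation counts. Rank diagnostics follow the
consensus-clustering approach: the cophenetic correlation of the
restart-consensus connectivity matrix (rank 1 defined as 1) and the best
RSS per rank. The recommended rank is the largest rank before the first
cophenetic drop >0.1; when the consensus stays stable across the range —
typical when exposures are well mixed — the strongest elbow of log-RSS
(largest second difference) is used instead, since improvements beyond
the true rank decay roughly geometrically as components absorb Poisson
noise. The recommendation is a documented heuristic and user-overridable.
For pair-aware extraction, catalogues are split into per-sample solitary
spectra and per-group pooled close-pair spectra (extra rows), conserving
totals. Refitting to fixed signatures is nonnegative least squares;
reconstruction quality is reported as relative RMSD = RMS channel
difference ÷ sample total. External signature tables (e.g. COSMIC) can be
supplied as files for cosine comparison; there is no network access.

## Synthetic data generator

The generator emulates the mutagenesis the analysis assumes, with
defaults chosen as the study conditions: 5 Mb single-chromosome i.i.d.
genome at GC 0.45, 20 clones, 200 lesions per clone placed uniformly on
GG/AG motif instances on either strand (p_upper = 0.5), primary-error
probability 0.3, collateral probability 0.05 (independent of the primary
outcome, so solitary collaterals arise next to invisible lesions),
slippage probability 0.5, reverse-orientation probability 0.2, collateral
distances from a truncated geometric on 2..100 bp with ≈87% of mass at
≤10 bp (empirical distributions can be supplied), background substitution
rate 2e-5/bp and indel rate 2e-6/bp per clone. These rates reproduce a
pooled CMR of roughly 4% and short-range-dominated pair distances,
matching the magnitude observed in mutagen-treated genomes. Primary
alleles are drawn so that every planted primary falls in the cisplatin
scheme's classes on the correct strand (G>T/A>T on the lesion strand).
Each record carries QC metrics (mean mapping quality, coverage
fluctuation flag, cross-sample support, reads with both variants,
ref/alt read counts) so the post-filters are exercisable.

Numerical choices: one seeded generator drives a whole simulation;
collision policy resamples an occupied position up to 100 times, then
skips and logs. The slippage flag and orientation side are drawn once per
collateral and only the distance is resampled on placement failure
(e.g. when the slippage target equals the collateral's reference base and
the event would be invisible), so the realised copy fraction and
orientation consistency equal p_slip and 1 − p_upstream_switch exactly in
expectation — this keeps parameter-recovery contracts clean.

What the generator does **not** emulate: replication timing, transcription
strand and chromatin covariates; interstrand crosslinks and structural
variation; alignment artefacts (QC metrics are clean by default);
multi-chromosome genomes and realistic N-gap structure. Passing recovery
tests therefore demonstrate correctness of the statistical machinery
under the model's assumptions, not robustness to every artefact of real
sequencing data — the metric-based post-filters exist precisely because
real catalogues violate the clean-data assumption.

## Degenerate inputs and tie-breaks

Empty catalogues give CMR = None rather than 0; zero-vector cosine and
zero-total relative RMSD raise; proportion tests return p = 1 exactly for
identical proportions (pooled z, equivalent to χ² without continuity
correction); the slippage expected-copy count uses round(n/3);
both-primary pairs with conflicting lesion strands are skipped in
orientation statistics; indels longer than 20 bp are flagged on input and
excluded from mixed-pair analysis.

## Known limitations

- The published close-mutation accounting for cisplatin (125 close
  mutations vs 59 pairs + two size-3 clusters = 124) contains a one-off
  discrepancy; the package's counting identity is the definition and no
  attempt is made to force the published figure.
- Whether the ÷2 null correction was originally applied per sample or on
  pooled ratios is unknowable from the text; it is applied per
  simulation here.
- NMF results depend on unpublished settings (algorithm variant, start
  count, convergence); component similarities are therefore approximate,
  and the pair-split analysis is validated on planted-signature data.
- Verification that pair members share supporting reads is represented
  only as predicates over supplied per-record metrics; no BAM access.

## Problem sizes

The test suite simulates genomes of 0.15–0.5 Mb with 2–8 clones per
case and 20 replicates for parameter recovery; the acceptance script
runs the full default 5 Mb / 20-clone conditions plus a 16-sample
planted-signature NMF. These sizes give stable statistics (hundreds of
pairs, thousands of sites) while keeping a full run in seconds.
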