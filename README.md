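# collatmut

Analysis of **collateral mutagenesis** in whole-genome somatic mutation
catalogues.

Translesion synthesis (TLS) lets specialised low-fidelity polymerases
(Pol η, Pol κ, Pol ζ, REV1) replicate across DNA lesions. Besides the
*primary* mutation made directly opposite the lesion, the TLS polymerase
can misinsert on the undamaged template nearby, leaving a *collateral*
mutation. In upper-strand coordinates the collateral lands 5' of an
upper-strand lesion and 3' of a lower-strand one, producing close mutation
pairs with a characteristic orientation; after error-free bypass the same
mechanism leaves *solitary* collateral mutations next to invisible
lesions. `collatmut` implements the downstream statistics of this model
for mutagen-treated (cisplatin-like, UVC-like) and homologous-
recombination-deficient genomes:

- **Close pairs and CMR** — single-linkage clustering of same-sample
  substitutions within 100 bp (directly adjacent events are first merged
  into double substitutions and excluded); size-2 clusters are close
  pairs, the close mutation ratio CMR = n_close / n_total; a
  random-position resampling null gives the CMR expected by chance
  (raw ratio ÷ 2 to count only same-strand coincidences).
- **Primary/collateral classification** — treatment-specific triplet
  classes over pyrimidine-normalised contexts (e.g. N[C>A]Y, N[T>A]C,
  C[T>A]N for cisplatin; Y[C>T]N, Y[T>A]N for UVC), lesion-strand
  assignment from the observed allele change, pair categorisation,
  orientation asymmetry (Fisher's exact test), and the polymerase-slippage
  statistic: how often the collateral allele copies its neighbour base on
  the lesion side, tested against the random 1:3 expectation.
- **Solitary-collateral burden** — directional CC/GG dinucleotide
  (potential lesion motif) enrichment in a ±300 bp window around solitary
  non-primary mutations; the excess over the median background converts
  into the number of correctly bypassed lesions and the collateral share
  of the non-primary burden.
- **Pair-aware signatures** — 96-channel spectra, NMF extraction with
  rank diagnostics (cophenetic coefficient, RSS), catalogues split into
  per-sample solitary and per-group close-pair spectra to isolate a
  collateral-specific component, cosine comparison and fixed-signature
  NNLS refitting.
- **Forward simulator** — lesions planted at GG/AG motifs on either
  strand with tunable primary-error, collateral, slippage and
  orientation-switch probabilities, emitting catalogues with full ground
  truth for every analysis stage.

## Worked example

```python
from collatmut import *

cfg = SyntheticConfig(genome_length=1_000_000, n_clones=8,
                      n_lesions_per_clone=200, p_primary_error=0.3,
                      p_collateral=0.15, p_slip=0.6, seed=7)
res = simulate_clones(cfg)

merged, dbs = merge_dbs([r for r in res.records if r.kind == "SBS"])
stats = close_mutation_ratio(merged)
# n_total 880, n_close 154, cmr 17.50%, 74 pairs, 2 omitted clusters

cats = categorize_pairs(stats["pairs"], "cisplatin_dt40", res.genome)
proper = [c for c in cats if c.category == "proper"]       # 64 pairs
slippage_analysis(proper, res.genome)
# {'n_copy': 37, 'n_noncopy': 27, 'copy_fraction': 0.578,
#  'fisher_p': 0.0075, 'n_excluded': 0}

null = expected_cmr(stats["n_total"] // 8,
                    NullConfig(n_sims=100, seed=1,
                               eligible_regions=res.genome.eligible_regions()))
# expected-by-chance CMR 1.19%
```

The observed CMR (17.5% at these deliberately elevated simulation rates)
vastly exceeds the 1.19% chance expectation; 64 of 74 pairs are *proper*
(one primary, one non-primary); the collateral allele copies its
lesion-side neighbour in 57.8% of pairs (planted slippage probability
0.6), significantly above the random one-third (p ≈ 0.0075); and 75% of
proper pairs have the canonical orientation (planted 80%).

The same functions run on real data read with
`read_catalog("calls.tsv")` / `Genome.from_fasta("genome.fa")`, or from
the shell:

```sh
collatmut simulate --out-dir sim/ --seed 4
collatmut pairs --catalog sim/catalog.tsv --out pairs.tsv
collatmut classify --catalog sim/catalog.tsv --genome sim/genome.fa --out cats.tsv
collatmut burden --catalog sim/catalog.tsv --genome sim/genome.fa
```

## Documentation

See `docs/methods.md` for the model, parameter conventions, numerical
choices and known limitations.
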