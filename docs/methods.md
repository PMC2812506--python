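# Methods notes

This note records the modelling assumptions, parameter defaults, numerical
choices and known limitations behind `sixframe`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Six-frame translation database

Translation uses the standard genetic code only; selenocysteine and other
non-standard decodings are not emitted. A putative protein is a
stop-to-stop segment: translation starts at nucleotide 1, 2 and 3 of each
strand and a segment ends at every stop codon (internal stops are never
retained inside an entry). Two retention filters follow the tryptic logic
of the downstream search: segments shorter than `min_len = 6` amino acids
are discarded, and segments containing neither Lys nor Arg are discarded
because they cannot yield a fully tryptic peptide (`require_kr`, on by
default; both are configurable).

Coordinates are 1-based inclusive on the forward chromosome (Ensembl
convention), strand ∈ {+1, −1}, and frame f ∈ {1,2,3} is the offset of the
first translated nucleotide on the reading strand's 5′ end. Every entry
satisfies `genomic_end − genomic_start + 1 = 3·|aa_seq|`, which is what
makes exact peptide-to-genome mapping a pure arithmetic operation later.

**Ambiguity codons.** A codon containing any IUPAC nucleotide ambiguity
letter (N, R, Y, S, W, K, M, B, D, H, V) terminates the current segment,
exactly as a stop codon does. The alternative — skipping the codon and
continuing the amino-acid chain — would emit sequences that claim
contiguous genomic coordinates while actually spanning a gap, breaking the
span invariant above; it remains available as `ambiguity="skip"` for
completeness (skip-mode entries keep the full genomic span, which then
exceeds 3·length). Ambiguity letters that coincide with amino-acid letters
(H, R, K, ...) are always interpreted as nucleotide codes in this context.

**Decoys.** One decoy per target, amino-acid sequence reversed, accession
prefixed `DECOY_`. Reversal preserves length, residue composition and the
number of entries, so decoy hit counts are an unbiased estimate of chance
matching under the search's scoring.

## Exon-junction database

For each gene, every ordered (donor 3′ end, acceptor 5′ end) exon pair is
concatenated and translated in three frames. Ends are `end_len = 54` nt per
side (whole exon when shorter) — enough to contain any tryptic peptide of
ordinary length crossing the junction at 3 nt/residue. A transcript's
5′-terminal exon contributes only its 3′ end and a 3′-terminal exon only
its 5′ end. Pairing across all transcripts of a gene (including self-pairs
and non-adjacent pairs) deliberately over-generates: it covers exon
skipping and alternative junctions at the cost of some never-spliced
combinations, which is harmless because the database is only used to
*explain* reference-unique peptides, never to call novelty. A
within-transcript pairing mode (donor rank < acceptor rank) is available.

## Stand-in search engine

Commercial search engines' internal scoring is proprietary and not
reproducible; this package's matcher is a declared stand-in that
preserves the pipeline-relevant contract: all target and decoy candidates
within the precursor window compete for each spectrum, exactly one best
PSM is reported per spectrum, and a confidence in [0, 1] makes "≥ 95%
confidence" thresholds expressible. Externally produced PSM tables (TSV)
can be substituted at every stage.

Details and defaults:

* Tryptic digestion cleaves C-terminal to K/R except before Pro, with up
  to 1 missed cleavage by default; a semi-tryptic mode exists because
  pseudo-tryptic peptides (one ragged terminus) do occur among real
  candidates.
* Theoretical fragments are the singly charged monoisotopic b/y ladder.
  Fixed modifications default to the iTRAQ/MMTS sample-preparation
  chemistry (+45.98772 Da on Cys; +144.10207 Da on Lys and the peptide
  N-terminus) and are fully configurable, including `ModConfig.none()`.
* Tolerances default to ±0.5 Th (precursor) and ±0.2 Th (fragment),
  appropriate for QqTOF-class data.
* The score is the number of theoretical ions matched one-to-one to
  spectrum peaks within tolerance. Matching is an exact maximum matching:
  because all tolerance windows have equal width, the bipartite
  compatibility graph is convex and Glover's sorted sweep (match each peak
  to the lowest-m/z unmatched compatible ion) attains the optimum; a
  nearest-first heuristic can undercount on adversarial peak layouts, so
  it is not used.
* Confidence is a logistic calibration of the matched-ion fraction,
  `1 / (1 + exp(−12·(fraction − 0.5)))`. The constants are declared, not
  claimed equivalent to any engine's probability model; 95% confidence
  corresponds to ≈ 75% of the ladder matched.
* Ties are broken deterministically: higher confidence, then more shared
  peaks, then lexicographically smallest peptide, then target before
  decoy, then smallest accession. Identical inputs give bit-identical PSM
  lists.

## Two-stage search and FDR

The pre-screen searches each chromosome's target+decoy database
separately, keeping target hits at ≥ the confidence threshold and *all*
decoy hits regardless of confidence — discarding sub-threshold decoys here
would bias the later FDR estimate downward. The second stage re-searches
every spectrum (not a re-ranking) against the amalgamated database:
reference proteome ∪ parents of pre-screen target hits ∪ parents of all
decoy hits, de-duplicated by accession (a namespace collision between
reference and six-frame accessions is an error).

FDR is `100 · D / T` with decoys estimating false positives and accepted
targets estimating FP+TP; the concatenated-set variant `100 · 2D/(T+D)` is
available by flag. Counts are peptide-level after best-per-peptide
collapse; PSM-level counting is available in the same functions. The
pre-screen FDR is computed per-peptide across units; because the same
spectrum may be assigned in several chromosome units before competition,
this quantity is inflated by construction and is reported for
comparability, not used for filtering.

Orphan identification is exact sequence matching: orphans are six-frame
peptides at ≥ threshold with no exact match among reference peptides at ≥
threshold, minus peptides matching multiple genomic loci and minus
peptides that do match a reference hit below threshold. Reference-unique
peptides are annotated junction-explained when their sequence occurs in a
junction translation, or low-confidence-explained when the six-frame
search found them below threshold. These buckets partition the input
(checked by a property test).

The funnel report's rounding follows the conventions of the published
tables it mirrors: the overlap percentage is rounded to an integer; the
adjusted correspondence is truncated (not rounded) to two decimals.

## Peptide mapping and classification

Plus strand: `start = parent_start + 3·offset`, `end = start + 3·len − 1`;
minus strand mirrors from the parent's genomic end. A gene's span is the
min exon start to max exon end over its exons (the operational definition;
no UTR model). Gene and exon overlap for the
intergenic/intronic/exonic decision is strand-agnostic — an antisense
locus inside an intron is still "intronic", as with annotation-database
range queries — while the in-frame call is positional and strand-aware:
the peptide's first codon position must agree with the annotated exon
phase on the same strand. Sequence containment alone is not used, to avoid
false in-frame calls from repeated subsequences. Exon-extending loci take
their 5′/3′ label from the exceeded edge in the exon's transcript
orientation; a peptide overlapping two genes' exons is classified by the
first containing gene in sorted order with a logged warning. Peptides
whose coding DNA occurs more than once in the genome (either strand) are
`multi_target` and excluded from classification.

## Annotation filters

* **Pseudogene filter**: exclusion iff the peptide's reading-strand coding
  DNA occurs verbatim (100% identity, full length, same strand) as a
  substring of any pseudogene cDNA record. The reverse complement is
  tested only when a reference set is declared unstranded. A BLAST-based
  exact match and a substring scan agree for contiguous records.
* **Repeat filter**: exclusion iff the locus overlaps any repeat interval
  by ≥ 1 nt, strand-agnostic, closed-interval semantics.
* **Conservation**: ΣR is the per-base sum over the locus divided by its
  length, with unscored positions contributing 0 (so a fully unscored
  locus has ΣR = 0 exactly). Survivors satisfy ΣR ≥ cutoff with default
  cutoff 0 — note ΣR = 0 survives, since absence of scoring is not
  evidence against. The cutoff choice is informed by a Mann-Whitney U
  comparison of exonic vs candidate ΣR distributions after removing exact
  zeros (zero-stripping applies only to the test, never to filtering).
* **EST evidence** is recorded as a support annotation and never excludes:
  applied as a filter it predominantly rejects true novel candidates,
  because EST coverage is biased toward already-annotated regions.

The three exclusion filters are independent predicates, so the survivor
set is invariant to application order (property-tested).

## Spectral validation

The common-ion score counts one-to-one peak matches (same maximum-matching
routine as the search score) after restricting both spectra to
m/z > 160, removing isobaric-tag reporter ions and potential ammonium
adducts; filtering both spectra keeps the score symmetric. The matching
tolerance defaults to ±0.2 Th.

The null distribution draws `set_size` spectra per repetition from a pool
of unrelated spectra, *without replacement across all repetitions* (the
pool must contain at least `n_reps · set_size` spectra), and scores each
against every synthetic reference, emitting exactly
`n_reps · set_size · n_references` scores. The defaults (7,000 repetitions
of 10) follow the original design at full scale; the synthetic workflow
uses the same machinery at pool-appropriate sizes. The FDR at score s is
the two-sample tail ratio `100 · P(null ≥ s) / P(real ≥ s)`, capped at
100 and made monotone non-increasing by a running minimum over ascending
thresholds (q-value convention); a pure null-tail percentile mode would be
a trivial specialisation. An unattainable target FDR is reported with the
minimum achievable value rather than silently clamped. Published score
thresholds (e.g. 34.6 at 5% FDR) depend on the original instrument data
and are treated as non-reproducible references, not targets.

## Synthetic data generator

The generator emulates the study's *structure*, not its scale: a
2 × 50 kb genome, 10 three-exon genes (random proteins of ~56–91 aa built
from tryptic blocks, deterministic codon choice, exon phases implied by
the cut points), 5 novel stop-to-stop ORFs (3 intergenic, 2 intronic; each
a leading Lys plus a 9–12 aa tryptic peptide between stop codons, so the
peptide is a guaranteed fully tryptic product of its six-frame parent),
3 pseudogene-derived ORFs whose reading-strand DNA is also emitted as a
pseudogene cDNA record, 5 repeat intervals placed away from all plants,
and a conservation track with R = +2 over genes and novel ORFs, −1 over
background windows, absent elsewhere (pseudogene plants are left unscored,
so they pass the ΣR ≥ 0 rule and are removed by exactly the pseudogene
filter — the separation is by construction). Spectra are b/y ladders with
20 uniform noise peaks, a 5% chimera rate (a second peptide's ladder
merged at half intensity) and 20 pure-noise spectra; precursors are set
from the peptide mass at charge 2.

All randomness flows from one seed through named substreams (genome,
genes, novel, pseudogene, repeats, conservation, spectra, placement), so
outputs are byte-identical per seed. The generator checks its own
guarantees (planted coding DNA unique in the genome; placement feasible)
and fails loudly otherwise.

What the fixtures do *not* emulate — realistic fragment intensities,
isotope envelopes, retention time, homologous gene families, genuine
pseudogene decay (plants are exact copies), polymorphism — bounds what
passing tests show: they certify the pipeline's bookkeeping, coordinate
arithmetic, FDR estimation and filter logic, not search-engine sensitivity
on real instrument data.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at the
default fixture scale (100 kb of genome, ~70 spectra, ~6,000 six-frame
entries per run), the decoy-calibration check at 500 spectra against a
~300-protein target+decoy database, and the oracle comparisons at
10 kb / ≤ 20 peaks. These sizes were chosen so every property is exercised
end-to-end while the whole suite completes in seconds.

## Known limitations

* The stand-in matcher's confidence is a declared calibration; absolute
  confidence values are not comparable to any commercial engine's.
* Six-frame entries are linear genomic peptides; spliced peptides are
  handled only via the junction database, never as split intervals.
* mzML/mzIdentML, PTM discovery, isotope deconvolution, protein-level
  inference and isobaric-reporter quantification are out of scope.
* In `ambiguity="skip"` mode the span invariant is intentionally relaxed
  (see above); coordinate-dependent downstream steps assume the default
  terminate mode.
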