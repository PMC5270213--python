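# Methods

## Problem setting and assumptions

The package compares two curated enzyme compilations: a **PM side** built from
genomes believed to contain no biosynthetic gene clusters (so every enzyme can
be assigned to primary metabolism with confidence) and an **SM side** built
from expert-annotated BGCs. Neither compilation is a census — both are
deliberately conservative proxies — so every derived quantity is a bound on,
not an estimate of, the true PM/SM overlap. Three assumptions run through the
analysis:

1. **EC numbers identify function.** Two enzymes catalyze the same reaction
   iff they share a full EC number; they share reaction chemistry iff they
   share the first three digits (the subdivision). Wildcarded annotations
   (e.g. `1.-.-.-`) are informative only down to their last concrete digit.
2. **A stringent BLAST hit implies homology** in the sense of shared fold and
   common ancestry. No attempt is made to resolve orthologs from paralogs:
   BGCs travel by horizontal transfer, which makes that distinction
   ill-posed here.
3. **Genomic context is an operon proxy.** Bacterial neighbors frequently
   share a pathway, so the composition of the ±10 window around a putative PM
   homolog (±2 as a typical-operon inner window) is evidence about its
   metabolic role. No operon prediction is attempted.

## Pipeline

**Ingestion.** Catalogs are TSV tables of records (gene, collection, EC list,
protein length, product). Inclusion requires exactly one EC number: records
without an EC have unknown function; records with several have ambiguous
function. Both removals are counted in a `FilterLog` that accounts for every
input record, so audits of the kind "N enzymes were eliminated" are
reproducible. Records whose single EC is wildcarded are kept and contribute
to every level at which they are complete; deeper levels drop them from the
denominator rather than impute digits.

**Spectra.** Frequencies count enzyme *records* (abundance), not distinct EC
numbers; a `weight="distinct"` switch exists for sensitivity analysis.
Frequencies are percentages of the records complete at the level and are kept
at full precision — rounding happens only in rendering. The
overrepresentation ratio is `f_SM/f_PM` per key; keys missing from the PM
side cannot form a ratio and are reported separately (they are flagged, not
silently infinite). The squared Pearson correlation of two spectra is offered
under two pairing policies — union-with-zero-fill (default; keys private to
one side count as disagreement) and intersection — because the choice is a
genuine degree of freedom and materially changes r².

**Homology screen.** Hit tables are BLAST outfmt-6 (12 columns, optionally
`qlen`/`slen`). Multi-HSP duplicates of a (query, subject) pair collapse to
the minimum-E-value row before filtering, since the unit of analysis is the
homolog pair, not the HSP. Filters: E-value ≤ cutoff (default `1e-20`,
inclusive; `1e-10` is the standard relaxed control) and
`|L_subject − L_query| / L_query` ≤ 0.30, also inclusive, with the *query*
length as denominator. Self-hits are removed by gene id. Filtering is
order-independent and monotone in both parameters (relaxing never removes a
kept hit); both properties are tested.

**Classification.** Kept hits are pooled per SM function key at each level.
A key is `ALL_SAME` when every pooled PM hit matches it, `ALL_DIFF` when none
does, `MIXED` otherwise — a partition of the classified keys. The
functional-conservation rate `fc` is hit-weighted:
`fc(g) = Σ n_same(g) / Σ n_hits(g)`. Summary fractions can be expressed
against a larger denominator than the classified keys (e.g. all SM
subdivisions, including the ones with no homolog at all), which is why
`ClassificationSummary` carries both `n_classified` and `n_keys`.

**Change networks.** Every hit whose PM key differs from its SM key
contributes to the directed edge `pm_key → sm_key`; same-function hits
contribute to node `fc` but never to edges, which yields the integer identity
`Σ incoming edge weights = n_hits × (1 − fc)` per node and, globally,
`Σ edge weights + Σ same-function hits = total hits` (property-tested). The
per-edge mean E-value is **geometric** by default (mean of log10 E-values,
exponentiated): E-values span dozens of orders of magnitude, and an
arithmetic mean would be dominated by the weakest hit; the arithmetic mean
remains available. Bin edges default to `1e-20, 1e-50, 1e-100` and are
configuration, recorded in the graph metadata — they are display bins, not
statistics. Keys never observed on the PM side carry `present_in_pm = False`.

**Neighborhoods.** Windows are gene-order based (ordinals), strand-agnostic,
truncated at linear replicon ends (a circular flag enables wraparound). The
anchor gene is **included** in the window and in all tallies; this inclusive
reading is what reproduces both transcribed worked examples (13 P/2 S for the
pabB window and 17 P/16 S for the trpE window) exactly. `P` requires a
complete EC present in the PM reference key set; `S` matches the gene's EC
*string* against the secondary-metabolism function mapping, which may itself
contain wildcarded entries (the trpE example contains one). Pathway rows are
sorted by (outer count desc, pathway id). HTML reports are deterministic:
stable ordering, no timestamps, every gene linked through a URL template.

## Synthetic data and what the tests show

`ecrecruit.simulate` emulates the study conditions end to end:

* 15 PM collections × 60 genes and 20 BGCs × 6 enzymes (≈10³ enzymes total),
  with background functions drawn from the observed PM/SM class spectra
  (18.71/35.25/17.25/10.70/6.67/11.42 and 22.10/36.33/11.64/17.28/6.81/5.84
  percent for classes 1–6);
* twelve planted homolog families — six monofunctional, four mixed, two fully
  changed — including an isochorismate-synthase-like family (SM 5.4.4.2 with
  PM homologs 2.6.1.85 and 4.1.3.27) and an acid-adenylate pair
  (2.7.7.58/6.2.1.26);
* in-family E-values log-uniform in `[1e-80, 1e-25]` (always below the
  stringent cutoff), decoys in `[1e-15, 1e-5]` (always above it, straddling
  the `1e-10` control), and a handful of passing-E-value hits with
  out-of-tolerance lengths; protein lengths per family jitter ±10% around a
  family base of 200–500 aa, so every in-family pair satisfies the 30% rule;
* 5% no-EC and 5% multi-EC records on both sides;
* per-genome gene orders with operon-like runs sharing a pathway label, one
  planted putative-PM anchor per genome inside such a run, and one embedded
  BGC span per genome.

The oracle recomputes every expected output by exhaustive enumeration over
plain strings and dictionaries, sharing no code with the pipeline. The test
suite asserts **exact** pipeline-vs-oracle equality of filter logs, spectra,
shared/exclusive sets, kept hit pairs, classifications, fc tables, edge
weights, and neighborhood tallies on seeds 1–5, plus exact recovery of the
planted family categories at the stringent cutoff.

What passing does **not** show: the generator plants hits directly rather
than running an aligner, draws E-values independently of sequence divergence,
uses clean single-replicon gene orders, and makes background EC numbers
collision-free with the planted designs by construction. Agreement with the
oracle therefore validates the package's arithmetic and bookkeeping, not the
biological fidelity of BLAST statistics or of real annotation noise.

## Numerical and degenerate-input choices

* Percentages and fc values are carried in double precision; files render
  floats with 6 significant digits for stable diffs.
* E-values of exactly 0 (aligner underflow) are clamped to `1e-300` before
  logs are taken.
* Ties in the multi-HSP collapse break by higher bitscore, making the
  collapse order-independent.
* Empty catalogs yield empty (not invalid) frequency tables; r² is refused
  (not NaN) below 3 pairs or at zero variance; a single-collection
  leave-one-out split warns and returns an empty reference set.
* Preliminary EC serials (`n`-prefixed) are rejected by default with an
  explicit opt-in to strip the prefix, and class 7 (translocases) is opt-in —
  the analysis universe is the classical six classes.

## Problem sizes

Tests and the acceptance script run the generator at its default scale
(≈1100 enzymes, ≈70 hit rows, 15 genomes) across five seeds; the whole suite
completes in a few seconds. The same code paths accept full-scale compilations
(tens of thousands of enzymes); all algorithms are linear or n·log n in
records and hits.

## Known limitations

* The package never runs BLAST; hit tables are inputs, and their provenance
  (search parameters, database composition) is the user's responsibility.
* PM/SM assignment is inherited from the input compilations; the package
  reports evidence (labels, tallies, neighborhoods) and does not issue a
  per-gene verdict.
* The S label depends on a supplied function→pathway mapping and inherits its
  over-breadth, as the trpE worked example deliberately illustrates.
* Classification fractions depend on the E-value cutoff; the relaxed control
  can only add hits, and the shipped monotonicity checks make that direction
  explicit, but no significance test is attached to the fractions.
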