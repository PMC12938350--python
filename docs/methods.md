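# Methods

This note documents the models, conventions and numerical choices behind
`mitoarch`, and what its synthetic data do and do not establish about
real mitogenomes.

## Coordinate model and annotation validation

Coordinates are 1-based and inclusive on both ends, matching the
convention of published mitogenome annotation tables (a feature printed
`1–68` has size 68). A feature crossing the origin of the circle is
stored with `wraps_origin=True` and `end < start`; its size is
`(L − start + 1) + end` for genome length `L`. The signed spacer between
consecutive features is `next.start − prev.end − 1`; negative values are
overlaps (e.g. the ATPase8/ATPase6 overlap of −10 bp). For the
wrap-around pair the spacer is `L − prev.end + next.start − 1`. These two
definitions telescope: for any feature list on a circular record,
Σ sizes + Σ spacers (wrap pair included) = L exactly, independent of
annotation completeness — a property the tests exercise on both packaged
and generated records.

The validator treats inconsistencies as data, not exceptions, because
published tables do contain them. The packaged shallow-water table ships
verbatim and is flagged on ten counts: two spacers printed 2 bp short of
their coordinate-derived values, one gene whose printed size is
frame-inconsistent with its printed amino-acid count and 1-nt stop
(1382 bp cannot encode 460 aa + T), four tRNA anticodons permuted
relative to the standard vertebrate assignments, and three tRNA sizes
that disagree with their own coordinates. The deep-water table validates
clean under the same rules. The final printed table row's spacer column
is not checked against the wrap pair, since printed tables leave the
control region unannotated there.

Number normalization accepts ASCII hyphen, en-dash and Unicode minus, and
strips thousands separators. Duplicated gene labels (two tRNA-Ala, the
Leu/Ser isoacceptor pairs) get ordinal suffixes in genomic order.

## Composition and skews

GC-skew = (G − C)/(G + C) and AT-skew = (A − T)/(A + T) are
scale-invariant, so counts and percentages give identical values; both
entry points exist. Region profiles (PCGs, rRNA, tRNA, control) pool each
feature's strand-oriented sequence — the reverse complement for
minus-strand genes — with a flag to count the heavy strand as annotated
instead; `genome` counts the raw heavy strand. Ambiguity codes are
excluded from counts and denominators. Percentages are conventionally
reported to 2 decimals and skews to 5, matching table formatting; stored
values are unrounded. Skew-column labels sometimes printed with a `%`
sign are treated as the unitless ratios they are.

## Codon analysis

The genetic code is fixed to NCBI translation table 2 (vertebrate
mitochondrial: AGA/AGG stop, ATA = Met, TGA = Trp). Stop tokens are
TAA/TAG/AGA/AGG (3 nt) and the incomplete TA- (2 nt) and T- (1 nt)
completed to TAA by polyadenylation of the mature transcript; the
amino-acid count of a gene is `(size − stop_length)/3`, and a
non-integral result raises a frame-inconsistency error — which is exactly
how the broken annotation row above surfaces. Accepted start codons are
ATG and GTG (COXI). RSCU families are defined by amino acid under table
2 (Met is the two-fold ATG/ATA family); stop codons are excluded; a
zero-count family gets RSCU 0 for all members and is flagged rather than
dividing by zero. RSCU is computed per species, not pooled.

## The TDRL engine

A round duplicates a contiguous block in tandem (copy inserted
immediately after the original) and then deletes a set of copies,
indexed against the post-duplication order; every distinct gene letter
must survive each round. The search space deliberately includes *any*
contiguous block and *any* loss subset, although published
reconstructions use whole-cluster copies: a minimality claim is only
meaningful over the full event space. The cluster is treated as linear
between its anchors, and strand is carried through duplication but
ignored in pattern matching.

Scenarios that differ only in deletion timing are identical in outcome,
so the engine canonicalizes to latest-possible deletion: a non-final
deletion is postponed into the next round exactly when the surviving
copy would fall outside the next round's block (inside the block it
would be re-duplicated, changing the outcome). The transform is iterated
to a fixed point, each step replay-asserted, and the enumeration is
deduplicated on canonical forms; results sort by total losses, then
lexicographic event encoding. Minimum-round search proceeds breadth
first over round counts; reachability is decided by a subsequence test
over duplicated expansions before any enumeration is attempted. Cost is
exponential in rounds: two rounds on a five-gene cluster enumerate in
well under a second, three rounds are tractable only for short orders
(the module documents this; the study's reconstructions need at most
two).

Because letter identity is arbitrary, scenario structure is invariant
under alphabet relabeling (tested); verifying the engine against a raw
subset-enumeration oracle on one distinct-letter source per length
therefore covers all sources of that length.

The packaged reconstructions derive WYANC and WNCYAC from WANCY by one
whole-cluster duplication each, and WNCYAA by two duplications — the
second copying a block of the eight-gene intermediate — with the loss
sets spelled out as explicit event lists. Replay of each yields its
pattern, and the exhaustive search confirms one round is minimal for
WYANC/WNCYAC and two for WNCYAA (no single duplication can place two
Ala copies after Tyr, since deletions never reorder).

## tRNA pair classification

Pairs are classified by unordered nucleotide set — {A,U}/{G,C}
Watson–Crick, {G,U} wobble, {A,C}, else "other" — so the partition is
exhaustive and endpoint-symmetric. DNA input is transcribed to U first.
Structure *prediction* is out of scope: the module consumes dot-bracket
structures (the published per-species wobble/A-C tallies depend on an
external predictor plus the deposited sequences, and are therefore not
reproduced here). All annotated pairs are counted, not just particular
arms.

## Parsimony and the permutation test

Minimum state changes are computed with Hartigan's majority-vote
generalization of the Fitch algorithm: children's state sets vote, the
node keeps the majority states, and steps increase by
(children − max vote). The more familiar iterated pairwise
intersection-else-union rule was considered and rejected because it is
not exact on multifurcations — on a four-tip star with states A,A,B,B it
reports 1 change where the true minimum is 2 — and the packaged topology
contains multifurcations at its unresolved nodes. Exactness is verified
against a brute-force enumeration of all internal labelings, including
that counterexample and the 16-taxon study topology (3 steps for the
rearrangement character).

The clustering test permutes the tip-state vector uniformly and reports
the add-one estimator p = (1 + #{perm steps ≤ observed})/(1 + n_perm),
reproducible under a fixed seed and never exactly zero; a constant
character returns p = 1 with a warning. Depth classes are binary —
shallow (<30 m) versus deep (>100 m), with intermediate depths mapping
by the 100 m threshold — and the concordance flag is set when each
cluster pattern co-occurs with exactly one depth class.

The topology itself is an *input*: tree inference from sequence data is
external to this package, so the family phylogeny ships as a newick
fixture encoding the clades described for the study taxa, with
unresolved relationships as multifurcations and branch support not
reproduced.

## Synthetic generator

The generator emulates the statistical structure of an annotated
snailfish mitogenome: the canonical vertebrate gene order with a
configurable ND2–COI cluster (a duplicated letter yields the 23-tRNA,
38-gene configuration), PCG sizes and incomplete-stop classes matching
the family's annotation (≈11.4 kb of coding sequence), rRNAs of 944 and
1688 bp, cloverleaf tRNAs of 70–74 bp with 21 stem pairs, a 37 bp O_L
inside the cluster, and a control region absorbing the remainder of the
requested genome length (default 17 kb; an error below 100 bp of slack).

Numerical choices worth noting:

* **Balanced composition realization.** Region sequences and the PCG
  codon pool are built as shuffled multisets whose counts match the
  target proportions by largest-remainder rounding; only the arrangement
  (and the assignment of fractional leftovers) is random. Recovered
  composition therefore differs from the target by O(1/length) rather
  than binomial noise, and GC-skew targets are recovered to well within
  ±0.02 at coding scale. Default proportions per region are taken from
  the measured composition of the shallow-water genome (the deep-water
  table's PCG row does not sum to 100 and was not used); all proportions
  are renormalized to 1.
* **Codon sampling.** The sense-codon distribution is an independent
  per-position base model fitted by iterative proportional scaling so
  that its *pooled* base marginal matches the region target despite the
  exclusion of stop codons; an optional within-family concentration
  exponent sharpens or flattens synonymous bias without changing family
  masses. Start (ATG, GTG for COXI) and stop bases are then overlaid, so
  coding composition is perturbed only at the ~0.7 % level.
* **tRNA structures.** Each tRNA plants the requested number of G-U and
  A-C pairs at uniformly chosen stem slots (feasibility checked against
  the 21 available pairs; defaults 1 G-U, 0 A-C per tRNA), fills the
  remaining slots with Watson–Crick pairs weighted by the composition
  target, and writes the standard anticodon into the anticodon loop.
  Dot-bracket structures are emitted alongside. Because stems and
  anticodons constrain the sequence, the tRNA region is excluded from
  target-recovery checks; ledger-exact recovery still holds.
* **Determinism.** One `numpy` generator seeded by the spec drives all
  draws in a fixed documented order (codon pool, rRNAs, tRNAs in genomic
  order, O_L, control region), so a given seed is byte-stable.

The ledger records *realized* quantities — per-region base counts in the
strand-oriented convention, per-PCG amino-acid counts and codon tokens,
per-tRNA planted pair counts and structures, the cluster pattern — so
recovery tests compare integers exactly and proportions at stated
tolerances. Generated records pass the validator with an empty report by
construction.

What passing these tests shows: the pipeline recovers every parameter
the generator controls, at the sizes stated. What it does not show: the
generator has no annotation noise, no sequencing error, no real codon
autocorrelation or rRNA secondary structure, uniform spacers (abutting
genes), and its tRNAs are a stylized cloverleaf — conclusions about
messy real annotations still rest on the validator and on the packaged
published tables.

## Pipeline

`run_pipeline` executes parse → validate → stats → codon → cluster →
TDRL → phylo; stages needing sequence are skipped for coordinate-only
records and the phylo stage is skipped (with a logged notice) when no
tree is configured. Outputs are pure functions of config + seed; the
manifest lists SHA-256 hashes of every output, and repeated runs of the
same config produce identical manifests. Defaults mirror the study's
scale: TDRL `max_rounds=2`, permutation `n_perm=999`. CLI exit codes:
0 success, 2 validation violations present, 1 error.

## Verification scale

Oracle comparisons run at sizes chosen to keep the default suite fast
(~10 s): full two-round TDRL equivalence against subset enumeration for
2-letter sources, sampled for 3-letter sources and the 5-letter one-round
frontier (relabeling invariance extends coverage across letterings);
brute-force parsimony on trees up to 10 tips and on the 16-taxon fixture
topology; generator recovery across 20 seeds at full genome size.

## Known limitations

Three-round TDRL enumeration is exponential and practical only for short
clusters. The GenBank adapter covers the common single-record
mitogenome layout (CDS/tRNA/rRNA/D-loop/rep_origin, origin-spanning
`join`), not arbitrary flat files. The permutation test conditions on
the observed state multiset; it is a clustering test, not a test of any
particular evolutionary model. Habitat-depth classes are a coarse
binary; the underlying depth ranges overlap in reality.
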