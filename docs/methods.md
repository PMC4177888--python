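# Methods

## Problem and model

A kinase's subfamily is determined from its catalytic-domain sequence;
its non-kinase domain complement is expected to be the subfamily's
canonical architecture.  `kinout` formalizes the exceptions.  Given a
subfamily assignment s and an observed architecture A (the ordered list
of assigned domains), the verdict is:

* **canonical** if A matches a registered template of s;
* **hybrid** if A instead matches a template of some other subfamily
  (all matching subfamilies are recorded as sources; *single-domain* if A
  is the bare kinase domain, *multi-domain* otherwise);
* **rogue** if A matches no registered template.

Template matching is repeat-aware: maximal runs of identical adjacent
domain names in A are collapsed to (name, count) and aligned
token-by-token with the template, each count constrained to the token's
repeat range (so `Pkinase+EF-hand{2,4}` accepts 2, 3 or 4 EF-hands).
Every template contains exactly one kinase-domain token; which domain
names count as "the kinase domain" is part of the registry.

## Pipeline stages and thresholds

| parameter | default | meaning |
|---|---|---|
| `min_len` | 200 residues | candidate sequences must be strictly longer (the kinase domain itself is 200–300 residues) |
| `max_evalue` | 1e-4 | per-domain (independent) e-value ceiling for subfamily-profile hits |
| `min_coverage` | 0.70 | profile coverage floor, `(hmm_to − hmm_from)/profile_len` |
| `min_identity` | 0.30 | alignment identity floor for subfamily assignment (boundary inclusive) |
| `domain_evalue` | 0.01 | e-value ceiling for Pfam-style domain hits used in architectures |
| `max_overlap` | 10 residues | tolerated overlap between accepted domain hits |
| `min_overhang` | 100 residues | N/C-terminal unassigned stretch worth flagging |
| `insert_window`, `nq_threshold` | 50, 0.40 | low-complexity scan window and N+Q fraction flag level |
| `cut_fraction` | 0.25 | dendrogram cut as a fraction of the maximum Ward merge height |
| `word_length` | 5 | LMS word length |

Identity for subfamily assignment is computed from the search alignment:
the hit's aligned sequence stretch is compared position-by-position with
the matching stretch of the profile consensus (no re-alignment), which
makes the assignment reproducible from the hit table plus consensus
sequences alone.  When several profiles pass 30%, the highest identity
wins, ties broken alphabetically.  Envelope coordinates are used for
architecture building and alignment coordinates for identity; all
internal coordinates are 0-based half-open, converted at the parsers.

The catalytic-loop scanner reads the consensus HRDLKxxN with the
catalytic Asp at window position 3 and the paired Asn five residues
after the Asp (as in PKA's HRDLKPEN).  D and N are mandatory; H/R/L/K
matches are counted (up to 6 with the mandatory pair) purely to rank
competing windows — substitutions there are observed in functional
kinases and are never grounds for exclusion.  Ties go to the leftmost
window.  Sequences without any qualifying window are excluded from the
dataset as likely inactive.

Overlap resolution follows "longer span and better e-value": hits are
ranked by span length, then e-value, then start position, and accepted
greedily when they overlap no accepted hit by more than `max_overlap`
residues.  Nested hits always conflict.  The greedy order makes the
result deterministic and independent of input order.

## Local Matching Score

The LMS formula family is fixed as:

* window score of a 5-mer = Σ BLOSUM62 M[i,i] over its residues;
* `raw(s)` = Σ window scores over all overlapping windows of s;
* `pair(a,b)` = Σ scores of windows of a whose word occurs verbatim in b,
  plus the symmetric term — each window counts at most once regardless of
  how often its word occurs in the partner, which guarantees
  `pair ≤ raw(a) + raw(b)`;
* `D(a,b) = 1 − pair(a,b)/(raw(a)+raw(b))`.

D is symmetric, 0 on identical sequences, 1 when no 5-mer is shared, and
always in [0, 1].  It is *not* monotone under appending shared words: the
four boundary-crossing windows created by an append can grow the
denominator faster than the matched score grows the numerator, so adding
a shared word can slightly raise D in adversarial cases; what does hold
(and is tested) is that the matched pair score gains at least the
appended word's window score.  Ambiguous residues (X) score +1 on the
diagonal so that window scores stay positive and the [0, 1] range is
preserved.  The indexed implementation (per-sequence 5-mer set) is
tested for exact equality against a naive window-by-window double loop.

## Clustering and entropy

Ward linkage runs on the LMS distance matrix via the Lance–Williams
update on squared dissimilarities (scipy's `linkage(..., "ward")`);
heights are square roots of the Ward costs and non-decreasing, and the
merge structure is verified against a from-scratch Ward implementation
that recomputes all cluster-pair costs each step.  Ties in merge costs
are broken by scipy's nearest-neighbour chain rather than an explicit
smallest-index rule; on continuous LMS distances exact ties do not occur
in practice.  Because Ward heights are not on the [0, 1] distance scale,
"cut at 0.25" is interpreted as 25% of the maximum merge height; an
absolute-height mode is available for callers who want the literal
value.  Cluster purity is the normalized Shannon entropy
E = −Σ p(i) ln p(i) / ln(k_total) with k_total defaulting to the number
of subfamilies observed in the run (configurable; a proteome-scale study
over the full subfamily catalogue would set it to that catalogue's
size).  E is 0 exactly for single-subfamily clusters and 1 for a uniform
mix of all k_total subfamilies; clusters with E = 0 are marked ignorable
for outlier validation.

## Synthetic kinome

The generator stands in for proteome downloads and profile searches.
Each subfamily gets an independent random 250-residue kinase-core
consensus (uniform over the 20 residues) with HRDLKPEN spliced at the
core midpoint, and a canonical template over an inner domain pool;
subfamily 1 is always the bare-kinase-domain subfamily and subfamily 2
always carries `EF-hand{2,4}`, so both single-domain-hybrid and
repeat-matching paths are exercised.  An outer pool of domain families
appears in no template and feeds rogue events.  Per sequence: the core
is point-mutated at 5% (motif window spared), the canonical complement
is instantiated, and events are planted at the configured rates — hybrid
(copy a donor subfamily's whole complement), rogue (splice one
outer-pool domain into the own complement), overhang (100–180 random
terminal residues), and in plasmodium mode a 60–90-residue poly-N/Q
stretch inside the kinase domain downstream of the motif.  Inter-domain
linkers are 5–25 residues and plain termini at most 30, keeping
accidental overhangs impossible.  Hit rows carry exact coordinates with
e-values sampled between 1e-8 and 1e-40 and full profile coverage, so
the threshold logic is exercised by dedicated boundary fixtures rather
than by the mass generator.  One RNG stream per sequence, seeded from
(seed, index), makes outputs byte-identical under a fixed seed and
stable under changes of n.

What the generator does **not** emulate: indels and length variation
inside domains, homology between subfamily cores (real kinase domains
share the fold and ~20–40% identity across subfamilies; synthetic cores
are mutually random), search-tool score distributions, alternate
splicing, and partial domain decay.  Passing the planted-event tests
therefore shows that the decision logic is correct on clean inputs, not
that real hmmscan output at these thresholds is noise-free.  In
particular, clusters of the synthetic kinome are much better separated
than the real clusters behind the entropy analysis, which is why the
enrichment claim is asserted as a mean comparison (outlier fraction in
E>0 vs E=0 clusters) rather than per cluster: a single-domain hybrid or
a rogue legitimately stays nearest its own catalytic subfamily and can
land in a pure cluster.

## Sizes and numerics

The default validation runs use 200 sequences from 10 subfamilies
(hybrid rate 0.10, rogue rate 0.025, seed 42) — enough for every event
type to appear repeatedly while the full LMS matrix (19 900 pairs) and
Ward tree compute in seconds; rate-convergence checks use n = 2000.  All
LMS arithmetic is integer until the final division, so the
indexed-vs-naive equality is exact.  Degenerate inputs are defined
explicitly: empty architectures are allowed (they classify as rogue and
have no overhangs), spans shorter than the insert window yield no insert
reports, and entropy requires at least one member and k_total ≥ 2.

## Known limitations

* The registry ships no transcription of the literature's canonical
  architectures; users supply their own registry TSV/JSON (the toy
  registry is generated, not curated).
* Identity from ungapped alignment-column comparison understates
  identity when the true alignment contains indels; with real search
  output, supply the tool's own identity (RPS-BLAST tables carry one).
* Single-kinase-domain templates make any bare kinase domain a hybrid
  candidate for *every* such subfamily; sources list them all, and
  interpretation is left to the caller.
* Sequences with long unassigned regions are labelled on assigned
  domains only; overhangs are reported separately rather than suppressing
  the single-domain verdict.
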