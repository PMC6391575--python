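# Methods

This note documents the model implemented by `mirslot`, the defaults it
ships with, what the synthetic-data generator does and does not emulate,
and the numerical conventions that make results reproducible.

## Slot scheme

Recognition is driven by a hierarchical scheme of lexical *slots*. The
bundled default (`src/mirslot/data/default_scheme.txt`) covers the slot
inventory documented for miRNA nomenclature:

| slot | kind | content | notes |
|---|---|---|---|
| Species | closed | hsa, cel | organism prefixes |
| Precursor | closed | pre, pri | precursor markers |
| miRNA | closed | mir, mirna, microrna, micro rna, let, lsy | indicator words |
| Let | closed, child of miRNA | let, lin | lethal-7 / lin-4 indicator family |
| Order | open | `^\d{1,4}[a-z]{0,2}\d?$` | numbering strings: 21, 181b, 16a1, 128c |
| Conj | closed | and, or | list conjunctions |
| Suffix | abstract parent | — | generalizes the two below |
| Hairpin | closed, child of Suffix | 3p, 5p | hairpin arm |
| Loci | open, child of Suffix | `^[1-9]$` | genomic locus digit |
| Prefix | closed | oncomir, anti | miscellaneous prefixes |

Matching is case-insensitive throughout (terms are case-folded on load),
and multi-token terms (`micro rna`) are matched greedily longest-first.
Hierarchy is generalization-only: a token matched by `Hairpin` is also
reported under `Suffix`, never the reverse. A token may carry several
labels (`5p` fits both the `Order` pattern and the `Hairpin` term list);
ambiguity is resolved only where a single label is needed — at principle
extraction — by preferring descendants over ancestors, closed-class over
open-class, then scheme declaration order. That rule reproduces the
published slot table: `5p` extracts as a suffix, `16a1` as an Order,
`let` as Let.

The published systems' full term lists are not public; the default
scheme deliberately contains only slots and terms that are documented.
Users extend it by editing the plain-text scheme file (one `SLOT` header
plus indented terms per block).

## Tokenization

All counts downstream depend on one pinned convention: split on
whitespace, then split off each of `- , / ( )` as a single-character
token (`miR-16-2` → `miR / - / 16 / - / 2`). Offsets are 0-based,
half-open. Sentence splitting is a simple terminal-punctuation rule;
both are deliberately minimal — no POS tagging is used anywhere.

## Principle induction

Every gold mention whose span aligns to token boundaries yields a
*principle*: the ordered sequence of (single, disambiguated) slot labels
inside the span, unlabeled tokens dropped. Identical sequences merge
with summed support, and each principle remembers which non-slot words
(`-`, `,`, `/`) its source mentions contained.

Principle *p* dominates *q* when *q* is derivable from *p* within the
IDS edit budget (insertions/deletions/substitutions at the slot level,
order preserved). Defaults: deletions ≤ 4, insertions = 0,
substitutions = 0 — a dominant may only omit slots, and 4 is the
smallest deletion budget under which the documented 7-slot dominant
`[Precursor][Species][miRNA][Order][Conj][Order][Suffix]` derives all
of its documented dominated principles (deriving `[miRNA][Order][Suffix]`
drops Precursor, Species, Conj and one Order). The budget is
config-exposed (`IDSCriteria`).

The summary cover is greedy: repeatedly select the vertex dominating the
most not-yet-covered vertices (ties: higher support, longer sequence,
lexicographic — fully deterministic), mirroring the standard
approximation for the NP-hard minimum dominating set; tests verify the
greedy cover stays within the (1 + ln n) factor of an exhaustive
minimum on small random graphs. Every selected vertex becomes a cluster
dominant together with *all* principles it dominates, so a principle may
belong to two clusters; recognition later simply takes the best-scoring
alignment.

## Scoring

For each symbol *S* — a slot, or a non-slot word observed inside at
least one gold mention — the training corpus yields frequencies inside
(`f_mi`) and outside (`f_non`) gold spans, hence
`P_miRNA = f_mi / (f_mi + f_non)`:

* matched slot: `score_m(S) = λ · P_miRNA(S)`, with λ = 100. Bounded in
  [0, λ]; a slot that never occurs outside mentions scores exactly 100.
* insertion: `score_i(S) = 1 / H(P_miRNA, P_nonMiRNA)` (binary entropy,
  log base 2); defined as 0 when `P_nonMiRNA = 0` (inserting a
  mention-exclusive symbol is free) and +∞ when `P_miRNA = 0` (inserting
  a symbol never seen inside a mention rejects the candidate).
* deletion: `score_d(S) = −log2(score_m(S)/λ) = −log2 P_miRNA(S)`; the
  matched score is normalized by λ before the log so the penalty is
  non-negative, and deleting a mention-exclusive slot is free.

Penalties are non-negative and subtracted in the final score
(the literature convention of printing insertion scores as negative
numbers corresponds to the `−score_i` contribution here). A candidate's
score is the sum over its alignment's matched/inserted/deleted sets.

Conventions for symbols unseen in training: matched score falls back to
λ/2, insertion penalty to a ceiling (default 30) — unseen symbols must
neither silently accept nor silently reject. No smoothing by default;
a pseudo-count is config-exposed.

### Acceptance threshold

Each cluster's threshold combines, over its members:

    T = Σ score_m(core slots)
      − Σ score_d(dominant slots ∉ core)
      − Σ P(S_k)·score_i(S_k)            over optional slots
      − Σ P(NonS_l)·score_i(NonS_l)      over non-slot words

where core slots occur in every member principle, optional slots in
some, and `P(·)` is the fraction of member mentions containing the
symbol. The threshold is therefore the expected score of a typical
member mention: core matches minus the deletion cost of the parts of
the dominant a member typically lacks minus the insertion cost a member
typically pays.

The sign of the last two terms was a genuinely open design point: the
threshold formula can be read with the insertion terms *added*. But the
candidate score *subtracts* every insertion penalty, so an added-cost
threshold sits above the score of exactly those mentions it is meant to
accept — a minimal `miR-21` (two core matches, one hyphen insertion)
would fall below its own cluster's threshold as soon as hyphens carry
any penalty, and recall on noisy corpora collapses. `mirslot` therefore
defaults to subtracting the expected insertion cost
(`threshold_insertion_mode="subtract"`) and exposes `"add"` for the
literal reading. Acceptance compares `score ≥ threshold − 1e-9`; the
slack exists because for clusters whose members all share the same
insertion symbols the two sides are analytically equal and differ only
by floating-point summation order.

## Recognition

Candidate windows are anchored per indicator token (any token labeled
`miRNA`, which includes `Let` by generalization) and extended left and
right over tokens that are slot-labeled or known non-slot symbols, up to
30 tokens per side — sized so that an 8-item hyphenated conjunction list
(3 tokens per additional item, 24 tokens total) fits in one window while
still bounding cost. Each window is aligned against every cluster
dominant by DP over (token, slot) with match/insert/delete moves; ties
prefer fewer insertions, then fewer deletions, then leftmost matches
(implemented as a lexicographic DP value, verified against exhaustive
enumeration of all monotone alignments). The best-scoring alignment per
anchor is kept and emitted iff it reaches its cluster's threshold; the
reported span runs from the first to the last slot-bearing aligned
token, so stray edge punctuation is trimmed but trailing list items
(inserted Order tokens) are kept. Overlapping accepted spans keep the
higher score.

Anaphoric bare indicators ("this miR") are generated as candidates but
score one matched slot against thresholds requiring at least two core
matches, and are filtered; no co-reference resolution is attempted.

## Normalization

The lexicon is compiled from a tab-separated Rfam `family` table dump
using 1-based columns 1 (accession), 2 (family id), 4 (description) and
11 (previous names); the column map is configurable for other dumps.
Description names are pulled by a nomenclature regex with slash
expansion (`mir-103/107` → `mir-103` + `mir-107`; a letter alternative
replaces the trailing letter block: `mir-29a/b-1` → `mir-29a`,
`mir-29b-1`); `\N` cells are ignored; every name gains a case-folded and
a `-`/`_`→space variant. Entries failing the nomenclature grammar stay
retrievable through a raw-token fallback index.

Each name variant is slot-labeled and aligned against the cluster
dominants; matched (slot, value) pairs index the accession. A mention is
grounded by retrieving candidates through its own slot values and
scoring each candidate with the same alignment scorer, where a mention
token matches a name token only if they share a slot and their
case-folded texts are equal. Mentions with several Order groups split
into sub-mentions normalized independently (`miR-1/133a` returns both
families); multi-accession output is a ranked list, ties broken by
ascending accession. An index-free brute-force scorer over all entries
exists as a test oracle, and top-1 agreement is verified on lexicons of
up to 200 entries.

Rfam families are not organism-specific, so no inter-species
disambiguation is attempted; normalization to miRBase is out of scope.

## Evaluation

Strict-span micro-averaged precision/recall/F1: a prediction is a true
positive only when its (start, end) exactly equals a gold span;
normalization mode additionally requires a non-empty intersection
between predicted and gold accession sets (gold mentions may carry
several accessions, and a multi-accession gold mention counts once).
Supported corpus formats are a standoff directory (per-document `.txt` +
`annotations.tsv`) and BioC XML.

## Synthetic corpora

The generator (`mirslot.synthetic`) emulates sentence-level annotated
corpora from the mention grammar

    [Precursor]? [Species]? [indicator] [Order] ([Conj|,] [Order])* [Suffix]?

with hyphen joining, comma/`and` conjunction lists, and occasional
slash pairs. Defaults (chosen once as realistic for this genre and not
tuned): species present 50%, precursor 15%, suffix 25%, let-family
indicator 15%, conjunction-length distribution 1:0.72, 2:0.12, 3:0.08,
4:0.05, 8:0.03, slash pairs 10% of length-2 lists, 0–2 mentions per
sentence, 40 toy families. Decoy noise plants slot terms and punctuation
in filler text at a configurable rate (default 0.05), which is what
gives symbols non-zero outside-mention frequencies; a matched toy family
table in the real Rfam column layout and a manifest of expected counts
are emitted alongside, and a fixed seed makes the output byte-identical.

What the generator does *not* emulate: real PubMed sentence style,
annotation inconsistencies, abbreviation definitions, anaphora, or
mentions adjacent to each other without intervening plain words —
distinct gold mentions are always separated by at least one unlabeled
filler token, matching the convention that adjacent conjunction lists
are annotated as a single mention. Recovery scores on these corpora
(held-out strict F1 = 1.0 noiseless, ≥ 0.95 at 5% noise) therefore show
that induction, scoring and matching invert the generating grammar; they
are not estimates of performance on real literature.

## Known limitations

* Mentions joined only by a conjunction ("hsa-miR-181b and pre-miR-149")
  merge into one span, because `and` is a labeled slot and windows
  extend through it; corpora that annotate such pairs separately will
  show boundary errors.
* A slot-term decoy directly adjacent to a true mention can be absorbed
  into its span (strict-boundary error); with 5% decoy noise this costs
  roughly 2–3% F1.
* The insertion penalty 1/H grows without bound as a symbol becomes
  nearly (but not exactly) mention-exclusive; the subtractive threshold
  compensates in expectation, but rare symbols can still be over-penalized
  on small corpora.
* The bundled scheme holds only the documented term lists; real-corpus
  use requires extending Species and indicator terms.
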