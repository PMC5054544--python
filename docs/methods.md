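# Methods

## Task and model

`cidex` treats document-level chemical-induced-disease (CID) extraction as
binary classification of concept pairs. For a title+abstract document with
entity mentions normalized to controlled-vocabulary IDs (MeSH-style
descriptors), every ⟨chemical ID, disease ID⟩ combination whose IDs are both
mentioned is a candidate; a linear soft-margin SVM decides, from one merged
feature vector per candidate, whether the document asserts that the chemical
induces the disease. Relations are sets of ID pairs per document — never
mention offsets — so a relation asserted across sentences is still a single
candidate.

The decision function is f(x) = w·x + b with hinge loss and L2 penalty
(C = 1 by default). Candidates are heavily imbalanced toward negatives, so
class weights are balanced by default (each class's total weight equalized).
The decision threshold is 0 and exposed for precision/recall trading:
prediction sets are monotonically non-increasing in the threshold, which the
test suite asserts.

## The Extended Dependency Graph

Each sentence gets a graph over its tokens with three edge layers:

1. **syntactic** — collapsed dependency edges from the parse adapter,
   treated as opaque labels (`nsubj`, `dobj`, `prep_of`, `agent`, …);
2. **numbered arguments** — `arg0` (agent) and `arg1` (patient/theme) edges
   derived by rule, unifying active, passive, nominalized and participial
   realizations of a predicate;
3. **semantic** — `member-collection` (a quantifier noun such as "number"
   to its "of"-complement) and `is-a` ("X such as Y" and "X, a Y"
   appositions, distributed over conjuncts).

The numbered-argument rules, each individually switchable in `EdgConfig`:

| rule | pattern | result |
|---|---|---|
| `nsubj` | active nominal subject | arg0(verb, subject) |
| `dobj` | direct object | arg1(verb, object) |
| `nsubjpass` | passive subject | arg1(verb, subject) |
| `agent` | "by"-phrase of a passive | arg0(verb, np) |
| `xcomp_control` | subject of a verb governing an open complement | arg0(complement verb, subject) |
| `participle_premod` | "X-induced Y" premodifying participle | arg0(participle, X), arg1(participle, Y) |
| `nominal_of` | trigger nominal with "of"-complement | arg1(nominal, complement) |

One deliberate subtlety: when a verb governs an `xcomp` (raising/control,
as in "X have been found **to cause** Y"), its surface subject is rerouted
to the complement verb and *not* also attached to the matrix verb — the
matrix verb carries no semantic argument of its own in these constructions,
and leaving both edges in place would spray spurious propagated arguments
over the graph.

**Argument propagation** then rewrites arguments whose target is not the
real entity, to a fixpoint (iteration cap = vertex count; exceeding it is a
hard error, and monotonicity plus idempotence are asserted by tests):

* *collection rule*: argK(p, c) ∧ member-collection(c, g) ∧ is-a(x, g)
  ⇒ argK(p, x);
* *core-term rule*: argK(p, h) for a non-entity head h with an
  "of"-complement x ⇒ argK(p, x) ("a **case** of tardive dyskinesia") —
  excluded when h heads a member-collection construction, which the
  collection rule owns.

Propagated edges carry provenance and a reconstructable derivation chain.

## Feature families

All features live in one sparse name→value map with namespaced names; the
merge class of every feature is determined by its namespace (hard error for
unknown namespaces).

* **Bag of words** (`bow:`, bag): lemma counts of up to two word tokens on
  each side of a mention (window size 5: the mention plus 2+2), punctuation
  skipped, windows clipped at sentence boundaries, accumulated over every
  occurrence of the concept ID in the document. Chemical and disease
  contexts share the namespace. Because the bag is already
  document-accumulated per ID, it enters the pair vector once, at ID level.
* **Bag of n-grams** (`bon1:`–`bon3:`, bag): uni/bi/trigrams over the lemma
  sequence from the chemical to the disease mention within one sentence,
  each mention rendered as its concept ID (IDs discriminate entities better
  than surface strings and generalize across synonyms). Cross-sentence
  pairs contribute nothing.
* **Trigger patterns** (`pat:`, boolean, exactly four): for each trigger
  lemma — cause, induce, associate, produce (nominalized forms map back to
  the trigger) — whether the propagated graph matches
  Chemical ← arg0 ← trigger → arg1 → Disease.
* **Path walks** (`path:vwalk:`, `path:ewalk:` bags; `path:weight`
  numeric): over all minimal simple paths between the pair's vertices in
  every co-mention sentence, edges traversable both ways with traversal
  direction recorded. A v-walk renders one edge with its endpoint lemmas
  (entity vertices as generic `Chemical`/`Disease`); an e-walk renders an
  interior vertex with its two flanking labels and their orientations.
  `path:weight` = mean over paths of λ^length with λ = 0.9, decaying the
  contribution of long paths.
* **Statistical features** (`stat:`, 19 of them): mention counts per ID
  (numeric); membership of each entity in the title, first and last
  abstract sentence; same-sentence co-occurrence; two knowledge-base
  booleans (is the pair curated in a CTD-style relation list; is it
  co-indexed in MeSH-style indexing — a null KB returns false everywhere);
  and eight contextual booleans (disease-context keywords, dosage-like
  tokens, increase/decrease, p-value mentions, demographic words) evaluated
  over the same 2-token window as the bag of words. Keyword lists are
  editable config; the dosage detector is a list of units plus a
  number(+unit) regex.

**Merging.** Mention-pair-level vectors (n-grams, patterns) are merged per
concept pair: booleans by OR (never flipping 1→0 as pairs are added),
numeric singletons by arithmetic mean, bags by summation. ID-level vectors
(bag of words, path walks, statistical) are appended unchanged. Feature
names are frozen on the training set; unseen names at prediction time are
dropped. No hashing; optional min-max scaling of numeric features exists in
config and is off by default.

## Parsing and the adapter contract

Sentence splitting: the title is always one sentence; the abstract splits
after sentence-final punctuation followed by whitespace and a
capital/digit/bracket, with an abbreviation stop-list; any boundary that
would cut a mention in two is merged away. Parses come through an adapter
protocol — tokens (text/lemma/POS) aligned to the sentence text by
character offsets plus labeled head→dependent edges. The packaged adapter
reads sidecar files (`#sent`/token lines/`#edge`), which is also the format
the synthetic generator emits; `#edge` lines let gold numbered-argument or
semantic edges be injected for fixtures. Alignment failures are hard
errors. No live parser ships with the package; the feature layer only
depends on the edge/label contract.

## Distant supervision

`build_weak_corpus` turns a curated ⟨doc, chemical, disease⟩ table plus raw
abstracts into weak training documents: mentions are recovered by
case-insensitive longest-match dictionary look-up over word boundaries
(optionally merged with an external tagger's mentions — exact-duplicate
spans prefer the tagger, overlapping spans keep the longer); a curated row
is kept only if both IDs actually appear among the document's mentions;
documents retaining no relation, and documents in the gold-corpus exclusion
list, are dropped. Retained rows become positive labels; all other
candidate pairs in the document are negatives. Shrinking the dictionary can
only shrink the retained relation set (asserted by a test).

## The synthetic generator

The generator emulates the *structure* of CID abstracts, not their prose:
documents are assembled from templates that emit their own parses, so the
whole pipeline runs deterministically with no external parser or download.
Defaults (chosen once as a plausible desk-scale regime): 2–3 chemicals and
2–3 diseases per document from a 30+30 vocabulary with reserved synthetic
ID prefixes (SC…/SD…); a fraction p_positive = 0.35 of candidate pairs are
true relations; p_trigger = 0.9 of those are expressed by a trigger
construction (uniformly: active, collection, core-term, participle
premodifier), the rest asserted across sentences; p_distractor = 0.5 of
negative pairs surface as treatment sentences ("X effectively treated
patients with Y"), the classic precision trap for co-occurrence systems.
Identical configs give byte-identical corpora.

ID corruption (`corrupt_table`) emulates normalization noise on the curated
rows: at the given rate a row's disease ID is replaced by a uniformly
random other disease ID from the vocabulary. Most corrupted rows fail
grounding and drop out; a minority ground spuriously and genuinely mislabel
a document — the realistic failure mode of distant supervision.

What the generator does **not** model: lexical variety, multi-token entity
names (covered instead by hand-parsed demo documents), parser errors,
hedging and negation, abbreviations, document length variation. Passing
tests on synthetic corpora therefore demonstrate pipeline correctness and
the learnability of the encoded distinctions — not performance on real
abstracts, which depends on NER quality and parse accuracy outside this
package's scope.

## Numerical and engineering choices

* λ = 0.9, n-gram order ≤ 3, window radius 2 are the package defaults and
  are asserted as configuration contracts.
* Shortest-path search collapses parallel edges between a vertex pair to
  the highest-priority layer (numbered_arg > semantic > syntactic) before
  enumeration: a derived argument edge subsumes the syntactic edge it was
  read off, giving one canonical path per semantic configuration. All
  minimal paths are kept (no tie-breaking); walk features are unioned and
  λ^length averaged over them. Correctness is checked against exhaustive
  DFS enumeration on 500 random graphs of ≤ 8 vertices.
* Multi-token mentions are anchored at their head token (the token whose
  governor lies outside the span; fallback: last token).
* Mentions that fail normalization keep the sentinel ID `-1`, stay on the
  document, and are excluded from candidate generation.
* Ambiguous dictionary names yield composite mentions carrying all IDs of a
  type (each ID participates in candidates separately).
* Training is deterministic under a fixed seed (liblinear with fixed
  `random_state`, tol 1e-4, max_iter 5000); the model archive is JSON
  (feature names, weights, config snapshot) and reloads with bit-identical
  decision values. Weak instances can be down-weighted
  (`weak_weight` < 1); the default 1.0 is plain concatenation.
* Scoring is micro-averaged over documents; 0/0 ratios are reported as 0
  with an `undefined` flag rather than raising.

## Experiment sizes

The packaged experiments (`cidex.experiments`, also driven by
`scripts/acceptance.py`) use 200 training, 50 test and 200 weak-source
documents per seed, five seeds per run — sizes at which one full
generate→parse→featurize→train→score cycle takes about two seconds on one
CPU while leaving several hundred positive pairs per corpus.

## Known limitations

* The numbered-argument rule inventory is a small concretization tuned to
  the constructions above; real text contains argument realizations
  (clefts, relative clauses, coordination of predicates) it does not cover.
* EDGs are strictly per-sentence; cross-sentence relations are reachable
  only through document-level statistical features, not through paths.
* Dictionary matching is exact on synonym strings; no stemming, spelling
  variation, or abbreviation expansion.
* The two-classifier architecture (separate sentence- and document-level
  models) is deliberately out of scope; this package trains one unified
  model per the design it implements.
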