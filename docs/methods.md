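# Methods

This note records the models and procedures `pwmap` implements, the
defaults it ships, the design decisions taken where the design was open,
and what the synthetic studies do and do not demonstrate.

## Problem setting

A pathway ontology supplies classes with a canonical name, synonyms, an
optional free-text definition and two hierarchies (*subclass*, *part-of*).
A pathway database supplies records with names, an optional definition and
optional parent/child links. The task is, for each record, to recommend a
short ranked list of ontology classes for a curator to review. The package
treats recommendation as binary classification over (record, class) pairs,
using only descriptive text — never the pathway's internal
entity/reaction graph, which is out of scope by design.

## String representation and lexical stage

Every entity is flattened to one string: names, then the definition, then
the canonical names of direct parents (both hierarchies for classes), then
direct children, space-joined. The fixed segment order makes tokenisation
and idf weighting reproducible; only *direct* relatives contribute —
transitive closure would blur the hierarchy signal and was deliberately not
used. Unresolvable relative ids are skipped with a logged warning.

Tokenisation lowercases, splits on non-alphanumeric runs and adds
within-word character n-grams for n ∈ {3, 4, 5}, namespaced (`"3#aci"`) so
they cannot collide with word tokens. The idf is the smoothed
`ln(N_docs/df) + 1`, strictly positive so the weighted-Jaccard denominator
never vanishes; tokens unseen in the corpus look up the maximum
`ln(N_docs) + 1` (maximally rare). The candidate selector keeps the top
k = 20 classes by summed idf of shared tokens; ties everywhere break by
ascending identifier so runs are deterministic. Selector scores are
recomputed per hit in a canonical (sorted-token) summation order, making
them bit-identical to a direct brute-force evaluation — a property the
test suite exploits.

The bag-of-words baseline emits classes whose idf-weighted Jaccard reaches
a threshold fitted by grid search (0.01..0.99, step 0.01) maximising F1 of
the positive class, smallest threshold on ties. The comparison is
inclusive (≥), resolving the ambiguity toward recall. F1 was chosen as the
grid objective because the fitted pairs are heavily negative-skewed and
accuracy would saturate.

## Training pairs

Positives are existing curated mappings, deduplicated, with unresolvable
rows dropped and counted. Per ontology class, 2 "easy" negatives are drawn
uniformly from the database and 2 "hard" negatives from the top of a
*reverse* candidate selector (pathways indexed, class as query — the
mirror of the prediction-time direction), always excluding that class's
positives; fewer are returned when the database is exhausted. When a pair
arrives with both labels the positive wins. Distant-supervision pairs
(e.g. GO–MeSH term mappings) enter as plain text bundles under their own
source tag, never resolved against the ontology.

## Bootstrapping

A logistic-regression model over five symmetric lexical features — the
normalised word-count difference `|p−q|/max(p,q,1)`, word-token Jaccard,
and character-n-gram Jaccard for n = 3, 4, 5 — is refit each round on the
cumulative training set and scored over every (pathway, top-20 candidate)
pair of the target database. The `ceil(0.0025 · pool)` highest- and
lowest-scoring pairs not already in the training set join it as positives
and negatives; 10 rounds by default. Ceiling rather than floor keeps tiny
fixtures bootstrapping. The pool is the candidate pairs, not the full
m × n cross product: blocking bounds the cost and matches how the selector
is used at prediction time. Candidate lists and features are cached across
rounds (they do not depend on the training set).

## Neural matchers

Both matchers share one shape: encode each text to a fixed vector,
concatenate the two encodings, two fully connected layers (rectifier, then
a single logit), sigmoid.

* **Name model** — a name is the sum of its word embeddings
  (order-insensitive; empty or all-unknown names encode to zeros).
* **Definition model** — a shared (siamese) BiLSTM, hidden size H = 100
  per direction; the final forward and backward hidden states concatenate
  to a 2H = 200-d encoding, matching the embedding width. Sequences are
  truncated at 256 tokens; an empty definition encodes to the zero vector.

Embeddings are a pluggable input in the standard word-vector text format —
either one 200-d table or two 100-d tables concatenated token-wise (the
dual word2vec/fasttext construction); they stay frozen during training.
Unknown tokens map to the zero vector: the simplest contract, and the
reason typo-corrupted synthetic tokens carry no signal in the name model.

The layers are implemented directly on NumPy (dense layers, masked batched
LSTM with backpropagation through time, Adam) and the backward pass is
verified against central finite differences in the test suite. Defaults:
Adam at lr 1e-3, batch 32, ≤50 epochs, Glorot initialisation, LSTM forget
bias 1. Training minimises binary cross-entropy; after each epoch the
development-set recall at threshold 0.5 is evaluated and the best-recall
snapshot (ties by lower dev loss) is returned — recall-oriented model
*selection* rather than loss re-weighting, because in a curation pipeline
a missed true mapping costs more than a spurious candidate. The 90/10
train/dev split is stratified by label and seeded. Non-finite loss raises
immediately, naming the epoch.

## Score combination and output

For a candidate pair, every (pathway name, class name) combination is
scored and `S_total = 0.75 · max(S_name) + 0.25 · S_def`. The weights
favour names deliberately — definitions are often missing or generic — and
are config-exposed. **Missing-definition contract:** when either side has
no definition, `S_total = max(S_name)`; the weights renormalise onto the
name term so undocumented pathways are not penalised. The output threshold
is 0.25, inclusive; predictions are grouped per pathway in input order and
ranked by descending score, ties by class id.

## Evaluation

*ppm* counts yes-or-related grades over all graded recommendations; *rpp*
counts pathways with ≥1 yes-or-related grade over the whole pathway
universe (pathways with no recommendations stay in the denominator);
*yield* counts pathways with any recommendation. "Related" means a parent,
child or sibling of a true class — graph distance 1 plus siblings, exactly.
Cohen's kappa is unweighted over the three nominal categories, computed
from the 3×3 contingency table; degenerate marginals (chance agreement 1)
raise. Reported values round half-up to 2 decimals.

## Synthetic corpus

The generator emulates the curation setting end to end. A tree-shaped
subclass hierarchy is grown from a packaged vocabulary of synthetic
biomedical-sounding tokens (stem × suffix combinations, grouped with 0–2
morphological synonyms); each child's name extends its parent's with one
fresh specialiser token, so names share tokens along the hierarchy as real
ontology names do. Classes get 0–2 synonym-substituted aliases and a
templated definition. Pathway records derive from classes by per-token
perturbation — synonym substitution, dropout (the most specific token is
never dropped), adjacent-character typos — and definitions by
synonym-substitution paraphrase, present at a configurable rate. Token
embeddings place synonym groups around shared centroids (within-group
cosine > 0.9, unrelated tokens near-orthogonal at 200 dims). Curator
grades are simulated exactly from the known truth and the hierarchy.

The default study corpus is 150 classes with two databases: `source` (one
pathway per class, half noise) supplies the curated training mappings, and
`target` (two per class, 300 pathways, full noise) is mapped and evaluated
against held-out truth. "Moderate" noise is synonym 0.3, dropout 0.15,
typo 0.1, paraphrase 0.3, definition presence 0.8 — enough that exact
string matching starts failing while names remain recognisably derived.
The pipeline default of 30 name-model and 15 definition-model epochs keeps
a full run at this scale to well under a minute while both matchers
plateau on the development set.

What the synthetic studies show: that each stage implements its contract,
and that the pipeline reproduces the qualitative precision/recall division
of labour between the lexical baseline and the neural pipeline. What they
do not show: performance on real ontologies and databases. Synthetic
definitions are short and templated (no long-range syntax for the BiLSTM
to exploit), synthetic embeddings carry only synonym geometry (no broader
semantics), and noise is independent per token (real synonymy is
phrase-level). Absolute metric values on the synthetic corpus therefore do
not transfer to real data; directions and invariants do.

## Known limitations

* Only descriptive text is used; records whose identity lies in their
  reaction content cannot be matched.
* The name model ignores word order, so anagram-like name pairs are
  indistinguishable to it.
* The bag-of-embeddings + concatenation architecture generalises similarity
  poorly from few training pairs when token overlap between training and
  test vocabulary is low; it relies on shared vocabulary, which the
  curation setting (one ontology on both sides) provides.
* Distant-supervision pairs are trusted as labelled; no noise model is
  applied to them.
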