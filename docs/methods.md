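# Methods

## The procedure

`slanglex` treats colloquial-synonym discovery as generate-and-validate.
For each eligible index term (a drug's generic name), one *iteration*
is: uniformly sample three known synonyms from the usable seed-lexicon
categories, render them into a numbered-list prompt ending in a hanging
enumerator ("4."), request a completion, parse the continued list into
candidate terms, and normalize them. Across `n_iterations` (default
1000) the candidates are tallied per term; the tallied vocabulary is
then validated by the drug-name, search, and (optionally) frequency
filters. Terms passing the drug-name and search filters form the
published lexicon; those additionally absent from the seed lexicon are
the novel yield (UNGS).

Two prompt templates are supported. The plain template lists three
seeds; the counterexample template first lists four hand-picked
non-synonyms (typically same-indication drugs), then two seeds, ending
in a hanging "3.". Counterexamples are configured per index term and
never selected automatically.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_iterations` | 1000 | completions per index term; yield grows sublinearly as common terms repeat |
| `temperature` | 1.0 | likelihood-vs-diversity trade-off in [0, 1]; higher yields more unique terms |
| `frequency_penalty`, `presence_penalty` | 0.0 | repetition penalties in [−2, 2] |
| `max_tokens` | 256 | completion budget; fits the ~7 list items a completion typically carries |
| search `max_depth` | 10 | results scanned per query variant; deeper hits are mostly noise |
| variants | `"", pill, drug, slang` | appended keywords that pull polysemous slang into a drug context |
| `match_mode` | substring | case-insensitive; tolerates inflections like "alprazolam-based"; whole-word available |
| frequency threshold | 1 | strictly-greater-than semantics: threshold 1 removes terms generated once |
| eligibility | ≥ 3 usable seeds | below that the prompt cannot be filled |
| widely-discussed cutoff | 10,000 forum hits | flags the high-interest subset; informational only |
| scheme | drug_name + google | the published-lexicon designation; frequency filter off because true synonyms occur at every frequency |

## Numerical and design choices

* **Normalization** is lowercase, trim, and removal of trailing `.,;`
  characters. All trailing marks are stripped (not just one) so that
  normalization is idempotent — a property the tally logic relies on;
  for realistic list items the two rules coincide.
* **Parser grammar.** The completion, prefixed by its hanging
  enumerator, is split on newlines; `N.`/`N)` lines yield items, blank
  lines are skipped, and parsing stops at the first non-blank,
  non-numbered line (models append prose). Unparseable completions
  yield an empty list, never an error; failed iterations still count
  toward `n_iterations` so runs remain cost-bounded and comparable.
* **Search depth is 1-based and per-variant**, not cumulative across
  variants; the recorded depth is the rank within the matching
  variant's own results. Searching for a term stops at its first hit.
* **Memoization** is per (term, variant) → depth-or-miss, persisted as
  TSV with a bit-exact round-trip. A hit depends on which index term
  was looked for, so the pipeline keeps one cache file per index term.
* **Determinism and resumability.** Per-iteration randomness derives
  only from `(run seed, index term, iteration)` via a CRC-keyed seed
  sequence, so an interrupted run resumed from its generation log and
  search cache reproduces an uninterrupted run byte-for-byte with
  deterministic backends. Quota exhaustion checkpoints state and
  raises a distinct, resumable error.
* **Name matching** between the controlled list and index terms is
  exact case-insensitive equality after trimming; no fuzzy matching of
  salt/ester qualifiers ("… hydrochloride"), which keeps selection
  reproducible at the cost of possibly missing qualified listings.
* **Seed usability.** Only brand-name, edit-distance, phonetic and
  pill-imprint categories seed prompts; search-derived and
  slang-dictionary columns carry too many false positives. The
  single-word rule is applied to brand-name entries only (multi-word
  brand entries are phrases that already contain a known synonym).
* **F2** is the standard β = 2 F-measure, `5pr/(4p+r)`; the published
  worked values (e.g. F2 = 0.642 at p = 0.264, r = 1.0) confirm this
  form. Metrics with zero denominators are reported as absent, and
  rounding (3 decimals) happens only at report serialization.
* **Novelty** checks a term against every seed-lexicon column *and*
  every index term, case-insensitively — the widest check, hence the
  most conservative novelty claim. A generated term equal to the
  queried index term can pass the filters but is never counted novel.
* **Evaluation universe.** Confusion matrices are computed over the
  labeled *generated* terms: labels exist only for what the model
  produced, so a planted synonym that a finite run never generates is
  not an evaluable false negative. `confusion()` accepts an explicit
  universe for callers that want a different convention.

## The synthetic worlds

A world plants, per index term, a set of true synonyms with a
Zipf-skewed generation distribution (a few very common colloquial
names, a long tail; skew 1.2, 75% of probability mass), the other index
terms (10% mass, mimicking same-indication confusions), and uniform
distractors (remaining mass). Each planted synonym's search results
mention its index term at a geometric depth (p = 0.5, truncated at the
depth budget) on one of the four variants; other drugs' index terms hit
at depth 1 through drug-comparison pages, so only the drug-name filter
removes them; distractors hit only at a configurable false-positive
rate (default 0). Truth labels are emitted by construction as a
synthetic stand-in for manual labeling (`truth_labels.csv`). The mock
completion backend treats temperature qualitatively (greedy top-k at 0,
`w**(1/T)` sampling above) — a monotone diversity knob for the sweep
harness, not a model of any real sampler.

The default test world uses 5 index terms × 30 planted synonyms × 200
distractors (seed 17), small enough for seconds-scale tests. The
acceptance run uses 500 iterations per term on the clean world and 300
on the 0.2-false-positive world; at those sizes every planted synonym
is generated with overwhelming probability, making the exact-recovery
check (precision = recall = 1.0) seed-robust, and the false-positive
world's precision has a closed-form expectation
`TP/(TP + f·D)` (TP generated planted terms, D generated distractors,
f the false-positive rate) with a delta-method standard error used as
the calibration band.

What passing on these worlds does **not** show: anything about a real
completion model's actual synonym coverage or a real search engine's
ranking. Real slang is polysemous, multilingual and drifting; the
worlds' vocabularies are disjoint synthetic strings with noise-free
labels. Production-scale throughput figures (thousands of generated terms
per drug at 1000 iterations against live backends) are live-run
expectations, not desk-reproducible quantities, and are therefore not
asserted by the test suite.

## Known limitations

* Live completion/search adapters are contracts only; users supply
  their own backend objects (credentials via environment, never config).
* The search cache is keyed without the index term, so one cache file
  is valid for one index term's run context only (the pipeline manages
  this; manual cache reuse across drugs would be wrong).
* Recall-oriented defaults admit false positives by design; precision-
  critical applications should enable the frequency filter or raise
  its threshold, at a known cost in recall.
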