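# slanglex

Lexicon induction for colloquial drug terminology, aimed at social-media
pharmacovigilance. Posts about drug use are written in slang and
misspellings ("zannies", "bars", "alprazolan") that controlled
vocabularies miss; `slanglex` automates the construction of a per-drug
lexicon of such synonyms by repeatedly prompting a text-completion
language model with a few known synonyms, parsing the enumerated-list
completions into candidate terms, and validating the candidates with
three composable filters:

* **search filter** — a candidate passes if the drug's generic (index)
  term appears in a title or snippet of the top-*k* web-search results
  for the candidate alone or with "pill" / "drug" / "slang" appended
  (default depth *k* = 10, with early termination and per-(term, variant)
  memoization to respect API quotas);
* **drug-name filter** — candidates that are index terms of *other*
  drugs are removed (completion models readily volunteer
  same-indication drugs);
* **frequency filter** — candidates generated no more than a threshold
  number of times are removed (default threshold 1; off in the default
  scheme).

Index terms are chosen by intersecting a seed lexicon of known synonyms
(organized in validation-category columns: brand names, edit-distance
misspellings, phonetic misspellings, pill imprints, …) with a
controlled-substance list, keeping terms with at least three usable
seed synonyms, and flagging a *widely-discussed* subset by forum hit
counts (cutoff 10,000).

Filter schemes are evaluated as binary classifiers against manual
labels using precision, recall and the F-beta family:

    precision = TP/(TP+FP)        recall = TP/(TP+FN)
    F1 = 2pr/(p+r)                F2 = 5pr/(4p+r)

F2 (β = 2) weights recall over precision because a synonym missing from
the lexicon can never flag a post, while false positives can be
filtered downstream. The pipeline's yield metric is the **UNGS** count
(unique novel generated synonyms): distinct terms that pass the active
scheme and appear nowhere in the seed lexicon.

Everything runs offline: deterministic mock completion/search backends
and a synthetic-world generator (`slanglex.worlds`) provide planted
ground truth for testing and calibration. Live API adapters are
deliberately not bundled; any object satisfying the
`CompletionBackend` / `SearchBackend` contracts can be passed to
`run_pipeline`.

## Worked example

Build a small synthetic world (3 drugs, 12 planted synonyms each, 50
distractor terms), run the pipeline for 200 iterations per drug, and
evaluate it against the world's planted truth:

```bash
slanglex simulate --out world --index-terms 3 --planted 12 --distractors 50 --seed 17
cat > config.yaml <<'EOF'
seed_lexicon_path: world/seed_lexicon.tsv
controlled_list_path: world/controlled_substances.txt
hit_counts_path: world/hit_counts.tsv
labels_path: world/truth_labels.csv
world_path: world
output_dir: out
n_iterations: 200
EOF
slanglex lexicon --config config.yaml --seed 7
slanglex evaluate --config config.yaml --seed 7
```

which prints (abridged):

```
compound00: 1400 generation events, 64 unique, 12 in lexicon
...
== compound00 ==
All generated terms: precision=0.188 recall=1.0 f1=0.316 f2=0.536
All seed-lexicon terms: precision=0.714 recall=0.417 f1=0.526 f2=0.455
Drug name filter: precision=0.194 recall=1.0 f1=0.324 f2=0.545
Drug name & frequency filters: precision=0.197 recall=1.0 f1=0.329 f2=0.55
Drug name & Google filters: precision=1.0 recall=1.0 f1=1.0 f2=1.0
Drug name, frequency, & Google filters: precision=1.0 recall=1.0 f1=1.0 f2=1.0
```

Reading: of 1400 generation events per drug, 64 distinct candidates
were produced; predicting every candidate to be a synonym gives perfect
recall but 19% precision, while the default drug-name + search scheme
recovers exactly the 12 planted synonyms (precision = recall = 1.0 in
this noise-free world). `out/lexicon.tsv` holds the published rows
(term, frequency, first search-hit depth and variant, filter flags,
seed-lexicon membership, novelty flag); `out/novelty.tsv` shows each
drug contributing 7 novel synonyms beyond its 5 seeds.

Other subcommands: `select` (index-term selection report), `generate`
and `filter` (individual stages, resumable with `--resume`), `sweep`
(the temperature / penalty / template parameter grid), all documented
via `slanglex --help`.

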