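"""Confusion matrices, F-beta metrics, novelty accounting, summaries."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from slanglex.errors import DataError
from slanglex.evaluation import (
    ConfusionMatrix,
    ManualLabel,
    SweepKey,
    NoveltyAccount,
    confusion,
    depth_histogram,
    frequency_histogram,
    metrics,
    novelty_account,
    scheme_comparison,
    sweep_marginal,
    sweep_summary,
)
from slanglex.filtering import SearchCache, apply_scheme, positives
from slanglex.generation import run_iterations
from slanglex.prompting import QueryParams
from slanglex.seed_lexicon import IndexTermSelection, load_seed_lexicon


def lab(term, synonym, index_term="alprazolam"):
    return ManualLabel(index_term=index_term, term=term,
                       label="synonym" if synonym else "non-synonym")


def test_all_positive_prediction_matches_published_counts():
    # 1019 labeled terms, 269 synonyms, everything predicted positive
    labels = [lab(f"s{i}", True) for i in range(269)] + [lab(f"n{i}", False) for i in range(750)]
    cm = confusion({l.term for l in labels}, labels)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (269, 750, 0, 0)


def test_empty_prediction_empty_labels():
    cm = confusion(set(), [])
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 0, 0)


def test_predicting_exactly_the_synonyms_is_perfect():
    labels = [lab("a", True), lab("b", True), lab("c", False)]
    cm = confusion({"a", "b"}, labels)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 0, 0, 1)


def test_unlabeled_evaluated_terms_raise_listing_them():
    with pytest.raises(DataError, match="mystery"):
        confusion({"mystery"}, [lab("a", True)])


@pytest.mark.parametrize(
    "tp,fp,fn,precision,recall,f1,f2",
    [
        (269, 750, 0, 0.264, 1.000, 0.418, 0.642),
        (314, 1114, 0, 0.220, 1.000, 0.361, 0.585),
        (48, 0, 221, 1.000, 0.178, 0.302, 0.213),
        (1, 1, 1, 0.5, 0.5, 0.5, 0.5),
    ],
)
def test_metric_worked_examples(tp, fp, fn, precision, recall, f1, f2):
    m = metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=0))
    assert round(m.precision, 3) == precision
    assert round(m.recall, 3) == recall
    assert abs(m.f1 - f1) <= 2e-3
    assert abs(m.f2 - f2) <= 2e-3


def test_zero_denominators_yield_absent_metrics():
    m = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
    assert m.precision is None and m.recall is None and m.f1 is None and m.f2 is None
    m = metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=0))
    assert m.precision == 0.0 and m.recall is None


@given(
    st.integers(min_value=0, max_value=500),
    st.integers(min_value=0, max_value=500),
    st.integers(min_value=0, max_value=500),
)
def test_fbeta_ordering(tp, fp, fn):
    m = metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=0))
    if m.precision is None or m.recall is None or m.f1 is None:
        return
    if m.recall > m.precision:
        assert m.f2 > m.f1
    if m.recall == m.precision:
        assert m.f2 == pytest.approx(m.f1) == pytest.approx(m.precision)


def test_rounding_only_at_serialization():
    m = metrics(ConfusionMatrix(tp=269, fp=750, fn=0, tn=0), scheme="baseline")
    assert m.precision == 269 / 1019  # full precision internally
    assert m.to_row()["precision"] == 0.264


# --- fixture-world scheme comparison against a brute-force oracle ----------


@pytest.fixture(scope="module")
def world_run(default_world_dir):
    from slanglex.worlds import load_world

    world = load_world(default_world_dir)
    seed_full = load_seed_lexicon(
        default_world_dir / "seed_lexicon.tsv",
        usable_categories=(
            "known", "edOne", "edTwo", "misspellingPhon", "pillMark",
            "google_ms", "google_title", "google_snippet", "ud_slang",
        ),
    )
    it = world.index_terms[0]
    sel = IndexTermSelection(
        index_term=it, usable_synonyms=world.planted[it][:5], eligible=True,
        widely_discussed=False,
    )
    records, tallies = run_iterations(
        sel, world.completion_backend(), QueryParams(), 150, rng_seed=13
    )
    flags = apply_scheme(
        tallies, {"drug_name", "google", "frequency"},
        all_index_terms=world.index_terms,
        search_backend=world.search_backend(), cache=SearchCache(),
    )
    labels = [l for l in world.truth_labels() if l.index_term == it]
    return world, it, records, tallies, flags, labels, seed_full


def brute_force_pass(world, it, term, scheme, freq):
    """Independent re-derivation of each predicate from the world model."""
    ok = True
    if "drug_name" in scheme:
        ok &= not (term in world.index_terms and term != it)
    if "google" in scheme:
        hit = False
        backend = world.search_backend()
        for variant in ("", "pill", "drug", "slang"):
            query = term if variant == "" else f"{term} {variant}"
            for title, snippet in backend.search(query, 10):
                if it in title.lower() or it in snippet.lower():
                    hit = True
        ok &= hit
    if "frequency" in scheme:
        ok &= freq > 1
    return ok


@pytest.mark.parametrize(
    "scheme",
    [set(), {"drug_name"}, {"drug_name", "frequency"}, {"drug_name", "google"},
     {"drug_name", "frequency", "google"}],
    ids=lambda s: "+".join(sorted(s)) or "none",
)
def test_scheme_positives_match_brute_force(world_run, scheme):
    world, it, _, tallies, flags, _, _ = world_run
    freqs = {t.term: t.frequency for t in tallies}
    expected = {
        term for term, f in freqs.items() if brute_force_pass(world, it, term, scheme, f)
    }
    assert positives(flags, scheme) == expected


def test_scheme_comparison_rows_match_recomputed_matrices(world_run):
    world, it, _, tallies, flags, labels, seed_full = world_run
    reports = scheme_comparison(tallies, flags, labels, seed_full)
    assert [r.scheme for r in reports] == [
        "All generated terms", "All seed-lexicon terms", "Drug name filter",
        "Drug name & frequency filters", "Drug name & Google filters",
        "Drug name, frequency, & Google filters",
    ]
    universe = {t.term for t in tallies}
    truth = {l.term: l.label == "synonym" for l in labels}
    freqs = {t.term: t.frequency for t in tallies}
    scheme_of = {
        "All generated terms": set(),
        "Drug name filter": {"drug_name"},
        "Drug name & frequency filters": {"drug_name", "frequency"},
        "Drug name & Google filters": {"drug_name", "google"},
        "Drug name, frequency, & Google filters": {"drug_name", "frequency", "google"},
    }
    for rep in reports:
        if rep.scheme == "All seed-lexicon terms":
            pred = {t for t in universe if t in seed_full}
        else:
            pred = {
                t for t in universe
                if brute_force_pass(world, it, t, scheme_of[rep.scheme], freqs[t])
            }
        tp = sum(1 for t in pred if truth[t])
        fn = sum(1 for t in universe - pred if truth[t])
        assert (rep.cm.tp, rep.cm.fp) == (tp, len(pred) - tp)
        assert (rep.cm.fn, rep.cm.tn) == (fn, len(universe - pred) - fn)


def test_scheme_comparison_requires_labels(world_run):
    _, _, _, tallies, flags, _, seed_full = world_run
    with pytest.raises(DataError):
        scheme_comparison(tallies, flags, [], seed_full)


def test_depth_histogram_matches_counting_oracle(world_run):
    _, _, _, _, flags, labels, _ = world_run
    outcomes = [f.google for f in flags.values() if f.google is not None]
    hist = depth_histogram(outcomes, labels)
    truth = {l.term: l.label == "synonym" for l in labels}
    oracle = Counter(
        (o.first_hit_depth, truth[o.term]) for o in outcomes if o.passed
    )
    for _, row in hist.iterrows():
        assert row["count_synonym"] == oracle[(row["bin"], True)]
        assert row["count_nonsynonym"] == oracle[(row["bin"], False)]
    assert hist["count_synonym"].sum() + hist["count_nonsynonym"].sum() == sum(
        1 for o in outcomes if o.passed
    )


def test_depth_histogram_trivial_cases():
    assert depth_histogram([]).empty
    from slanglex.filtering import GoogleOutcome

    hist = depth_histogram([GoogleOutcome(f"t{i}", True, 1, "") for i in range(3)])
    assert hist["bin"].tolist() == [1] and hist["count"].tolist() == [3]


def test_frequency_histogram_matches_counting_oracle(world_run):
    _, _, _, tallies, flags, labels, _ = world_run
    truth = {l.term: l.label == "synonym" for l in labels}
    hist_all = frequency_histogram(tallies, labels)
    oracle = Counter((t.frequency, truth[t.term]) for t in tallies)
    for _, row in hist_all.iterrows():
        assert row["count_synonym"] == oracle[(row["bin"], True)]
        assert row["count_nonsynonym"] == oracle[(row["bin"], False)]
    hist_google = frequency_histogram(tallies, labels, with_google=True, flags=flags)
    assert hist_google["count_synonym"].sum() <= hist_all["count_synonym"].sum()
    assert hist_google["count_nonsynonym"].sum() <= hist_all["count_nonsynonym"].sum()


def test_novelty_chain_inequality_and_seed_exclusion(world_run):
    world, it, _, tallies, flags, _, seed_full = world_run
    acc = novelty_account(it, tallies, flags, {"drug_name", "google"}, seed_full)
    assert acc.ungs <= acc.gpt3_synonyms <= acc.unique_generated <= acc.total_generated
    # seeds pass the filters but are in the lexicon, so they are never novel
    seeds = set(world.planted[it][:5])
    pos = positives(flags, {"drug_name", "google"})
    assert seeds <= pos
    assert acc.ungs == len(pos) - len(seeds)


def test_novelty_account_validates_chain():
    with pytest.raises(DataError):
        NoveltyAccount(index_term="x", total_generated=5, unique_generated=6,
                       gpt3_synonyms=0, ungs=0)


def test_sweep_summary_and_marginals():
    accounts = {}
    for temp in (0.0, 1.0):
        for template in ("plain", "counterexample"):
            key = SweepKey(temp, template, 0.0, 0.0)
            accounts[key] = NoveltyAccount(
                index_term="x", total_generated=100, unique_generated=50,
                gpt3_synonyms=20, ungs=int(5 * (1 + temp) + (template == "plain")),
            )
    summary = sweep_summary(accounts)
    assert len(summary) == 4
    marg = sweep_marginal(summary, "temperature")
    assert marg.sum() == summary["ungs"].sum()  # conservation
    assert marg[1.0] > marg[0.0]
    with pytest.raises(DataError):
        sweep_marginal(summary, "rng_seed")
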