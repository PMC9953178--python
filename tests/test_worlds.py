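"""Synthetic-world construction, mock backends, and their guarantees."""

from __future__ import annotations

import numpy as np
import pytest

from slanglex.errors import ConfigurationError
from slanglex.generation import parse_completion, run_iterations
from slanglex.prompting import QueryParams
from slanglex.seed_lexicon import IndexTermSelection
from slanglex.worlds import WorldSpec, build_world, load_world, make_world


def world_selection(world, i=0):
    it = world.index_terms[i]
    return IndexTermSelection(
        index_term=it, usable_synonyms=world.planted[it][: world.spec.seeds_per_term],
        eligible=True, widely_discussed=False,
    )


def test_same_spec_builds_identical_worlds(tmp_path):
    spec = WorldSpec(n_index_terms=2, planted_per_term=5, n_distractors=10, rng_seed=3)
    build_world(spec, tmp_path / "a")
    build_world(spec, tmp_path / "b")
    for name in (
        "seed_lexicon.tsv", "controlled_substances.txt", "hit_counts.tsv",
        "truth_labels.csv", "world.yaml",
    ):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name


def test_world_reloads_equivalently(tmp_path):
    spec = WorldSpec(n_index_terms=2, planted_per_term=5, n_distractors=10, rng_seed=3)
    world = build_world(spec, tmp_path / "w")
    again = load_world(tmp_path / "w")
    assert again.spec == world.spec
    assert again.search_index == world.search_index
    assert again.false_positives == world.false_positives
    vocab1, probs1 = world.generation_distribution(world.index_terms[0])
    vocab2, probs2 = again.generation_distribution(world.index_terms[0])
    assert vocab1 == vocab2 and np.allclose(probs1, probs2)


def test_generation_distribution_is_normalized(default_world):
    for it in default_world.index_terms:
        vocab, probs = default_world.generation_distribution(it)
        assert len(vocab) == len(set(vocab)) == len(probs)
        assert probs.sum() == pytest.approx(1.0)
        assert set(default_world.planted[it]).isdisjoint(default_world.index_terms)


def test_no_synthetic_term_contains_an_index_term_substring(default_world):
    # filler search results echo the query; a vocabulary term embedding
    # an index term would corrupt the substring match
    for it in default_world.index_terms:
        vocab, _ = default_world.generation_distribution(it)
        for other in default_world.index_terms:
            assert all(
                other not in term
                for term in vocab
                if term not in default_world.index_terms
            )


def test_inconsistent_spec_rejected():
    with pytest.raises((ConfigurationError, ValueError)):
        WorldSpec(n_index_terms=1, planted_per_term=2, n_distractors=0,
                  seeds_per_term=3, items_per_completion=7)
    with pytest.raises((ConfigurationError, ValueError)):
        WorldSpec(planted_mass=0.9, other_drug_mass=0.2)


def test_temperature_zero_is_deterministic(default_world):
    backend = default_world.completion_backend()
    params = QueryParams(temperature=0.0)
    prompt = "ways to say compound00:\n1. a\n2. b\n3. c\n4."
    c1 = backend.complete(prompt, params, rng=np.random.default_rng(0))
    c2 = backend.complete(prompt, params, rng=np.random.default_rng(99))
    assert c1 == c2  # greedy decoding ignores the rng entirely


def test_higher_temperature_yields_more_unique_terms(default_world):
    sel = world_selection(default_world)
    _, cold = run_iterations(
        sel, default_world.completion_backend(), QueryParams(temperature=0.0), 100, 1
    )
    _, hot = run_iterations(
        sel, default_world.completion_backend(), QueryParams(temperature=1.0), 100, 1
    )
    assert len(hot) >= len(cold)
    assert len(cold) == default_world.spec.items_per_completion  # top-k only


def test_positive_penalties_damp_within_completion_repetition(default_world):
    prompt = "ways to say compound00:\n1. a\n2. b\n3. c\n4."
    backend = default_world.completion_backend()
    plain = backend.complete(prompt, QueryParams(), rng=np.random.default_rng(5))
    pen = backend.complete(
        prompt, QueryParams(frequency_penalty=2.0, presence_penalty=2.0),
        rng=np.random.default_rng(5),
    )
    assert len(set(parse_completion(pen, 4))) >= len(set(parse_completion(plain, 4)))


def test_malformed_mode_exercises_the_parser_stop_rule(default_world):
    backend = default_world.completion_backend(malformed_rate=1.0)
    prompt = "ways to say compound00:\n1. a\n2. b\n3. c\n4."
    completion = backend.complete(prompt, QueryParams(), rng=np.random.default_rng(2))
    assert "hope this helps!" in completion and "stray" in completion
    items = parse_completion(completion, 4)
    assert "stray" not in items  # numbered lines after prose are unreachable
    assert 0 < len(items) <= default_world.spec.items_per_completion


def test_search_backend_places_planted_hits_as_drawn(default_world):
    backend = default_world.search_backend()
    term, (owner, variant, depth) = next(iter(default_world.search_index.items()))
    query = term if variant == "" else f"{term} {variant}"
    results = backend.search(query, default_world.spec.max_depth)
    assert owner in results[depth - 1][1]
    for rank, (title, snippet) in enumerate(results, start=1):
        if rank != depth:
            assert owner not in title and owner not in snippet
    # other variants never mention the index term
    for other in ("", "pill", "drug", "slang"):
        if other == variant:
            continue
        q = term if other == "" else f"{term} {other}"
        assert all(owner not in t and owner not in s
                   for t, s in backend.search(q, 10))


def test_other_index_terms_hit_via_comparison_pages(default_world):
    backend = default_world.search_backend()
    results = backend.search(default_world.index_terms[1], 10)
    assert default_world.index_terms[0] in results[0][1]


def test_distractor_pages_never_hit_without_false_positives(default_world):
    it = default_world.index_terms[0]
    backend = default_world.search_backend()
    for term in default_world.distractors[it][:10]:
        for variant in ("", "pill", "drug", "slang"):
            q = term if variant == "" else f"{term} {variant}"
            assert all(it not in t and it not in s for t, s in backend.search(q, 10))


def test_false_positive_rate_plants_flagged_distractors():
    world = make_world(WorldSpec(search_false_positive_rate=0.2, rng_seed=23))
    n_total = sum(len(d) for d in world.distractors.values())
    n_fp = len(world.false_positives)
    # binomial(1000, 0.2): 3 sigma band
    assert abs(n_fp - 0.2 * n_total) < 3 * np.sqrt(n_total * 0.2 * 0.8)
    backend = world.search_backend()
    term, (owner, depth) = next(iter(world.false_positives.items()))
    assert owner in backend.search(term, world.spec.max_depth)[depth - 1][1]


def test_truth_labels_cover_each_terms_vocabulary(default_world):
    labels = default_world.truth_labels()
    by_term = {}
    for lab in labels:
        by_term.setdefault(lab.index_term, set()).add(lab.term)
    for it in default_world.index_terms:
        vocab, _ = default_world.generation_distribution(it)
        assert set(vocab) <= by_term[it]
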