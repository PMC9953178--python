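"""Self-contained synthetic worlds for offline, deterministic testing.

A *world* is a complete miniature of the problem the pipeline faces: a
seed lexicon of index terms with categorized synonyms, a
controlled-substance list, planted ground-truth synonyms, a mock
completion backend whose categorical generation distribution has a
Zipf-like skew (a few very common colloquial names, a long tail), and a
mock search index in which each planted synonym's results mention its
index term at a geometrically drawn depth on one of the four query
variants.  Distractor terms never hit (except at a configurable false
positive rate), and other drugs' index terms hit at depth 1 — emulating
drug-comparison pages — so only the drug-name cross-reference removes
them.

Everything is a deterministic function of the :class:`WorldSpec`
(including its seed), so worlds rebuild byte-identically and every
pipeline stage can be exercised without credentials or network.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from slanglex.errors import ConfigurationError, QuotaExhaustedError
from slanglex.evaluation import NON_SYNONYM, SYNONYM, ManualLabel
from slanglex.prompting import QueryParams
from slanglex.seed_lexicon import CATEGORIES, SeedEntry, SeedLexicon

_USABLE_CYCLE = ("known", "edOne", "edTwo", "misspellingPhon", "pillMark")
_PROMPT_TERM_RE = re.compile(r"(?:ways to say|but these are synonyms for) (.+?):")
_HANGING_RE = re.compile(r"(\d+)\.\s*$")


class WorldSpec(BaseModel):
    """Parameters of a synthetic world.

    The defaults are sized for seconds-scale test runs: 5 index terms
    with 30 planted synonyms each and 200 per-term distractors.  The
    generation distribution puts ``planted_mass`` of its probability on
    the planted synonyms (Zipf-skewed with exponent ``zipf_exponent``),
    ``other_drug_mass`` on the other index terms (models volunteer
    same-indication drugs), and the remainder uniformly on distractors.
    Planted synonyms receive a search hit at a geometric depth
    (success probability ``depth_geometric_p``, truncated at
    ``max_depth``) on one of the four query variants; each distractor
    independently receives a false-positive hit with probability
    ``search_false_positive_rate``.
    """

    model_config = {"frozen": True}

    n_index_terms: int = Field(default=5, ge=1)
    planted_per_term: int = Field(default=30, ge=1)
    n_distractors: int = Field(default=200, ge=0)
    seeds_per_term: int = Field(default=5, ge=3)
    zipf_exponent: float = Field(default=1.2, gt=0.0)
    planted_mass: float = Field(default=0.75, gt=0.0, le=1.0)
    other_drug_mass: float = Field(default=0.10, ge=0.0, lt=1.0)
    items_per_completion: int = Field(default=7, ge=1)
    max_depth: int = Field(default=10, ge=1)
    depth_geometric_p: float = Field(default=0.5, gt=0.0, le=1.0)
    search_false_positive_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    rng_seed: int = Field(default=17, ge=0)

    @model_validator(mode="after")
    def _consistent(self) -> "WorldSpec":
        if self.seeds_per_term > self.planted_per_term:
            raise ConfigurationError("seeds_per_term cannot exceed planted_per_term")
        if self.planted_mass + self.other_drug_mass > 1.0 + 1e-12:
            raise ConfigurationError("planted_mass + other_drug_mass must be <= 1")
        vocab = self.planted_per_term + self.n_distractors + max(self.n_index_terms - 1, 0)
        if self.items_per_completion > vocab:
            raise ConfigurationError(
                f"items_per_completion ({self.items_per_completion}) exceeds the "
                f"per-term vocabulary ({vocab})"
            )
        return self


@dataclass(frozen=True)
class World:
    """A realized synthetic world (see module docstring)."""

    spec: WorldSpec
    index_terms: tuple[str, ...]
    planted: dict[str, tuple[str, ...]]
    distractors: dict[str, tuple[str, ...]]
    #: planted term -> (owner index term, matching variant, hit depth)
    search_index: dict[str, tuple[str, str, int]]
    #: false-positive distractor -> (owner index term, hit depth)
    false_positives: dict[str, tuple[str, int]]
    _weights: dict[str, tuple[tuple[str, ...], np.ndarray]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for it in self.index_terms:
            vocab, probs = self._build_weights(it)
            self._weights[it] = (vocab, probs)

    def _build_weights(self, index_term: str) -> tuple[tuple[str, ...], np.ndarray]:
        spec = self.spec
        planted = self.planted[index_term]
        others = tuple(t for t in self.index_terms if t != index_term)
        distract = self.distractors[index_term]
        vocab = planted + others + distract
        zipf = np.array([(k + 1) ** -spec.zipf_exponent for k in range(len(planted))])
        w = np.zeros(len(vocab))
        w[: len(planted)] = spec.planted_mass * zipf / zipf.sum()
        other_mass = spec.other_drug_mass if others else 0.0
        if others:
            w[len(planted) : len(planted) + len(others)] = other_mass / len(others)
        rest = 1.0 - spec.planted_mass - other_mass
        if len(distract):
            w[len(planted) + len(others) :] = rest / len(distract)
        return vocab, w / w.sum()

    def generation_distribution(self, index_term: str) -> tuple[tuple[str, ...], np.ndarray]:
        """The categorical vocabulary and probabilities for one index term."""
        vocab, probs = self._weights[index_term]
        return vocab, probs.copy()

    def seed_lexicon(self) -> SeedLexicon:
        """The world's seed lexicon (usable categories plus decoys).

        The first ``seeds_per_term`` planted synonyms of each index term
        are entered under the usable categories; a multi-word brand
        phrase and a search-derived decoy entry are added to exercise
        the loading rules.
        """
        entries: list[SeedEntry] = []
        for it in self.index_terms:
            seeds = self.planted[it][: self.spec.seeds_per_term]
            for j, syn in enumerate(seeds):
                entries.append(
                    SeedEntry(index_term=it, synonym=syn, category=_USABLE_CYCLE[j % 5])
                )
            entries.append(
                SeedEntry(index_term=it, synonym=f"{seeds[0]} works great", category="known")
            )
            entries.append(
                SeedEntry(index_term=it, synonym=f"{it}-decoy", category="google_ms")
            )
        return SeedLexicon(entries=tuple(entries))

    def truth_labels(self) -> list[ManualLabel]:
        """Ground-truth labels covering each term's full generation vocabulary."""
        labels: list[ManualLabel] = []
        for it in self.index_terms:
            vocab, _ = self._weights[it]
            planted = set(self.planted[it])
            for term in vocab:
                labels.append(
                    ManualLabel(
                        index_term=it,
                        term=term,
                        label=SYNONYM if term in planted else NON_SYNONYM,
                    )
                )
        return labels

    def hit_counts(self) -> dict[str, int]:
        """Forum hit counts: alternate widely-discussed / niche terms."""
        return {
            it: (25_000 if i % 2 == 0 else 400) for i, it in enumerate(self.index_terms)
        }

    def controlled_names(self) -> list[str]:
        """All index terms plus two names absent from the lexicon."""
        return [*self.index_terms, "placebozine", "nullamine"]

    def completion_backend(self, malformed_rate: float = 0.0) -> "MockCompletionBackend":
        return MockCompletionBackend(self, malformed_rate=malformed_rate)

    def search_backend(self) -> "MockSearchBackend":
        return MockSearchBackend(self)

    def expected_search_precision(
        self, tallies_by_term: Mapping[str, set[str]]
    ) -> tuple[float, float]:
        """Closed-form precision of the drug-name+search scheme, with SE.

        Given the realized generated-term sets, every generated planted
        synonym passes (TP), other index terms are removed by the
        drug-name filter, and each generated distractor passes
        independently with the false-positive rate f.  With TP planted
        and D generated distractors, precision = TP / (TP + X) where
        X ~ Binomial(D, f); the delta-method standard error is
        TP * sqrt(D f (1-f)) / (TP + D f)^2.
        """
        f = self.spec.search_false_positive_rate
        tp = sum(
            len(terms & set(self.planted[it])) for it, terms in tallies_by_term.items()
        )
        d = sum(
            len(terms & set(self.distractors[it])) for it, terms in tallies_by_term.items()
        )
        expected = tp / (tp + f * d) if tp + f * d > 0 else float("nan")
        se = tp * math.sqrt(d * f * (1 - f)) / (tp + f * d) ** 2 if tp + f * d > 0 else float("nan")
        return expected, se


def make_world(spec: WorldSpec) -> World:
    """Realize a world from its spec; deterministic in ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    # No synthetic synonym/distractor name may contain an index-term
    # substring, or the substring match in the search filter would hit
    # on filler results that merely echo the query.
    index_terms = tuple(f"compound{i:02d}" for i in range(spec.n_index_terms))
    planted = {
        it: tuple(f"syn{i:02d}x{j:02d}" for j in range(spec.planted_per_term))
        for i, it in enumerate(index_terms)
    }
    distractors = {
        it: tuple(f"junk{i:02d}x{j:03d}" for j in range(spec.n_distractors))
        for i, it in enumerate(index_terms)
    }
    search_index: dict[str, tuple[str, str, int]] = {}
    variants = ("", "pill", "drug", "slang")
    for it in index_terms:
        for term in planted[it]:
            depth = min(int(rng.geometric(spec.depth_geometric_p)), spec.max_depth)
            variant = variants[rng.integers(0, len(variants))]
            search_index[term] = (it, variant, depth)
    false_positives: dict[str, tuple[str, int]] = {}
    for it in index_terms:
        for term in distractors[it]:
            if rng.random() < spec.search_false_positive_rate:
                depth = min(int(rng.geometric(spec.depth_geometric_p)), spec.max_depth)
                false_positives[term] = (it, depth)
    return World(
        spec=spec,
        index_terms=index_terms,
        planted=planted,
        distractors=distractors,
        search_index=search_index,
        false_positives=false_positives,
    )


class MockCompletionBackend:
    """Deterministic stand-in for a completion model.

    Continues the prompt's numbered list with draws from the world's
    per-term generation distribution.  Temperature is interpreted
    qualitatively: 0 returns the top-weight items deterministically,
    higher values sample with probabilities proportional to
    ``w**(1/T)``, so diversity rises monotonically with temperature.
    Positive frequency/presence penalties damp within-completion
    repetition by down-weighting already-drawn items.  A configurable
    malformed-output mode appends prose (and stray numbered lines after
    it) to exercise the parser's stop rule.
    """

    def __init__(self, world: World, malformed_rate: float = 0.0):
        self.world = world
        self.malformed_rate = malformed_rate
        self._rng = np.random.default_rng(world.spec.rng_seed + 1)
        self.calls = 0

    def complete(
        self, prompt: str, params: QueryParams, rng: np.random.Generator | None = None
    ) -> str:
        self.calls += 1
        rng = rng if rng is not None else self._rng
        terms = _PROMPT_TERM_RE.findall(prompt)
        if not terms:
            return ""  # contract: never raise on unusable prompts
        index_term = terms[-1].strip().lower()
        if index_term not in self.world.planted:
            return ""
        m = _HANGING_RE.search(prompt)
        next_index = int(m.group(1)) if m else 4
        vocab, probs = self.world.generation_distribution(index_term)
        n = self.world.spec.items_per_completion
        if params.temperature == 0.0:
            order = np.lexsort((np.array(vocab), -probs))
            items = [vocab[i] for i in order[:n]]
        else:
            w = probs ** (1.0 / params.temperature)
            damp = math.exp(-max(params.frequency_penalty + params.presence_penalty, 0.0))
            items = []
            for _ in range(n):
                p = w / w.sum()
                i = int(rng.choice(len(vocab), p=p))
                items.append(vocab[i])
                if damp < 1.0:
                    w[i] *= damp
        lines = [f" {items[0]}"]
        lines += [f"{next_index + i}. {item}" for i, item in enumerate(items[1:], start=1)]
        if self.malformed_rate > 0 and rng.random() < self.malformed_rate:
            lines += ["", "hope this helps!", f"{next_index + len(items)}. stray"]
        return "\n".join(lines)


class MockSearchBackend:
    """Deterministic stand-in for a web-search API.

    Result pages are synthesized per query.  A planted synonym's page
    mentions its index term in the snippet at its drawn depth, on its
    drawn variant only.  Another drug's index term yields a
    drug-comparison page whose first snippet mentions every index term.
    A false-positive distractor yields a generic drug-list page with its
    owner's index term at its drawn depth.  Everything else is filler
    that mentions no index term.  Result order is stable per query.
    """

    _SUFFIXES = ("pill", "drug", "slang")

    def __init__(self, world: World):
        self.world = world
        self.calls = 0

    def _split(self, query: str) -> tuple[str, str]:
        for suffix in self._SUFFIXES:
            if query.endswith(" " + suffix):
                return query[: -len(suffix) - 1], suffix
        return query, ""

    def search(self, query: str, max_results: int) -> list[tuple[str, str]]:
        self.calls += 1
        term, variant = self._split(query)
        hit_depth: int | None = None
        hit_text = ""
        if term in self.world.search_index:
            owner, hit_variant, depth = self.world.search_index[term]
            if variant == hit_variant:
                hit_depth, hit_text = depth, f"people use {term} when talking about {owner}"
        elif term in self.world.index_terms and variant == "":
            hit_depth = 1
            hit_text = "compare medications: " + ", ".join(self.world.index_terms)
        elif term in self.world.false_positives and variant == "":
            owner, depth = self.world.false_positives[term]
            hit_depth, hit_text = depth, f"glossary of street names including {owner}"
        results = []
        for rank in range(1, max_results + 1):
            if rank == hit_depth:
                results.append((f"forum thread about {term}", hit_text))
            else:
                results.append((f"result {rank} for {query}", "nothing of interest here"))
        return results


class QuotaLimitedBackend:
    """Wrap a completion or search backend with a finite call budget.

    After ``budget`` successful calls every further call raises
    :class:`QuotaExhaustedError` — the mock analogue of a metered API,
    used to test checkpointing and resumption.
    """

    def __init__(self, inner, budget: int):
        self.inner = inner
        self.budget = budget
        self.used = 0

    def _spend(self) -> None:
        if self.used >= self.budget:
            raise QuotaExhaustedError("mock quota exhausted")
        self.used += 1

    def complete(self, prompt, params, rng=None):
        self._spend()
        return self.inner.complete(prompt, params, rng=rng)

    def search(self, query, max_results):
        self._spend()
        return self.inner.search(query, max_results)


# ---------------------------------------------------------------------------
# Serialization: a world directory uses the same formats the pipeline reads.

def build_world(spec: WorldSpec, out_dir: str | Path) -> World:
    """Realize *spec* and write the world directory.

    Files: ``seed_lexicon.tsv``, ``controlled_substances.txt``,
    ``hit_counts.tsv``, ``truth_labels.csv`` (synthetic stand-in for
    manual labels), and ``world.yaml`` (spec plus realized search
    index).  Rebuilding from the same spec is byte-identical.
    """
    world = make_world(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.seed_lexicon().write(out / "seed_lexicon.tsv")
    (out / "controlled_substances.txt").write_text(
        "# synthetic controlled-substance list\n"
        + "\n".join(world.controlled_names())
        + "\n",
        encoding="utf-8",
    )
    (out / "hit_counts.tsv").write_text(
        "".join(f"{it}\t{n}\n" for it, n in sorted(world.hit_counts().items())),
        encoding="utf-8",
    )
    pd.DataFrame(
        [(lab.index_term, lab.term, lab.label) for lab in world.truth_labels()],
        columns=["index_term", "term", "label"],
    ).to_csv(out / "truth_labels.csv", index=False)
    payload = {
        "spec": spec.model_dump(),
        "index_terms": list(world.index_terms),
        "planted": {it: list(v) for it, v in world.planted.items()},
        "distractors": {it: list(v) for it, v in world.distractors.items()},
        "search_index": {t: list(v) for t, v in sorted(world.search_index.items())},
        "false_positives": {t: list(v) for t, v in sorted(world.false_positives.items())},
    }
    (out / "world.yaml").write_text(
        yaml.safe_dump(payload, sort_keys=True), encoding="utf-8"
    )
    return world


def load_world(path: str | Path) -> World:
    """Reload a world from its directory (or a ``world.yaml`` path)."""
    p = Path(path)
    if p.is_dir():
        p = p / "world.yaml"
    payload = yaml.safe_load(p.read_text(encoding="utf-8"))
    return World(
        spec=WorldSpec(**payload["spec"]),
        index_terms=tuple(payload["index_terms"]),
        planted={it: tuple(v) for it, v in payload["planted"].items()},
        distractors={it: tuple(v) for it, v in payload["distractors"].items()},
        search_index={t: (v[0], v[1], int(v[2])) for t, v in payload["search_index"].items()},
        false_positives={t: (v[0], int(v[1])) for t, v in payload["false_positives"].items()},
    )
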