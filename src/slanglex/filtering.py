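"""Candidate-term validation filters.

Three composable predicates decide whether a generated candidate term
is kept as a synonym:

* **search filter** — the candidate (alone, then with "pill", "drug",
  "slang" appended) is web-searched; it passes when the queried index
  term appears in a result title or snippet within the top ``max_depth``
  results of any variant.  Searching for a term stops at the first hit,
  and per-(term, variant) outcomes are memoized so repeated calls issue
  no backend traffic — search APIs meter daily quota.
* **drug-name filter** — candidates that are index terms of *other*
  drugs are rejected (models readily volunteer same-indication drugs).
* **frequency filter** — candidates generated no more than a threshold
  number of times are rejected (default: generated only once).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Protocol, Sequence, runtime_checkable

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from slanglex.errors import ConfigurationError, FormatError, QuotaExhaustedError
from slanglex.generation import TermTally

SCHEME_FILTERS = ("drug_name", "google", "frequency")


@runtime_checkable
class SearchBackend(Protocol):
    """Behavior contract for search providers.

    ``search`` returns the top results for a query as ordered
    (title, snippet) pairs; order must be stable for a given query.
    Live adapters raise :class:`QuotaExhaustedError` on quota errors.
    """

    def search(self, query: str, max_results: int) -> list[tuple[str, str]]: ...


class GoogleFilterConfig(BaseModel):
    """Search-filter settings: depth budget, query variants, match mode."""

    model_config = {"frozen": True}

    max_depth: int = Field(default=10, ge=1)
    variants: tuple[str, ...] = ("", "pill", "drug", "slang")
    match_mode: Literal["substring", "whole-word"] = "substring"

    @field_validator("variants")
    @classmethod
    def _bare_term_first(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v or v[0] != "":
            raise ValueError('the bare-term variant "" must come first')
        return v


@dataclass(frozen=True, slots=True)
class GoogleOutcome:
    """Result of the search filter for one term.

    ``first_hit_depth`` is the 1-based rank, within the matching
    variant's own results, of the first result mentioning the index
    term; it and ``matching_variant`` are present exactly when the term
    passed.
    """

    term: str
    passed: bool
    first_hit_depth: int | None = None
    matching_variant: str | None = None

    def __post_init__(self) -> None:
        present = (self.first_hit_depth is not None, self.matching_variant is not None)
        if self.passed != present[0] or self.passed != present[1]:
            raise ValueError("passed must coincide with depth and variant presence")
        if self.first_hit_depth is not None and self.first_hit_depth < 1:
            raise ValueError("depth is 1-based")


@dataclass(frozen=True, slots=True)
class FilterFlags:
    """Per-term outcomes of the three filters (flags are independent)."""

    term: str
    passes_drug_name: bool
    passes_google: bool
    passes_frequency: bool
    google: GoogleOutcome | None = None


class SearchCache:
    """Memo of per-(term, variant) search outcomes.

    Maps ``(term, variant)`` to the 1-based depth of the first result
    mentioning the index term, or ``None`` for a scanned miss.  Persists
    as a TSV ``term<TAB>variant<TAB>depth`` (depth ``-`` for a miss)
    with a bit-exact round-trip, enabling resumable large runs.  Because
    a hit depends on which index term was looked for, one cache file
    covers one index term's run.
    """

    def __init__(self, data: Mapping[tuple[str, str], int | None] | None = None):
        self._data: dict[tuple[str, str], int | None] = dict(data or {})
        self.backend_calls = 0  # incremented by google_filter on cache misses

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._data

    def __len__(self) -> int:
        return len(self._data)

    def get(self, key: tuple[str, str]) -> int | None:
        return self._data[key]

    def put(self, key: tuple[str, str], depth: int | None) -> None:
        self._data[key] = depth

    def items(self):
        return self._data.items()

    def save(self, path: str | Path) -> None:
        lines = [
            f"{term}\t{variant}\t{'-' if depth is None else depth}"
            for (term, variant), depth in sorted(self._data.items())
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SearchCache":
        data: dict[tuple[str, str], int | None] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"bad cache line {lineno}: {line!r}")
            term, variant, depth = parts
            data[(term, variant)] = None if depth == "-" else int(depth)
        return cls(data)


def _matches(index_term: str, text: str, mode: str) -> bool:
    if mode == "whole-word":
        return re.search(rf"\b{re.escape(index_term)}\b", text, re.IGNORECASE) is not None
    return index_term.lower() in text.lower()


def google_filter(
    term: str,
    index_term: str,
    backend: SearchBackend,
    cfg: GoogleFilterConfig | None = None,
    cache: SearchCache | None = None,
) -> GoogleOutcome:
    """Validate *term* against *index_term* through the search backend.

    Query variants are tried in order; for each, the top ``max_depth``
    results are scanned in rank order for the index term in title or
    snippet.  The first hit ends all searching for this term.  Outcomes
    are memoized per (term, variant) in *cache*; a warm cache issues no
    backend calls.  Quota errors propagate as
    :class:`QuotaExhaustedError` carrying the cache for checkpointing.
    """
    cfg = cfg or GoogleFilterConfig()
    for variant in cfg.variants:
        key = (term, variant)
        if cache is not None and key in cache:
            depth = cache.get(key)
        else:
            query = term if variant == "" else f"{term} {variant}"
            try:
                results = backend.search(query, cfg.max_depth)
            except QuotaExhaustedError as exc:
                raise QuotaExhaustedError(str(exc), cache=cache) from exc
            if cache is not None:
                cache.backend_calls += 1
            depth = None
            for rank, (title, snippet) in enumerate(results[: cfg.max_depth], start=1):
                if _matches(index_term, title, cfg.match_mode) or _matches(
                    index_term, snippet, cfg.match_mode
                ):
                    depth = rank
                    break
            if cache is not None:
                cache.put(key, depth)
        if depth is not None:
            return GoogleOutcome(
                term=term, passed=True, first_hit_depth=depth, matching_variant=variant
            )
    return GoogleOutcome(term=term, passed=False)


def drug_name_filter(term: str, index_term: str, all_index_terms: Iterable[str]) -> bool:
    """True (kept) unless *term* is a *different* drug's index term."""
    return not (term in set(all_index_terms) and term != index_term)


def frequency_filter(tally: TermTally, threshold: int = 1) -> bool:
    """True (kept) iff the term was generated strictly more than *threshold* times."""
    if threshold < 1:
        raise ConfigurationError("frequency threshold must be >= 1")
    return tally.frequency > threshold


def apply_scheme(
    tallies: Sequence[TermTally],
    scheme: Iterable[str],
    *,
    all_index_terms: Iterable[str] | None = None,
    search_backend: SearchBackend | None = None,
    google_config: GoogleFilterConfig | None = None,
    cache: SearchCache | None = None,
    frequency_threshold: int = 1,
) -> dict[str, FilterFlags]:
    """Compute :class:`FilterFlags` for every tallied term.

    *scheme* selects which predicates define the positive set (see
    :func:`positives`); an empty scheme is the all-terms-pass baseline.
    Flags for the drug-name and frequency filters are always computed;
    search outcomes are computed whenever a backend is supplied, and
    requesting ``google`` without one is a configuration error.
    """
    scheme = set(scheme)
    unknown = scheme - set(SCHEME_FILTERS)
    if unknown:
        raise ConfigurationError(f"unknown filters in scheme: {sorted(unknown)}")
    if "google" in scheme and search_backend is None:
        raise ConfigurationError("scheme includes 'google' but no search backend was given")
    index_set = frozenset(all_index_terms) if all_index_terms is not None else frozenset()

    flags: dict[str, FilterFlags] = {}
    for t in tallies:
        outcome: GoogleOutcome | None = None
        if search_backend is not None:
            outcome = google_filter(t.term, t.index_term, search_backend, google_config, cache)
        flags[t.term] = FilterFlags(
            term=t.term,
            passes_drug_name=drug_name_filter(t.term, t.index_term, index_set),
            passes_google=outcome.passed if outcome is not None else False,
            passes_frequency=frequency_filter(t, frequency_threshold),
            google=outcome,
        )
    return flags


def positives(flags: Mapping[str, FilterFlags], scheme: Iterable[str]) -> set[str]:
    """Terms passing every predicate in *scheme* (all terms if empty)."""
    scheme = set(scheme)
    out = set()
    for term, f in flags.items():
        ok = True
        if "drug_name" in scheme:
            ok = ok and f.passes_drug_name
        if "google" in scheme:
            ok = ok and f.passes_google
        if "frequency" in scheme:
            ok = ok and f.passes_frequency
        if ok:
            out.add(term)
    return out


def write_filter_report(
    tallies: Sequence[TermTally], flags: Mapping[str, FilterFlags], path: str | Path
) -> None:
    """TSV report with one row per tallied term and all filter outcomes."""
    rows = []
    for t in tallies:
        f = flags[t.term]
        g = f.google
        rows.append(
            {
                "index_term": t.index_term,
                "term": t.term,
                "frequency": t.frequency,
                "passes_drug_name": f.passes_drug_name,
                "passes_google": f.passes_google,
                "first_hit_depth": "" if g is None or g.first_hit_depth is None else g.first_hit_depth,
                "matching_variant": "" if g is None or g.matching_variant is None else g.matching_variant,
                "passes_frequency": f.passes_frequency,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "index_term", "term", "frequency", "passes_drug_name", "passes_google",
            "first_hit_depth", "matching_variant", "passes_frequency",
        ],
    ).to_csv(path, sep="\t", index=False)
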