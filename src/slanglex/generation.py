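"""Completion backends, list parsing, and the per-term generation loop.

A completion backend turns a rendered prompt into free text.  Because
the prompts end with a hanging enumerator, well-behaved completions
continue the numbered list; :func:`parse_completion` extracts the list
items with a small, forgiving grammar and stops at the first line that
is neither blank nor a numbered item (models occasionally append
prose).  :func:`run_iterations` drives the sample → render → complete →
parse loop for one index term and aggregates per-term generation
frequencies.
"""

from __future__ import annotations

import logging
import re
import time
import zlib
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from slanglex.errors import PreconditionError, QuotaExhaustedError, TransientBackendError
from slanglex.prompting import QueryParams, render_prompt, sample_seed_synonyms
from slanglex.seed_lexicon import IndexTermSelection

logger = logging.getLogger(__name__)

_ITEM_RE = re.compile(r"^\s*(\d+)[.)]\s?(.*)$")
_TRAILING_PUNCT = ".,;"


@runtime_checkable
class CompletionBackend(Protocol):
    """Behavior contract for completion providers.

    Implementations must tolerate empty completions (return ``""``
    rather than raising).  Live adapters must retry transient failures
    per their policy and raise :class:`QuotaExhaustedError` when their
    quota runs out.  ``rng`` lets the caller supply per-iteration
    randomness so deterministic mocks are reproducible and resumable;
    live adapters are free to ignore it.
    """

    def complete(
        self, prompt: str, params: QueryParams, rng: np.random.Generator | None = None
    ) -> str: ...


@dataclass(frozen=True, slots=True)
class GenerationRecord:
    """One generated candidate term with its iteration provenance."""

    index_term: str
    term: str
    iteration: int
    raw_text: str

    def __post_init__(self) -> None:
        if self.iteration < 1:
            raise PreconditionError("iteration numbers are 1-based")
        if not self.term or self.term != normalize_term(self.raw_text):
            raise PreconditionError("term must be the normalized, non-empty raw text")

    @property
    def token_count(self) -> int:
        return len(self.term.split())


@dataclass(frozen=True, slots=True)
class TermTally:
    """Aggregate generation frequency of one (index term, term) pair."""

    index_term: str
    term: str
    frequency: int

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise PreconditionError("tally frequency must be >= 1")

    @property
    def token_count(self) -> int:
        return len(self.term.split())


def normalize_term(raw: str) -> str:
    """Canonical form of a parsed list item.

    Lowercase, trim, and drop trailing sentence punctuation (``.,;``)
    so repeated generations of the same term tally together.  Idempotent.
    """
    return raw.strip().lower().rstrip(_TRAILING_PUNCT).strip()


def parse_completion(completion: str, next_index: int) -> list[str]:
    """Extract raw list items from a completion continuing ``next_index.``.

    The completion, prefixed by its hanging enumerator, is split on
    newlines.  The first line (the continuation of the hanging item) is
    taken if non-empty; subsequent lines matching ``N.`` or ``N)``
    followed by text yield items; blank lines are skipped; parsing stops
    at the first line that is neither blank nor a numbered item.  An
    unparseable completion yields an empty list (never an error).
    """
    items: list[str] = []
    prefixed = f"{next_index}." + completion
    for line in prefixed.splitlines():
        if not line.strip():
            continue
        m = _ITEM_RE.match(line)
        if m is None:
            break
        text = m.group(2).rstrip()
        if text.strip():
            items.append(text)
    return items


def term_stream_seed(rng_seed: int, index_term: str, iteration: int) -> np.random.SeedSequence:
    """Deterministic per-(term, iteration) seed, stable across processes."""
    return np.random.SeedSequence([rng_seed, zlib.crc32(index_term.encode("utf-8")), iteration])


def tally(records: Iterable[GenerationRecord]) -> list[TermTally]:
    """Aggregate records into per-term frequencies, sorted by term."""
    counts: Counter[tuple[str, str]] = Counter((r.index_term, r.term) for r in records)
    return [
        TermTally(index_term=it, term=t, frequency=n)
        for (it, t), n in sorted(counts.items())
    ]


def run_iterations(
    sel: IndexTermSelection,
    backend: CompletionBackend,
    params: QueryParams,
    n_iterations: int,
    rng_seed: int,
    *,
    counterexamples: Sequence[str] | None = None,
    skip_iterations: frozenset[int] | set[int] = frozenset(),
    retry_attempts: int = 3,
    retry_wait: float = 0.0,
    checkpoint_path: str | Path | None = None,
) -> tuple[list[GenerationRecord], list[TermTally]]:
    """Run the generation loop for one eligible index term.

    Each iteration samples seed synonyms, renders the prompt (plain, or
    counterexample form when *counterexamples* has four entries),
    requests a completion, parses the numbered list, and normalizes the
    items into :class:`GenerationRecord` objects.  Per-iteration
    randomness is derived from ``(rng_seed, index term, iteration)``
    only, so runs are deterministic with a deterministic backend and an
    interrupted run resumed via *skip_iterations* matches an
    uninterrupted one.

    Transient backend errors are retried ``retry_attempts`` times, then
    the iteration is skipped with a warning (it still counts toward
    *n_iterations*).  On quota exhaustion the partial records are
    checkpointed to *checkpoint_path* (when given) and the error is
    re-raised carrying them.
    """
    if not sel.eligible:
        raise PreconditionError(f"index term {sel.index_term!r} is not eligible")
    if n_iterations < 1:
        raise PreconditionError("n_iterations must be >= 1")

    k = 2 if counterexamples is not None else 3
    records: list[GenerationRecord] = []
    try:
        for iteration in range(1, n_iterations + 1):
            if iteration in skip_iterations:
                continue
            rng = np.random.default_rng(term_stream_seed(rng_seed, sel.index_term, iteration))
            seeds = sample_seed_synonyms(sel, k=k, rng_seed=rng)
            spec = render_prompt(sel.index_term, seeds, counterexamples)
            completion = _complete_with_retry(
                backend, spec.rendered, params, rng, retry_attempts, retry_wait
            )
            if completion is None:
                logger.warning(
                    "iteration %d for %r skipped after %d failed attempts",
                    iteration, sel.index_term, retry_attempts,
                )
                continue
            for raw in parse_completion(completion, spec.next_index):
                term = normalize_term(raw)
                if not term:
                    continue
                records.append(
                    GenerationRecord(
                        index_term=sel.index_term, term=term, iteration=iteration, raw_text=raw
                    )
                )
    except QuotaExhaustedError as exc:
        if checkpoint_path is not None:
            write_generation_log(records, checkpoint_path)
        raise QuotaExhaustedError(str(exc), cache=exc.cache, partial=records) from exc
    return records, tally(records)


def _complete_with_retry(
    backend: CompletionBackend,
    prompt: str,
    params: QueryParams,
    rng: np.random.Generator,
    attempts: int,
    wait: float,
) -> str | None:
    for attempt in range(1, attempts + 1):
        try:
            return backend.complete(prompt, params, rng=rng)
        except TransientBackendError as exc:
            logger.warning("transient backend error (attempt %d/%d): %s", attempt, attempts, exc)
            if attempt < attempts and wait > 0:
                time.sleep(wait * 2 ** (attempt - 1))
    return None


_LOG_COLUMNS = ["index_term", "iteration", "raw_text", "term"]


def write_generation_log(records: Iterable[GenerationRecord], path: str | Path) -> None:
    """Write records as a TSV log: ``index_term, iteration, raw_text, term``."""
    frame = pd.DataFrame(
        [(r.index_term, r.iteration, r.raw_text, r.term) for r in records],
        columns=_LOG_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_generation_log(path: str | Path) -> list[GenerationRecord]:
    """Read a TSV generation log back into records."""
    frame = pd.read_csv(path, sep="\t", dtype={"index_term": str, "raw_text": str, "term": str},
                        keep_default_na=False)
    return [
        GenerationRecord(
            index_term=row["index_term"],
            term=row["term"],
            iteration=int(row["iteration"]),
            raw_text=row["raw_text"],
        )
        for _, row in frame.iterrows()
    ]
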