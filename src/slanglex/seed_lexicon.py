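"""Seed lexicon ingestion and index-term selection.

The seed lexicon is a table of known drug synonyms: one row per *index
term* (a generic drug name) and one column per validation category
(brand names, close edit distance, phonetic misspellings, pill
imprints, search-engine evidence, slang-dictionary presence).  Synonym
cells hold delimiter-separated term lists.  Only a subset of the
categories is trusted enough to seed prompts; brand-name entries that
are multi-word phrases are dropped because they usually embed the drug
name itself and add no information as prompt examples.

Index terms are selected for querying by intersecting them with a
controlled-substance name list; a term is *eligible* when it retains at
least three usable seed synonyms, and *widely discussed* when an
optional per-term forum hit count reaches a cutoff (default 10,000).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from slanglex.errors import FormatError

#: The nine synonym categories of the seed-lexicon layout, in column order.
CATEGORIES: tuple[str, ...] = (
    "known",
    "edOne",
    "edTwo",
    "misspellingPhon",
    "pillMark",
    "google_ms",
    "google_title",
    "google_snippet",
    "ud_slang",
)

#: Categories trusted as prompt seeds (brand names, edit-distance and
#: phonetic misspellings, pill imprints).  Search-engine and
#: slang-dictionary columns carry more false positives and are excluded.
USABLE_CATEGORIES: frozenset[str] = frozenset(
    {"known", "edOne", "edTwo", "misspellingPhon", "pillMark"}
)

INDEX_COLUMN = "index_term"


@dataclass(frozen=True, slots=True)
class SeedEntry:
    """One known synonym of one index term, with its validation category."""

    index_term: str
    synonym: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise FormatError(f"unknown synonym category {self.category!r}")
        if not self.synonym.strip():
            raise FormatError("empty synonym string")


@dataclass(frozen=True)
class SeedLexicon:
    """A collection of :class:`SeedEntry` with case-insensitive membership."""

    entries: tuple[SeedEntry, ...]
    _synonym_set: frozenset[str] = field(init=False, repr=False)
    _index_set: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_synonym_set", frozenset(e.synonym for e in self.entries)
        )
        object.__setattr__(
            self, "_index_set", frozenset(e.index_term for e in self.entries)
        )

    @property
    def index_terms(self) -> frozenset[str]:
        """Distinct index terms present in the lexicon."""
        return self._index_set

    def __contains__(self, term: str) -> bool:
        """Case-insensitive: is *term* a known synonym or an index term?"""
        t = term.strip().lower()
        return t in self._synonym_set or t in self._index_set

    def synonyms_for(
        self, index_term: str, categories: Iterable[str] | None = None
    ) -> tuple[str, ...]:
        """Distinct synonyms of *index_term*, sorted, optionally by category."""
        it = index_term.strip().lower()
        cats = set(categories) if categories is not None else set(CATEGORIES)
        return tuple(
            sorted(
                {
                    e.synonym
                    for e in self.entries
                    if e.index_term == it and e.category in cats
                }
            )
        )

    def to_frame(self, delimiter: str = "|") -> pd.DataFrame:
        """One row per index term, synonym lists joined with *delimiter*."""
        rows = []
        for it in sorted(self._index_set):
            row: dict[str, str] = {INDEX_COLUMN: it}
            for cat in CATEGORIES:
                syns = sorted(
                    {e.synonym for e in self.entries if e.index_term == it and e.category == cat}
                )
                row[cat] = delimiter.join(syns)
            rows.append(row)
        return pd.DataFrame(rows, columns=[INDEX_COLUMN, *CATEGORIES])

    def write(self, path: str | Path, delimiter: str = "|") -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
        self.to_frame(delimiter).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True, slots=True)
class IndexTermSelection:
    """One index term's querying status after intersection and eligibility."""

    index_term: str
    usable_synonyms: tuple[str, ...]
    eligible: bool
    widely_discussed: bool
    reddit_hits: int | None = None

    def __post_init__(self) -> None:
        if self.eligible != (len(self.usable_synonyms) >= 3):
            raise ValueError("eligible flag inconsistent with synonym count")
        if self.widely_discussed and self.reddit_hits is None:
            raise ValueError("widely_discussed requires a hit count")


def _table_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_seed_lexicon(
    path: str | Path,
    usable_categories: Iterable[str] = USABLE_CATEGORIES,
    delimiter: str = "|",
) -> SeedLexicon:
    """Read a seed-lexicon table restricted to *usable_categories*.

    Every term is lowercased and whitespace-trimmed at load so that all
    downstream comparisons (drug-name cross-reference, novelty checks)
    are case-insensitive.  Brand-name (``known``) entries containing
    internal whitespace are dropped — multi-word brand entries are
    typically phrases that already contain a known synonym.  Duplicate
    synonyms within one (index term, category) cell are collapsed.

    Raises
    ------
    FormatError
        If a required column is missing (named in the message) or the
        table has no rows.
    """
    path = Path(path)
    usable = set(usable_categories)
    unknown = usable - set(CATEGORIES)
    if unknown:
        raise FormatError(f"unknown usable categories: {sorted(unknown)}")
    try:
        frame = pd.read_csv(path, sep=_table_sep(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"seed lexicon file {path} is empty") from exc
    for col in (INDEX_COLUMN, *CATEGORIES):
        if col not in frame.columns:
            raise FormatError(f"seed lexicon {path} is missing required column {col!r}")
    if frame.empty:
        raise FormatError(f"seed lexicon {path} has no data rows")

    entries: list[SeedEntry] = []
    for _, row in frame.iterrows():
        index_term = str(row[INDEX_COLUMN]).strip().lower()
        if not index_term:
            raise FormatError(f"seed lexicon {path} has a row with an empty index term")
        for cat in CATEGORIES:
            if cat not in usable:
                continue
            seen: set[str] = set()
            for raw in str(row[cat]).split(delimiter):
                syn = raw.strip().lower()
                if not syn:
                    continue
                if cat == "known" and any(ch.isspace() for ch in syn):
                    continue  # single-word rule for brand-name entries
                if syn in seen:
                    continue  # collapse duplicates within one category cell
                seen.add(syn)
                entries.append(SeedEntry(index_term=index_term, synonym=syn, category=cat))
    return SeedLexicon(entries=tuple(entries))


def load_controlled_names(path: str | Path) -> frozenset[str]:
    """Read a controlled-substance list: one name per line, ``#`` comments."""
    names: set[str] = set()
    text = Path(path).read_text(encoding="utf-8")
    for line in io.StringIO(text):
        line = line.split("#", 1)[0].strip().lower()
        if line:
            names.add(line)
    return frozenset(names)


def load_hit_counts(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``index_term<TAB>hits`` into a dict."""
    frame = pd.read_csv(path, sep="\t", header=None, names=[INDEX_COLUMN, "hits"], dtype=str)
    counts: dict[str, int] = {}
    for _, row in frame.iterrows():
        try:
            counts[str(row[INDEX_COLUMN]).strip().lower()] = int(row["hits"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"bad hit count row {tuple(row)!r} in {path}") from exc
    return counts


def select_index_terms(
    lex: SeedLexicon,
    controlled_names: Iterable[str],
    hit_counts: Mapping[str, int] | None = None,
    cutoff: int = 10_000,
) -> list[IndexTermSelection]:
    """Intersect index terms with the controlled list and mark eligibility.

    Returns one record per index term in the (case-insensitive, exact
    string) intersection, sorted lexicographically.  A term is eligible
    when it has at least three distinct usable seed synonyms; it is
    widely discussed when *hit_counts* lists it with at least *cutoff*
    hits.  An empty intersection yields an empty list.
    """
    controlled = {str(n).strip().lower() for n in controlled_names}
    selections: list[IndexTermSelection] = []
    for it in sorted(lex.index_terms & controlled):
        syns = lex.synonyms_for(it)
        hits = None
        if hit_counts is not None and it in hit_counts:
            hits = int(hit_counts[it])
        selections.append(
            IndexTermSelection(
                index_term=it,
                usable_synonyms=syns,
                eligible=len(syns) >= 3,
                widely_discussed=hits is not None and hits >= cutoff,
                reddit_hits=hits,
            )
        )
    return selections
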