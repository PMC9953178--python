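"""Prompt construction for few-shot synonym elicitation.

Two templates are supported.  The plain template lists three known
synonyms of the index term as a numbered list and leaves a hanging
``4.`` so the completion model continues the enumeration.  The
counterexample template first lists four terms that are *not* synonyms
(typically same-indication drugs the model tends to confuse with the
index term), then two known synonyms, leaving a hanging ``3.``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field

from slanglex.errors import FormatError, PreconditionError
from slanglex.seed_lexicon import IndexTermSelection

PLAIN_TEMPLATE = "ways to say {index_term}:\n1. {seed_1}\n2. {seed_2}\n3. {seed_3}\n4."

COUNTEREXAMPLE_TEMPLATE = (
    "these are not synonyms for {index_term}:\n"
    "1. {counter_1}\n2. {counter_2}\n3. {counter_3}\n4. {counter_4}\n"
    "but these are synonyms for {index_term}:\n"
    "1. {seed_1}\n2. {seed_2}\n3."
)

_HANGING_RE = re.compile(r"(\d+)\.\s*$")


class QueryParams(BaseModel):
    """Sampling parameters forwarded to the completion backend.

    ``temperature`` trades likelihood for diversity (0 = greedy).  The
    frequency penalty discourages verbatim token repetition and the
    presence penalty discourages topic repetition; both range over
    [-2, 2] with 0 meaning no penalty.  ``max_tokens`` bounds the
    completion length; the default 256 comfortably fits the ~7 list
    items a typical completion carries.
    """

    model_config = {"frozen": True}

    temperature: float = Field(default=1.0, ge=0.0, le=1.0)
    frequency_penalty: float = Field(default=0.0, ge=-2.0, le=2.0)
    presence_penalty: float = Field(default=0.0, ge=-2.0, le=2.0)
    max_tokens: int = Field(default=256, gt=0)


@dataclass(frozen=True, slots=True)
class PromptSpec:
    """A fully rendered prompt plus the pieces it was built from."""

    index_term: str
    seed_synonyms: tuple[str, ...]
    counterexamples: tuple[str, ...] | None
    rendered: str

    @property
    def next_index(self) -> int:
        """The hanging enumerator the completion is expected to continue."""
        m = _HANGING_RE.search(self.rendered)
        if m is None:  # unreachable for the shipped templates
            raise PreconditionError("rendered prompt does not end with a hanging enumerator")
        return int(m.group(1))


def sample_seed_synonyms(
    sel: IndexTermSelection, k: int = 3, rng_seed: int | np.random.Generator = 0
) -> list[str]:
    """Uniformly sample *k* distinct seed synonyms without replacement.

    Deterministic given *rng_seed* (an int seed or a live Generator).
    The selection must be eligible and hold at least *k* usable synonyms.
    """
    if not sel.eligible:
        raise PreconditionError(f"index term {sel.index_term!r} is not eligible for querying")
    pool = sel.usable_synonyms
    if k > len(pool):
        raise PreconditionError(
            f"cannot sample {k} synonyms for {sel.index_term!r}: only {len(pool)} available"
        )
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def render_prompt(
    index_term: str,
    seeds: Sequence[str],
    counterexamples: Sequence[str] | None = None,
    *,
    plain_template: str = PLAIN_TEMPLATE,
    counterexample_template: str = COUNTEREXAMPLE_TEMPLATE,
) -> PromptSpec:
    """Render the prompt for *index_term*; pure function of its inputs.

    The plain form takes exactly 3 seeds; the counterexample form takes
    exactly 2 seeds and 4 counterexamples.
    """
    index_term = index_term.strip()
    if not index_term:
        raise PreconditionError("index term must be non-empty")
    seeds = tuple(seeds)
    if len(set(seeds)) != len(seeds):
        raise PreconditionError("seed synonyms must be distinct")
    if counterexamples is None:
        if len(seeds) != 3:
            raise PreconditionError(f"plain template needs exactly 3 seeds, got {len(seeds)}")
        rendered = plain_template.format(
            index_term=index_term, seed_1=seeds[0], seed_2=seeds[1], seed_3=seeds[2]
        )
        counters = None
    else:
        counters = tuple(counterexamples)
        if len(seeds) != 2 or len(counters) != 4:
            raise PreconditionError(
                "counterexample template needs exactly 2 seeds and 4 counterexamples, "
                f"got {len(seeds)} and {len(counters)}"
            )
        rendered = counterexample_template.format(
            index_term=index_term,
            counter_1=counters[0],
            counter_2=counters[1],
            counter_3=counters[2],
            counter_4=counters[3],
            seed_1=seeds[0],
            seed_2=seeds[1],
        )
    return PromptSpec(
        index_term=index_term, seed_synonyms=seeds, counterexamples=counters, rendered=rendered
    )


def load_templates(path: str | Path) -> dict[str, str]:
    """Load prompt templates from a YAML file.

    The file maps ``plain`` / ``counterexample`` to template strings
    using ``{index_term}``, ``{seed_i}`` and ``{counter_i}``
    placeholders.  Each template must end with a hanging enumerator.
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise FormatError(f"template file {path} must be a mapping")
    templates: dict[str, str] = {}
    for key in ("plain", "counterexample"):
        if key in data:
            tpl = str(data[key])
            if _HANGING_RE.search(tpl) is None:
                raise FormatError(f"template {key!r} does not end with a hanging enumerator")
            templates[key] = tpl
    if not templates:
        raise FormatError(f"template file {path} defines neither 'plain' nor 'counterexample'")
    return templates
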