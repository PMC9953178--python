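"""End-to-end orchestration: generate → filter → evaluate → lexicon.

A run is described by a :class:`PipelineConfig`.  For every eligible
index term the generation loop is executed for ``n_iterations``, the
tallied candidates are passed through the filters, and the terms
passing the drug-name and search filters become the published lexicon
rows.  Runs are resumable: per-term generation logs and search caches
are checkpointed, and quota exhaustion stops the run cleanly in a state
from which ``resume=True`` reproduces exactly what an uninterrupted run
would have produced (with deterministic backends).  A manifest
capturing the full configuration is written alongside the outputs, and
replaying a manifest reproduces them byte-identically.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from slanglex.errors import ConfigurationError, QuotaExhaustedError
from slanglex.evaluation import (
    MetricsReport,
    NoveltyAccount,
    SweepKey,
    load_labels,
    novelty_account,
    reports_to_frame,
    scheme_comparison,
    sweep_summary,
)
from slanglex.filtering import (
    FilterFlags,
    GoogleFilterConfig,
    SearchCache,
    apply_scheme,
    write_filter_report,
)
from slanglex.generation import (
    GenerationRecord,
    TermTally,
    read_generation_log,
    run_iterations,
    tally,
    write_generation_log,
)
from slanglex.prompting import QueryParams
from slanglex.seed_lexicon import (
    CATEGORIES,
    IndexTermSelection,
    SeedLexicon,
    load_controlled_names,
    load_hit_counts,
    load_seed_lexicon,
    select_index_terms,
)

logger = logging.getLogger(__name__)

LEXICON_COLUMNS = [
    "index_term", "term", "frequency", "first_hit_depth", "matching_variant",
    "passes_drug_name", "passes_google", "in_seed_lexicon", "is_ungs", "token_count",
]


class PipelineConfig(BaseModel):
    """Full description of a pipeline run.

    The defaults are the published final settings: 1000 iterations per
    index term, temperature 1.0 with zero penalties, the plain prompt
    template, search depth 10 with the four query variants, and the
    drug-name + search filtering scheme.  Mock backends require a world
    directory; live adapters take credentials from the environment only
    and are not bundled here.
    """

    seed_lexicon_path: Path
    controlled_list_path: Path
    output_dir: Path
    hit_counts_path: Path | None = None
    labels_path: Path | None = None
    world_path: Path | None = None

    n_iterations: int = Field(default=1000, ge=1)
    query: QueryParams = QueryParams()
    google: GoogleFilterConfig = GoogleFilterConfig()
    scheme: tuple[str, ...] = ("drug_name", "google")
    frequency_threshold: int = Field(default=1, ge=1)
    template: Literal["plain", "counterexample"] = "plain"
    counterexamples: dict[str, tuple[str, str, str, str]] = Field(default_factory=dict)
    rng_seed: int = Field(default=0, ge=0)
    widely_discussed_cutoff: int = Field(default=10_000, ge=1)
    completion_backend: Literal["mock", "live"] = "mock"
    search_backend: Literal["mock", "live"] = "mock"
    max_index_terms: int | None = Field(default=None, ge=1)
    resume: bool = False

    @model_validator(mode="after")
    def _backends_resolvable(self) -> "PipelineConfig":
        if "mock" in (self.completion_backend, self.search_backend) and self.world_path is None:
            raise ConfigurationError("mock backends require world_path (a world directory)")
        return self


@dataclass(frozen=True, slots=True)
class LexiconEntry:
    """One published lexicon row: a term passing drug-name + search filters."""

    index_term: str
    term: str
    frequency: int
    first_hit_depth: int | None
    matching_variant: str | None
    passes_drug_name: bool
    passes_google: bool
    in_seed_lexicon: bool
    is_ungs: bool
    token_count: int

    def __post_init__(self) -> None:
        if self.is_ungs and self.in_seed_lexicon:
            raise ValueError("a novel synonym cannot be in the seed lexicon")


@dataclass
class PipelineResult:
    """In-memory view of a completed run (files are the durable outputs)."""

    selections: list[IndexTermSelection]
    records: dict[str, list[GenerationRecord]]
    tallies: dict[str, list[TermTally]]
    flags: dict[str, dict[str, FilterFlags]]
    lexicon: pd.DataFrame
    novelty: dict[str, NoveltyAccount]
    evaluation: dict[str, list[MetricsReport]]
    manifest: dict


def _resolve_backends(cfg: PipelineConfig, completion=None, search=None):
    """Instantiate backends per config unless overridden by the caller."""
    from slanglex.worlds import load_world  # local import: worlds uses evaluation types

    world = None
    if completion is None or search is None:
        if "live" in (cfg.completion_backend, cfg.search_backend) and (
            (completion is None and cfg.completion_backend == "live")
            or (search is None and cfg.search_backend == "live")
        ):
            raise ConfigurationError(
                "live backends are not bundled; pass backend objects to run_pipeline "
                "(credentials must come from the environment, never the config file)"
            )
        world = load_world(cfg.world_path)
    if completion is None:
        completion = world.completion_backend()
    if search is None:
        search = world.search_backend()
    return completion, search


def _term_seed(rng_seed: int, index_term: str) -> int:
    return (rng_seed + zlib.crc32(index_term.encode("utf-8"))) % (2**31)


def run_pipeline(
    cfg: PipelineConfig, *, completion_backend=None, search_backend=None
) -> PipelineResult:
    """Execute a full run and write its outputs under ``cfg.output_dir``.

    Outputs: ``lexicon.tsv`` (the published rows), ``filter_report.tsv``,
    ``novelty.tsv``, per-term generation logs and search caches under
    ``checkpoints/`` and ``cache/``, ``evaluation.tsv`` when labels are
    configured, and ``manifest.yaml``.  On quota exhaustion the partial
    state is checkpointed and :class:`QuotaExhaustedError` propagates;
    rerunning with ``resume=True`` completes the run.
    """
    completion, search = _resolve_backends(cfg, completion_backend, search_backend)
    out = Path(cfg.output_dir)
    (out / "checkpoints").mkdir(parents=True, exist_ok=True)
    (out / "cache").mkdir(parents=True, exist_ok=True)

    seed_usable = load_seed_lexicon(cfg.seed_lexicon_path)
    seed_full = load_seed_lexicon(cfg.seed_lexicon_path, usable_categories=CATEGORIES)
    controlled = load_controlled_names(cfg.controlled_list_path)
    hits = load_hit_counts(cfg.hit_counts_path) if cfg.hit_counts_path else None
    selections = select_index_terms(
        seed_usable, controlled, hits, cutoff=cfg.widely_discussed_cutoff
    )
    eligible = [s for s in selections if s.eligible]
    if not eligible:
        raise ConfigurationError("no eligible index terms after selection")
    if cfg.max_index_terms is not None:
        eligible = eligible[: cfg.max_index_terms]

    labels_by_term: dict[str, list] = {}
    if cfg.labels_path is not None:
        for lab in load_labels(cfg.labels_path):
            labels_by_term.setdefault(lab.index_term, []).append(lab)

    records: dict[str, list[GenerationRecord]] = {}
    tallies: dict[str, list[TermTally]] = {}
    flags: dict[str, dict[str, FilterFlags]] = {}
    novelty: dict[str, NoveltyAccount] = {}
    evaluation: dict[str, list[MetricsReport]] = {}
    lexicon_rows: list[LexiconEntry] = []

    for sel in eligible:
        it = sel.index_term
        gen_path = out / "checkpoints" / f"{it}.gen.tsv"
        cache_path = out / "cache" / f"{it}.cache.tsv"

        prior: list[GenerationRecord] = []
        skip: frozenset[int] = frozenset()
        if cfg.resume and gen_path.exists():
            prior = read_generation_log(gen_path)
            skip = frozenset(r.iteration for r in prior)
        counters = cfg.counterexamples.get(it) if cfg.template == "counterexample" else None
        if cfg.template == "counterexample" and counters is None:
            raise ConfigurationError(f"no counterexamples configured for {it!r}")
        try:
            fresh, _ = run_iterations(
                sel, completion, cfg.query, cfg.n_iterations,
                _term_seed(cfg.rng_seed, it),
                counterexamples=counters, skip_iterations=skip,
                checkpoint_path=gen_path,
            )
        except QuotaExhaustedError as exc:
            # run_iterations checkpointed only its own fresh records; merge.
            merged = sorted(prior + list(exc.partial or []), key=lambda r: r.iteration)
            write_generation_log(merged, gen_path)
            _write_manifest(cfg, out, selections, status="interrupted-resumable")
            raise
        recs = sorted(prior + fresh, key=lambda r: r.iteration)
        write_generation_log(recs, gen_path)
        records[it] = recs
        tallies[it] = tally(recs)

        cache = SearchCache.load(cache_path) if (cfg.resume and cache_path.exists()) else SearchCache()
        try:
            flags[it] = apply_scheme(
                tallies[it], cfg.scheme,
                all_index_terms=seed_usable.index_terms,
                search_backend=search, google_config=cfg.google,
                cache=cache, frequency_threshold=cfg.frequency_threshold,
            )
        except QuotaExhaustedError as exc:
            if exc.cache is not None:
                exc.cache.save(cache_path)
            _write_manifest(cfg, out, selections, status="interrupted-resumable")
            raise
        cache.save(cache_path)

        novelty[it] = novelty_account(it, tallies[it], flags[it], cfg.scheme, seed_full)
        if it in labels_by_term:
            evaluation[it] = scheme_comparison(
                tallies[it], flags[it], labels_by_term[it], seed_full
            )
        for t in tallies[it]:
            f = flags[it][t.term]
            if not (f.passes_drug_name and f.passes_google):
                continue
            in_seed = t.term in seed_full or t.term == it
            g = f.google
            lexicon_rows.append(
                LexiconEntry(
                    index_term=it, term=t.term, frequency=t.frequency,
                    first_hit_depth=None if g is None else g.first_hit_depth,
                    matching_variant=None if g is None else g.matching_variant,
                    passes_drug_name=f.passes_drug_name, passes_google=f.passes_google,
                    in_seed_lexicon=in_seed, is_ungs=not in_seed,
                    token_count=t.token_count,
                )
            )
        logger.info(
            "%s: %d generation events, %d unique, %d in lexicon",
            it, sum(t.frequency for t in tallies[it]), len(tallies[it]),
            sum(1 for r in lexicon_rows if r.index_term == it),
        )

    lexicon = pd.DataFrame(
        [
            {
                "index_term": r.index_term, "term": r.term, "frequency": r.frequency,
                "first_hit_depth": "" if r.first_hit_depth is None else r.first_hit_depth,
                "matching_variant": "" if r.matching_variant is None else r.matching_variant,
                "passes_drug_name": r.passes_drug_name, "passes_google": r.passes_google,
                "in_seed_lexicon": r.in_seed_lexicon, "is_ungs": r.is_ungs,
                "token_count": r.token_count,
            }
            for r in sorted(lexicon_rows, key=lambda r: (r.index_term, r.term))
        ],
        columns=LEXICON_COLUMNS,
    )
    lexicon.to_csv(out / "lexicon.tsv", sep="\t", index=False)

    all_tallies = [t for ts in tallies.values() for t in ts]
    merged_flags = {t.term: flags[t.index_term][t.term] for t in all_tallies}
    write_filter_report(all_tallies, merged_flags, out / "filter_report.tsv")

    pd.DataFrame(
        [
            {
                "index_term": n.index_term, "total_generated": n.total_generated,
                "unique_generated": n.unique_generated,
                "gpt3_synonyms": n.gpt3_synonyms, "ungs": n.ungs,
            }
            for n in novelty.values()
        ]
    ).to_csv(out / "novelty.tsv", sep="\t", index=False)

    if evaluation:
        frames = []
        for it, reports in evaluation.items():
            frame = reports_to_frame(reports)
            frame.insert(0, "index_term", it)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(out / "evaluation.tsv", sep="\t", index=False)

    manifest = _write_manifest(cfg, out, selections, status="complete")
    return PipelineResult(
        selections=selections, records=records, tallies=tallies, flags=flags,
        lexicon=lexicon, novelty=novelty, evaluation=evaluation, manifest=manifest,
    )


def _write_manifest(
    cfg: PipelineConfig, out: Path, selections: Sequence[IndexTermSelection], status: str
) -> dict:
    from importlib.metadata import version

    try:
        pkg_version = version("slanglex")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "package_version": pkg_version,
        "status": status,
        "config": yaml.safe_load(yaml.safe_dump(_config_dump(cfg))),
        "counts": {
            "index_terms_selected": len(selections),
            "eligible": sum(1 for s in selections if s.eligible),
            "widely_discussed": sum(1 for s in selections if s.widely_discussed),
        },
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")
    return manifest


def _config_dump(cfg: PipelineConfig) -> dict:
    dump = cfg.model_dump(mode="json")
    return dump


def run_from_manifest(
    manifest_path: str | Path,
    output_dir: str | Path | None = None,
    *,
    completion_backend=None,
    search_backend=None,
) -> PipelineResult:
    """Replay a recorded manifest; reproduces the outputs byte-identically
    with deterministic backends."""
    manifest = yaml.safe_load(Path(manifest_path).read_text(encoding="utf-8"))
    cfg = PipelineConfig(**manifest["config"])
    if output_dir is not None:
        cfg = cfg.model_copy(update={"output_dir": Path(output_dir)})
    return run_pipeline(cfg, completion_backend=completion_backend, search_backend=search_backend)


DEFAULT_GRID: dict[str, tuple] = {
    "temperature": (0.0, 0.3, 0.6, 1.0),
    "frequency_penalty": (0.0, 0.5, 1.0),
    "presence_penalty": (0.0, 0.5, 1.0),
    "template": ("plain", "counterexample"),
}


def run_sweep(
    cfg: PipelineConfig,
    grid: Mapping[str, Sequence] | None = None,
    index_term: str | None = None,
    *,
    completion_backend=None,
    search_backend=None,
) -> pd.DataFrame:
    """Run the sampling-parameter sweep on one index term.

    *grid* maps axes (``temperature``, ``frequency_penalty``,
    ``presence_penalty``, ``template``) to value lists; missing axes
    stay at the config's values.  Each grid point runs the full
    generate → filter chain at ``cfg.n_iterations`` and is summarized by
    its novelty yield.  One shared search cache serves all points, since
    search outcomes do not depend on sampling parameters.
    """
    grid = dict(grid if grid is not None else DEFAULT_GRID)
    unknown = set(grid) - {"temperature", "frequency_penalty", "presence_penalty", "template"}
    if unknown:
        raise ConfigurationError(f"unknown sweep axes: {sorted(unknown)}")
    completion, search = _resolve_backends(cfg, completion_backend, search_backend)

    seed_usable = load_seed_lexicon(cfg.seed_lexicon_path)
    seed_full = load_seed_lexicon(cfg.seed_lexicon_path, usable_categories=CATEGORIES)
    controlled = load_controlled_names(cfg.controlled_list_path)
    selections = [s for s in select_index_terms(seed_usable, controlled) if s.eligible]
    if not selections:
        raise ConfigurationError("no eligible index terms for the sweep")
    if index_term is not None:
        matching = [s for s in selections if s.index_term == index_term]
        if not matching:
            raise ConfigurationError(f"index term {index_term!r} is not eligible")
        sel = matching[0]
    else:
        sel = selections[0]

    temperatures = tuple(grid.get("temperature", (cfg.query.temperature,)))
    freq_pens = tuple(grid.get("frequency_penalty", (cfg.query.frequency_penalty,)))
    pres_pens = tuple(grid.get("presence_penalty", (cfg.query.presence_penalty,)))
    templates = tuple(grid.get("template", (cfg.template,)))
    if "counterexample" in templates and sel.index_term not in cfg.counterexamples:
        raise ConfigurationError(
            f"sweep includes the counterexample template but no counterexamples "
            f"are configured for {sel.index_term!r}"
        )

    cache = SearchCache()
    accounts: dict[SweepKey, NoveltyAccount] = {}
    for temp in temperatures:
        for template in templates:
            for fp in freq_pens:
                for pp in pres_pens:
                    key = SweepKey(temp, template, fp, pp)
                    params = cfg.query.model_copy(
                        update={
                            "temperature": temp,
                            "frequency_penalty": fp,
                            "presence_penalty": pp,
                        }
                    )
                    point_seed = (
                        _term_seed(cfg.rng_seed, sel.index_term)
                        + zlib.crc32(repr(key).encode("utf-8"))
                    ) % (2**31)
                    counters = (
                        cfg.counterexamples.get(sel.index_term)
                        if template == "counterexample"
                        else None
                    )
                    _, point_tallies = run_iterations(
                        sel, completion, params, cfg.n_iterations, point_seed,
                        counterexamples=counters,
                    )
                    point_flags = apply_scheme(
                        point_tallies, cfg.scheme,
                        all_index_terms=seed_usable.index_terms,
                        search_backend=search, google_config=cfg.google, cache=cache,
                        frequency_threshold=cfg.frequency_threshold,
                    )
                    accounts[key] = novelty_account(
                        sel.index_term, point_tallies, point_flags, cfg.scheme, seed_full
                    )
    summary = sweep_summary(accounts)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "sweep_summary.tsv", sep="\t", index=False)
    return summary
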