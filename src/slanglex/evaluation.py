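"""Evaluation of candidate-term classification against manual labels.

Filtering schemes are binary classifiers over generated terms; manual
labels (synonym / non-synonym) serve as a proxy for ground truth.  The
quality metrics are precision, recall, and the F-beta family::

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 p r / (p + r)
    F2        = 5 p r / (4 p + r)

F2 (beta = 2) weights recall over precision: a synonym missing from the
lexicon can never flag a post, while a false positive can be filtered
downstream.  A metric whose denominator is zero is reported as absent
rather than coerced to 0.

Also here: novelty accounting (how many terms survive the filters and
are absent from the seed lexicon — the pipeline's yield metric), and
the depth/frequency histograms and parameter-sweep summaries used to
choose filter and sampling settings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from slanglex.errors import DataError
from slanglex.filtering import FilterFlags, GoogleOutcome, positives
from slanglex.generation import TermTally
from slanglex.seed_lexicon import SeedLexicon

SYNONYM = "synonym"
NON_SYNONYM = "non-synonym"

#: The six classification schemes compared in the study, in report order.
COMPARISON_SCHEMES: tuple[tuple[str, frozenset[str] | None], ...] = (
    ("All generated terms", frozenset()),
    ("All seed-lexicon terms", None),  # membership baseline, not a filter scheme
    ("Drug name filter", frozenset({"drug_name"})),
    ("Drug name & frequency filters", frozenset({"drug_name", "frequency"})),
    ("Drug name & Google filters", frozenset({"drug_name", "google"})),
    ("Drug name, frequency, & Google filters", frozenset({"drug_name", "frequency", "google"})),
)


@dataclass(frozen=True, slots=True)
class ManualLabel:
    """A human judgment: is *term* a valid synonym of *index_term*?"""

    index_term: str
    term: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (SYNONYM, NON_SYNONYM):
            raise DataError(f"label must be {SYNONYM!r} or {NON_SYNONYM!r}, got {self.label!r}")


@dataclass(frozen=True, slots=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion counts must be nonnegative")


@dataclass(frozen=True, slots=True)
class MetricsReport:
    """Precision/recall/F1/F2 for one scheme; absent metrics are ``None``."""

    scheme: str
    cm: ConfusionMatrix
    precision: float | None
    recall: float | None
    f1: float | None
    f2: float | None

    def to_row(self, ndigits: int = 3) -> dict[str, object]:
        """Presentation row; rounding happens here only."""
        def r(x: float | None) -> float | None:
            return None if x is None else round(x, ndigits)

        return {
            "scheme": self.scheme,
            "tp": self.cm.tp,
            "fp": self.cm.fp,
            "fn": self.cm.fn,
            "tn": self.cm.tn,
            "precision": r(self.precision),
            "recall": r(self.recall),
            "f1": r(self.f1),
            "f2": r(self.f2),
        }


@dataclass(frozen=True, slots=True)
class NoveltyAccount:
    """Per-index-term yield accounting.

    ``ungs`` counts unique novel synonyms: distinct terms that pass the
    active scheme and appear nowhere in the seed lexicon (any synonym
    category or index term).  The chain
    ``ungs <= gpt3_synonyms <= unique_generated <= total_generated``
    always holds.
    """

    index_term: str
    total_generated: int
    unique_generated: int
    gpt3_synonyms: int
    ungs: int

    def __post_init__(self) -> None:
        if not (0 <= self.ungs <= self.gpt3_synonyms <= self.unique_generated <= self.total_generated):
            raise DataError("novelty chain inequality violated")


def load_labels(path: str | Path) -> list[ManualLabel]:
    """Read a label CSV ``index_term,term,label``."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("index_term", "term", "label"):
        if col not in frame.columns:
            raise DataError(f"label file {path} is missing column {col!r}")
    return [
        ManualLabel(
            index_term=row["index_term"].strip().lower(),
            term=row["term"].strip().lower(),
            label=row["label"].strip(),
        )
        for _, row in frame.iterrows()
    ]


def _label_map(labels: Iterable[ManualLabel]) -> dict[str, bool]:
    out: dict[str, bool] = {}
    for lab in labels:
        prev = out.get(lab.term)
        is_syn = lab.label == SYNONYM
        if prev is not None and prev != is_syn:
            raise DataError(f"conflicting labels for term {lab.term!r}")
        out[lab.term] = is_syn
    return out


def confusion(
    predicted_positive: Iterable[str],
    labels: Iterable[ManualLabel],
    universe: Iterable[str] | None = None,
) -> ConfusionMatrix:
    """Confusion matrix of a predicted-positive set against labels.

    The evaluated universe defaults to the labeled terms; pass
    *universe* (e.g. the generated terms) to restrict it.  Every
    evaluated term must be labeled — unlabeled terms raise
    :class:`DataError` listing them.
    """
    lab = _label_map(labels)
    pred = set(predicted_positive)
    uni = set(universe) if universe is not None else set(lab)
    unlabeled = sorted((uni | pred) - set(lab))
    if unlabeled:
        raise DataError(f"unlabeled evaluated terms: {unlabeled}")
    pred &= uni
    tp = sum(1 for t in pred if lab[t])
    fp = len(pred) - tp
    fn = sum(1 for t in uni - pred if lab[t])
    tn = len(uni - pred) - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(cm: ConfusionMatrix, scheme: str = "") -> MetricsReport:
    """Precision, recall, F1 and F2 from a confusion matrix.

    Values are kept at full precision; rounding is applied only when a
    report is serialized.
    """
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    f1 = f2 = None
    if precision is not None and recall is not None:
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        if 4 * precision + recall > 0:
            f2 = 5 * precision * recall / (4 * precision + recall)
    return MetricsReport(scheme=scheme, cm=cm, precision=precision, recall=recall, f1=f1, f2=f2)


def scheme_comparison(
    tallies: Sequence[TermTally],
    flags: Mapping[str, FilterFlags],
    labels: Iterable[ManualLabel],
    seed_lex: SeedLexicon,
) -> list[MetricsReport]:
    """Metrics for the six standard classification schemes.

    Rows: the all-generated baseline, the seed-lexicon membership
    baseline, drug-name only, drug-name+frequency, drug-name+Google,
    and all three filters.  Labels must cover every tallied term.
    """
    labels = list(labels)
    if not labels:
        raise DataError("empty label set")
    universe = {t.term for t in tallies}
    reports: list[MetricsReport] = []
    for name, scheme in COMPARISON_SCHEMES:
        if scheme is None:
            pred = {t for t in universe if t in seed_lex}
        else:
            pred = positives(flags, scheme) & universe if scheme else set(universe)
        reports.append(metrics(confusion(pred, labels, universe=universe), scheme=name))
    return reports


def reports_to_frame(reports: Iterable[MetricsReport], ndigits: int = 3) -> pd.DataFrame:
    """Serialize reports as a table (rounded at this boundary only)."""
    return pd.DataFrame([r.to_row(ndigits) for r in reports])


def novelty_account(
    index_term: str,
    tallies: Sequence[TermTally],
    flags: Mapping[str, FilterFlags],
    scheme: Iterable[str],
    seed_lex: SeedLexicon,
) -> NoveltyAccount:
    """Yield accounting for one index term under *scheme*.

    A term equal to the queried index term may pass the filters but can
    never be novel, since every index term is in the seed lexicon.
    """
    mine = [t for t in tallies if t.index_term == index_term]
    pos = positives(flags, scheme) & {t.term for t in mine}
    novel = {t for t in pos if t not in seed_lex and t != index_term}
    return NoveltyAccount(
        index_term=index_term,
        total_generated=sum(t.frequency for t in mine),
        unique_generated=len(mine),
        gpt3_synonyms=len(pos),
        ungs=len(novel),
    )


def depth_histogram(
    outcomes: Iterable[GoogleOutcome], labels: Iterable[ManualLabel] | None = None
) -> pd.DataFrame:
    """Counts of terms by first-hit search depth, split by label if given.

    Only passing outcomes contribute (failing terms have no depth).
    Without labels, a single ``count`` column is produced.
    """
    passed = [o for o in outcomes if o.passed]
    if labels is None:
        counts = Counter(o.first_hit_depth for o in passed)
        return pd.DataFrame(
            [{"bin": d, "count": n} for d, n in sorted(counts.items())],
            columns=["bin", "count"],
        )
    lab = _label_map(labels)
    syn: Counter[int] = Counter()
    non: Counter[int] = Counter()
    for o in passed:
        if o.term not in lab:
            raise DataError(f"unlabeled term in outcomes: {o.term!r}")
        (syn if lab[o.term] else non)[o.first_hit_depth] += 1
    bins = sorted(set(syn) | set(non))
    return pd.DataFrame(
        [{"bin": d, "count_synonym": syn[d], "count_nonsynonym": non[d]} for d in bins],
        columns=["bin", "count_synonym", "count_nonsynonym"],
    )


def frequency_histogram(
    tallies: Sequence[TermTally],
    labels: Iterable[ManualLabel] | None = None,
    with_google: bool = False,
    flags: Mapping[str, FilterFlags] | None = None,
) -> pd.DataFrame:
    """Counts of terms by generation frequency, split by label if given.

    With ``with_google=True`` only terms passing the search filter are
    counted (*flags* must then be supplied).
    """
    if with_google:
        if flags is None:
            raise DataError("with_google requires filter flags")
        tallies = [t for t in tallies if t.term in flags and flags[t.term].passes_google]
    if labels is None:
        counts = Counter(t.frequency for t in tallies)
        return pd.DataFrame(
            [{"bin": f, "count": n} for f, n in sorted(counts.items())],
            columns=["bin", "count"],
        )
    lab = _label_map(labels)
    syn: Counter[int] = Counter()
    non: Counter[int] = Counter()
    for t in tallies:
        if t.term not in lab:
            raise DataError(f"unlabeled tallied term: {t.term!r}")
        (syn if lab[t.term] else non)[t.frequency] += 1
    bins = sorted(set(syn) | set(non))
    return pd.DataFrame(
        [{"bin": f, "count_synonym": syn[f], "count_nonsynonym": non[f]} for f in bins],
        columns=["bin", "count_synonym", "count_nonsynonym"],
    )


class SweepKey(NamedTuple):
    """One point of the sampling-parameter grid."""

    temperature: float
    template: str  # "plain" | "counterexample"
    frequency_penalty: float
    presence_penalty: float


def sweep_summary(accounts: Mapping[SweepKey, NoveltyAccount]) -> pd.DataFrame:
    """Tabulate novelty yield per parameter-grid point."""
    rows = []
    for key, acc in sorted(accounts.items()):
        rows.append(
            {
                "temperature": key.temperature,
                "template": key.template,
                "frequency_penalty": key.frequency_penalty,
                "presence_penalty": key.presence_penalty,
                "index_term": acc.index_term,
                "total_generated": acc.total_generated,
                "unique_generated": acc.unique_generated,
                "gpt3_synonyms": acc.gpt3_synonyms,
                "ungs": acc.ungs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "temperature", "template", "frequency_penalty", "presence_penalty",
            "index_term", "total_generated", "unique_generated", "gpt3_synonyms", "ungs",
        ],
    )


def sweep_marginal(summary: pd.DataFrame, parameter: str) -> pd.Series:
    """Total novelty yield marginalized onto one grid axis."""
    if parameter not in ("temperature", "template", "frequency_penalty", "presence_penalty"):
        raise DataError(f"unknown sweep parameter {parameter!r}")
    return summary.groupby(parameter)["ungs"].sum()
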