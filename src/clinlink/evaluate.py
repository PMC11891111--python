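"""Accuracy metrics and configuration sweeps for entity-linking output.

A gold benchmark record carries a mention text, its context label and the
set *G* of valid CUIs; the system's output for that mention is a set (or
ranked list) *R*.  The two metrics are::

    Accuracy     = |G ∩ R| / |G|
    Accuracy@N   = |G ∩ top-N(R)| / |G|

Accuracy@N is non-decreasing in N and equals Accuracy once N covers the
whole output.  Records are matched by exact (normalized text, context)
pairs; gold records the system never produced are scored 0 and listed, so
silent drops are penalized.  Means are unweighted over records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._text import normalize


class EvaluationError(ValueError):
    pass


def accuracy(gold, returned) -> float:
    """Proportion of gold CUIs the system returned: |G ∩ R| / |G|."""
    gold = set(gold)
    if not gold:
        raise EvaluationError("accuracy is undefined for an empty gold set")
    return len(gold & set(returned)) / len(gold)


def accuracy_at_n(gold, ranked, n: int) -> float:
    """Accuracy restricted to the top-N of a ranked CUI list.

    The ranked list is deduplicated preserving first occurrence before
    truncation.
    """
    if n < 1:
        raise EvaluationError("n must be >= 1")
    seen: list[str] = []
    for cui in ranked:
        if cui not in seen:
            seen.append(cui)
    return accuracy(gold, seen[:n])


@dataclass(frozen=True)
class GoldRecord:
    text: str
    context: str
    cuis: frozenset[str]

    def __post_init__(self) -> None:
        if not self.cuis:
            raise EvaluationError(f"gold record {self.text!r} has no CUIs")


def _norm_fields(obj: dict) -> dict:
    return {k.lower(): v for k, v in obj.items()}


def load_gold(path: str | Path) -> list[GoldRecord]:
    """Load gold JSON-lines; tolerates Text/Context/CUIs capitalization.

    Duplicate (normalized text, context) pairs are rejected: the benchmark
    includes each mention/context pair exactly once.
    """
    records: list[GoldRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = _norm_fields(json.loads(line))
            rec = GoldRecord(
                text=obj["text"], context=obj["context"], cuis=frozenset(obj["cuis"])
            )
            key = (normalize(rec.text), rec.context)
            if key in seen:
                raise EvaluationError(f"{path}:{lineno} duplicate gold record {key}")
            seen.add(key)
            records.append(rec)
    return records


def load_predictions(source) -> list[dict]:
    """Accept prediction rows directly, or read them from a JSON-lines path."""
    if isinstance(source, (str, Path)):
        rows = []
        with open(source, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
        return rows
    return list(source)


@dataclass
class EvalReport:
    n_gold: int
    n_matched: int
    mean_accuracy: float
    accuracy_at: dict[int, float]
    per_record: list[dict] = field(default_factory=list)
    missing: list[tuple[str, str]] = field(default_factory=list)
    status_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_gold": self.n_gold,
            "n_matched": self.n_matched,
            "mean_accuracy": self.mean_accuracy,
            "accuracy_at": {str(k): v for k, v in self.accuracy_at.items()},
            "missing": [list(m) for m in self.missing],
            "status_counts": self.status_counts,
        }


def evaluate(predictions, gold, n_values=(1, 5, 15)) -> EvalReport:
    """Score predictions against the gold benchmark.

    ``predictions`` are rows with text/surface, context/label and a ranked
    ``cuis`` list (paths to JSON-lines files are accepted for both
    arguments).  Unmatched gold records score 0 on every metric and are
    listed in the report.
    """
    if isinstance(gold, (str, Path)):
        gold = load_gold(gold)
    rows = load_predictions(predictions)
    by_key: dict[tuple[str, str], dict] = {}
    status_counts: dict[str, int] = {}
    for row in rows:
        text = row.get("text", row.get("surface"))
        context = row.get("context", row.get("label"))
        by_key.setdefault((normalize(text), context), row)
        if "status" in row:
            status_counts[row["status"]] = status_counts.get(row["status"], 0) + 1

    per_record: list[dict] = []
    missing: list[tuple[str, str]] = []
    accs: list[float] = []
    at: dict[int, list[float]] = {n: [] for n in n_values}
    n_matched = 0
    for g in gold:
        key = (normalize(g.text), g.context)
        row = by_key.get(key)
        if row is None:
            missing.append(key)
            accs.append(0.0)
            for n in n_values:
                at[n].append(0.0)
            per_record.append(
                {"text": g.text, "context": g.context, "matched": False, "accuracy": 0.0}
            )
            continue
        n_matched += 1
        ranked = list(row.get("cuis", []))
        a = accuracy(g.cuis, ranked)
        accs.append(a)
        for n in n_values:
            at[n].append(accuracy_at_n(g.cuis, ranked, n))
        per_record.append(
            {"text": g.text, "context": g.context, "matched": True, "accuracy": a,
             "cuis": ranked}
        )
    if n_matched == 0:
        raise EvaluationError("no prediction matched any gold record")
    return EvalReport(
        n_gold=len(gold),
        n_matched=n_matched,
        mean_accuracy=sum(accs) / len(accs),
        accuracy_at={n: sum(v) / len(v) for n, v in at.items()},
        per_record=per_record,
        missing=missing,
        status_counts=status_counts,
    )


def sweep(
    configs,
    notes,
    index,
    gold,
    recognizer,
    llm_factory=None,
    acronym_dict=None,
    n_values=(1, 5, 15),
) -> pd.DataFrame:
    """Evaluate the pipeline under each configuration; one row per config.

    ``llm_factory`` is called once per config so call counters start fresh.
    Per-config failures are recorded in the row and the sweep continues.
    Rows keep the config order, so the table is deterministic.
    """
    from .pipeline import run as run_pipeline

    rows = []
    for config in configs:
        desc = {
            "q_type": config.q_type.value,
            "theta_sim": config.theta_sim,
            "k": config.k,
            "prompt": config.prompt_style.value,
        }
        try:
            client = llm_factory(config) if llm_factory else None
            pred_rows, report = run_pipeline(
                notes, index, config, recognizer, client, acronym_dict=acronym_dict
            )
            ev = evaluate(pred_rows, gold, n_values=n_values)
            row = {
                **desc,
                "mean_accuracy": ev.mean_accuracy,
                **{f"accuracy_at_{n}": ev.accuracy_at[n] for n in n_values},
                "n_entities": report.n_entities,
                "llm_calls": report.llm_disambiguation_calls,
                "ambiguous": report.ambiguous_decisions,
                "error": None,
            }
        except Exception as exc:
            row = {**desc, "error": str(exc)}
        rows.append(row)
    return pd.DataFrame(rows)
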