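"""Entity-span extraction and entity-level precision/recall/F1.

Evaluation is span-exact: a predicted entity counts as a true positive only
when its type, start and end all match a gold entity.  P = TP/(TP+FP),
R = TP/(TP+FN), F1 = 2PR/(P+R), with the 0 convention when a denominator
vanishes.  Scores are reported overall (micro) and per type, as percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["EntitySpan", "extract_entities", "spans_to_tags", "evaluate", "metrics_to_json"]


@dataclass(frozen=True, order=True)
class EntitySpan:
    type_code: str
    start: int  # 0-based, inclusive
    end: int  # exclusive

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def extract_entities(tags: list[str], stray_i: str = "repair") -> list[EntitySpan]:
    """Each maximal B-X (I-X)* run becomes one span.

    A stray I-X with no live head is repaired to B-X by default
    (``stray_i="repair"``); ``stray_i="drop"`` discards such positions.
    """
    if stray_i not in ("repair", "drop"):
        raise ValueError(f"unknown stray-I policy {stray_i!r}")
    spans: list[EntitySpan] = []
    cur_type: str | None = None
    cur_start = 0
    for i, tag in enumerate(tags):
        if tag.startswith("B-"):
            if cur_type is not None:
                spans.append(EntitySpan(cur_type, cur_start, i))
            cur_type, cur_start = tag[2:], i
        elif tag.startswith("I-"):
            typ = tag[2:]
            if cur_type == typ:
                continue  # extends the current span
            if cur_type is not None:
                spans.append(EntitySpan(cur_type, cur_start, i))
                cur_type = None
            if stray_i == "repair":
                cur_type, cur_start = typ, i
        else:  # "O"
            if cur_type is not None:
                spans.append(EntitySpan(cur_type, cur_start, i))
                cur_type = None
    if cur_type is not None:
        spans.append(EntitySpan(cur_type, cur_start, len(tags)))
    return spans


def spans_to_tags(spans: list[EntitySpan], length: int) -> list[str]:
    """Inverse of :func:`extract_entities` for non-overlapping spans."""
    tags = ["O"] * length
    for sp in sorted(spans):
        if sp.end > length:
            raise ValueError("span exceeds sentence length")
        tags[sp.start] = f"B-{sp.type_code}"
        for i in range(sp.start + 1, sp.end):
            tags[i] = f"I-{sp.type_code}"
    return tags


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return {"P": 100.0 * p, "R": 100.0 * r, "F1": 100.0 * f1}


def evaluate(
    pred_sentences: list[list[str]],
    gold_sentences: list[list[str]],
    stray_i: str = "repair",
) -> dict:
    """Span-exact micro P/R/F1 overall and per entity type.

    Arguments are aligned lists of per-sentence tag sequences.
    """
    if len(pred_sentences) != len(gold_sentences):
        raise ValueError("pred and gold corpora have different sizes")
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    for k, (pred, gold) in enumerate(zip(pred_sentences, gold_sentences)):
        if len(pred) != len(gold):
            raise ValueError(f"sentence {k}: pred length {len(pred)} != gold {len(gold)}")
        pset = set(extract_entities(pred, stray_i))
        gset = set(extract_entities(gold, stray_i))
        for sp in pset & gset:
            tp[sp.type_code] = tp.get(sp.type_code, 0) + 1
        for sp in pset - gset:
            fp[sp.type_code] = fp.get(sp.type_code, 0) + 1
        for sp in gset - pset:
            fn[sp.type_code] = fn.get(sp.type_code, 0) + 1
    types = sorted(set(tp) | set(fp) | set(fn))
    per_type = {
        t: _prf(tp.get(t, 0), fp.get(t, 0), fn.get(t, 0)) for t in types
    }
    overall = _prf(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    return {"overall": overall, "per_type": per_type}


def metrics_to_json(metrics: dict, path: str | Path) -> None:
    """Write metrics with percentages rounded to 2 decimals."""

    def rnd(d):
        return {k: round(v, 2) if isinstance(v, float) else rnd(v) for k, v in d.items()}

    Path(path).write_text(json.dumps(rnd(metrics), indent=2))
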