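"""Evaluation of gene normalization output against a gold answer key.

Micro-averaged precision/recall/F-score over article-level GeneID sets, and
TAP-k (threshold average precision) over score-ranked per-article gene lists.
TAP-k truncates each ranked list at its k-th false positive and adds a
terminal precision term, so rankings that end in a tail of false positives
are penalized even when their average precision over relevant items is high.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

__all__ = ["EvalReport", "prf", "tap_k", "funnel_report", "FunnelReport"]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_score: float
    tp: int
    fp: int
    fn: int
    per_article: dict[str, tuple[int, int]]  # article -> (fp, fn)


def prf(predicted: dict[str, set[str]], gold: dict[str, set[str]]
        ) -> EvalReport:
    """Micro-averaged P/R/F over articles.

    Articles present in only one of the two maps count with an empty set on
    the other side.
    """
    tp = fp = fn = 0
    per_article: dict[str, tuple[int, int]] = {}
    for art in sorted(set(predicted) | set(gold)):
        p = predicted.get(art, set())
        g = gold.get(art, set())
        a_tp = len(p & g)
        a_fp = len(p - g)
        a_fn = len(g - p)
        tp += a_tp
        fp += a_fp
        fn += a_fn
        per_article[art] = (a_fp, a_fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall else 0.0)
    return EvalReport(precision, recall, f, tp, fp, fn, per_article)


def _tap_single(ranked: list[str], gold: set[str], k: int) -> float:
    """TAP-k of one ranked list: average precision truncated at the k-th
    false positive, plus a terminal precision term, normalized by the number
    of gold items + 1."""
    if not gold:
        return 0.0
    if not ranked:
        return 0.0
    cutoff = len(ranked)
    fp_seen = 0
    for i, gid in enumerate(ranked, 1):
        if gid not in gold:
            fp_seen += 1
            if fp_seen == k:
                cutoff = i
                break
    rel = 0
    prec_sum = 0.0
    for i, gid in enumerate(ranked[:cutoff], 1):
        if gid in gold:
            rel += 1
            prec_sum += rel / i
    terminal = rel / cutoff
    return (prec_sum + terminal) / (len(gold) + 1)


def tap_k(ranked: dict[str, list[tuple[str, float]]],
          gold: dict[str, set[str]], k: int) -> float:
    """Mean TAP-k over articles.

    ``ranked`` maps article -> [(GeneID, score), ...]; lists are (re)sorted by
    descending score with GeneID as deterministic tie-break.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arts = sorted(gold)
    if not arts:
        return 0.0
    total = 0.0
    for art in arts:
        items = sorted(ranked.get(art, []), key=lambda x: (-x[1], x[0]))
        total += _tap_single([gid for gid, _ in items], gold[art], k)
    return total / len(arts)


@dataclass
class FunnelReport:
    list_len_min: int
    list_len_median: float
    list_len_max: int
    fp_min: int
    fp_median: float
    fp_max: int
    fn_total: int
    fn_percent: float


def funnel_report(predicted: dict[str, set[str]], gold: dict[str, set[str]]
                  ) -> FunnelReport:
    """Output-list-length and false-positive statistics per article, plus the
    total false-negative percentage over the gold key."""
    arts = sorted(set(predicted) | set(gold))
    lengths = [len(predicted.get(a, set())) for a in arts]
    fps = [len(predicted.get(a, set()) - gold.get(a, set())) for a in arts]
    fn_total = sum(len(gold.get(a, set()) - predicted.get(a, set()))
                   for a in arts)
    gold_total = sum(len(g) for g in gold.values())
    return FunnelReport(
        min(lengths) if lengths else 0,
        median(lengths) if lengths else 0.0,
        max(lengths) if lengths else 0,
        min(fps) if fps else 0,
        median(fps) if fps else 0.0,
        max(fps) if fps else 0,
        fn_total,
        100.0 * fn_total / gold_total if gold_total else 0.0,
    )
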