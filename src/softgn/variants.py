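"""Soft tagging: overlapping mention variants with confidence scores.

The combined n-best solutions of a sentence yield a multiset of mention
spans.  Each distinct (text, span) pair becomes a *variant* whose frequency
is its occurrence count divided by the number of combined solutions.  A
logistic-regression scorer turns a variant's frequency, morphology, content
tokens and +/-2-token context into a confidence in (0, 1); filtering by a
threshold trades recall for precision, and a recursive max-score selector
reduces overlapping variants to a single mention when a hard tagging is
required.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline

from .corpus import Sentence
from .crf import TagSolution, ibo2_to_mentions

__all__ = [
    "Variant",
    "ScorerModel",
    "extract_variants",
    "featurize",
    "build_training_set",
    "train_scorer",
    "score_and_filter",
    "select_nonoverlapping_max",
    "variants_overlap",
]

GN_THRESHOLD_DEFAULT = 0.2
GM_SELECTION_THRESHOLD_DEFAULT = 0.5


@dataclass(frozen=True)
class Variant:
    text: str
    start: int
    end: int
    frequency: float
    score: float | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def variants_overlap(a: Variant, b: Variant) -> bool:
    return a.start < b.end and b.start < a.end


def extract_variants(solutions: list[TagSolution], sentence: Sentence
                     ) -> list[Variant]:
    """Distinct (text, span) mentions across the combined solutions, each
    carrying frequency = occurrences / number of solutions.  Overlaps are
    retained — that is the point of soft tagging."""
    counts: dict[tuple[int, int], int] = {}
    for sol in solutions:
        for m in ibo2_to_mentions(sol, sentence.tokens, sentence.text):
            counts[(m.start, m.end)] = counts.get((m.start, m.end), 0) + 1
    denom = len(solutions)
    out = [
        Variant(sentence.text[s:e], s, e, c / denom)
        for (s, e), c in counts.items()
    ]
    out.sort(key=lambda v: (v.start, v.end))
    return out


_ALNUM_RE = re.compile(r"[^0-9a-z]+")


def _content_tokens(text: str) -> list[str]:
    """Lowercase and strip punctuation before content tokenization."""
    return [t for t in _ALNUM_RE.sub(" ", text.lower()).split() if t]


def featurize(variant: Variant, sentence: Sentence) -> dict[str, float]:
    """Feature dictionary for one variant: one continuous frequency feature,
    9 morphological flags, content-token and context-token indicators."""
    f: dict[str, float] = {"frequency": variant.frequency}
    text = variant.text
    if any(c.isupper() for c in text):
        f["has_upper"] = 1.0
    if any(c.islower() for c in text):
        f["has_lower"] = 1.0
    if any(c.isdigit() for c in text):
        f["has_digit"] = 1.0
    first, last = text[0], text[-1]
    if first.isupper():
        f["starts_upper"] = 1.0
    if first.islower():
        f["starts_lower"] = 1.0
    if first.isdigit():
        f["starts_digit"] = 1.0
    if last.isupper():
        f["ends_upper"] = 1.0
    if last.islower():
        f["ends_lower"] = 1.0
    if last.isdigit():
        f["ends_digit"] = 1.0
    for tok in _content_tokens(text):
        f[f"content={tok}"] = 1.0
    # context: two tokens on each side of the variant span (fewer at edges)
    toks = sentence.tokens
    before = [t for t in toks if t.end <= variant.start]
    after = [t for t in toks if t.start >= variant.end]
    for t in before[-2:]:
        f[f"ctx={t.surface.lower()}"] = 1.0
    for t in after[:2]:
        f[f"ctx={t.surface.lower()}"] = 1.0
    return f


def build_training_set(items) -> tuple[list[dict[str, float]], list[int]]:
    """Label extracted variants against curator spans.

    ``items`` is an iterable of (sentence, solutions, acceptable_spans) where
    acceptable_spans is a set of (start, end) pairs covering the gold mention
    and its curator-acceptable alternatives.  A variant is positive iff its
    span is in the acceptable set (exact-span identity; mere overlap is
    negative).
    """
    X: list[dict[str, float]] = []
    y: list[int] = []
    for sentence, solutions, acceptable in items:
        for v in extract_variants(solutions, sentence):
            X.append(featurize(v, sentence))
            y.append(1 if (v.start, v.end) in set(acceptable) else 0)
    return X, y


class ScorerModel:
    """Logistic-regression confidence scorer over sparse variant features.

    L2-regularized; regularization strength selected by 5-fold stratified
    cross-validation (fixed fold seed).  ``cv_accuracy`` holds the mean
    held-out accuracy of the selected configuration.
    """

    _CS = (0.1, 1.0, 10.0)

    def __init__(self, pipeline: Pipeline, cv_accuracy: float):
        self.pipeline = pipeline
        self.cv_accuracy = cv_accuracy

    def score(self, features: dict[str, float]) -> float:
        return float(self.pipeline.predict_proba([features])[0, 1])

    def score_many(self, features: list[dict[str, float]]) -> np.ndarray:
        if not features:
            return np.empty(0)
        return self.pipeline.predict_proba(features)[:, 1]

    def save(self, path) -> None:
        vec: DictVectorizer = self.pipeline.named_steps["vec"]
        clf: LogisticRegression = self.pipeline.named_steps["clf"]
        payload = {
            "format": "softgn-scorer/1",
            "features": list(vec.get_feature_names_out()),
            "coef": clf.coef_[0].tolist(),
            "intercept": float(clf.intercept_[0]),
            "C": float(clf.C),
            "cv_accuracy": self.cv_accuracy,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ScorerModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "softgn-scorer/1":
            raise ValueError("unrecognized scorer file format")
        vec = DictVectorizer(sparse=True)
        vec.fit([{f: 1.0 for f in payload["features"]}])
        order = {f: i for i, f in enumerate(vec.get_feature_names_out())}
        coef = np.empty(len(order))
        for f, w in zip(payload["features"], payload["coef"]):
            coef[order[f]] = w
        clf = LogisticRegression(C=payload["C"])
        clf.classes_ = np.array([0, 1])
        clf.coef_ = coef[None, :]
        clf.intercept_ = np.array([payload["intercept"]])
        pipe = Pipeline([("vec", vec), ("clf", clf)])
        return cls(pipe, payload["cv_accuracy"])


def train_scorer(X: list[dict[str, float]], y: list[int],
                 seed: int = 0) -> ScorerModel:
    """Fit the confidence scorer; raises on single-class input."""
    classes = set(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    folds = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    best_c, best_acc = None, -1.0
    for c in ScorerModel._CS:
        pipe = Pipeline([
            ("vec", DictVectorizer(sparse=True)),
            ("clf", LogisticRegression(C=c, max_iter=1000)),
        ])
        acc = float(np.mean(cross_val_score(pipe, X, y, cv=folds,
                                            scoring="accuracy")))
        if acc > best_acc:
            best_c, best_acc = c, acc
    pipe = Pipeline([
        ("vec", DictVectorizer(sparse=True)),
        ("clf", LogisticRegression(C=best_c, max_iter=1000)),
    ])
    pipe.fit(X, y)
    return ScorerModel(pipe, best_acc)


def score_and_filter(variants: list[Variant], sentence: Sentence,
                     model: ScorerModel, threshold: float = GN_THRESHOLD_DEFAULT
                     ) -> list[Variant]:
    """Attach confidence scores and drop variants scoring below ``threshold``.

    Retained sets are nested across thresholds: raising the threshold never
    admits a variant it previously excluded.
    """
    if not variants:
        return []
    scores = model.score_many([featurize(v, sentence) for v in variants])
    return [
        replace(v, score=float(s))
        for v, s in zip(variants, scores)
        if s >= threshold
    ]


def select_nonoverlapping_max(variants: list[Variant]) -> list[Variant]:
    """Recursive hard selection: repeatedly keep the highest-scoring variant
    and discard everything overlapping it.

    Ties on score prefer the longer variant, then the leftmost.  The result
    is an independent set in the overlap graph in which every kept variant
    scores at least as high as anything it overlapped.
    """
    for v in variants:
        if v.score is None:
            raise ValueError(f"unscored variant {v.text!r}")
    remaining = sorted(
        variants, key=lambda v: (-v.score, -(v.end - v.start), v.start, v.end)
    )
    selected: list[Variant] = []
    while remaining:
        best = remaining[0]
        selected.append(best)
        remaining = [v for v in remaining[1:] if not variants_overlap(best, v)]
    selected.sort(key=lambda v: (v.start, v.end))
    return selected
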