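"""Linear-chain CRF gene-mention tagger with exact n-best Viterbi decoding.

Tokens are labeled with the IOB2 scheme over {B, I, O}.  Two models are
trained per corpus: a *forward* model on the token sequences as written and a
*backward* model on reversed sequences (with span-consistent relabeling), and
their n-best solution lists are concatenated.  The union of mentions across
the combined solutions trades precision for a near-exhaustive recall; the
confidence scorer downstream restores precision.

Decoding is exact: the i-th returned labeling is the i-th best by joint model
score, with deterministic lexicographic tie-breaking (B < I < O).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "LABELS",
    "TagSolution",
    "MentionSpan",
    "CRFModel",
    "extract_features",
    "train_crf",
    "decode_nbest",
    "combine_solutions",
    "ibo2_to_mentions",
    "is_valid_ibo2",
    "reverse_labels",
    "read_conll",
    "write_conll",
]

LABELS = ("B", "I", "O")
_LIDX = {lab: i for i, lab in enumerate(LABELS)}
B, I, O = 0, 1, 2


@dataclass(frozen=True)
class TagSolution:
    labels: tuple[str, ...]
    score: float


@dataclass(frozen=True)
class MentionSpan:
    text: str
    start: int
    end: int


def is_valid_ibo2(labels) -> bool:
    prev = "O"
    for lab in labels:
        if lab not in _LIDX:
            return False
        if lab == "I" and prev == "O":
            return False
        prev = lab
    return True


def _validate_corpus(corpus) -> None:
    if not corpus:
        raise ValueError("empty training corpus")
    for i, (tokens, labels) in enumerate(corpus):
        if len(tokens) != len(labels):
            raise ValueError(f"sentence {i}: token/label length mismatch")
        bad = [lab for lab in labels if lab not in _LIDX]
        if bad:
            raise ValueError(f"sentence {i}: unknown label {bad[0]!r}")
        if not is_valid_ibo2(labels):
            raise ValueError(f"sentence {i}: invalid IOB2 label sequence")


# ---------------------------------------------------------------------------
# Features


def _shape(word: str) -> str:
    out = []
    for ch in word:
        if ch.isupper():
            c = "X"
        elif ch.islower():
            c = "x"
        elif ch.isdigit():
            c = "9"
        else:
            c = "-"
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def extract_features(surfaces: list[str]) -> list[list[str]]:
    """Per-token feature strings: identity, lowercase, affixes (2-4),
    orthographic flags, shape, and a +/-2 lowercase-word window."""
    lowers = [w.lower() for w in surfaces]
    feats: list[list[str]] = []
    n = len(surfaces)
    for t, w in enumerate(surfaces):
        f = ["bias", f"w={w}", f"wl={lowers[t]}", f"shape={_shape(w)}"]
        for ln in (2, 3, 4):
            if len(w) > ln:
                f.append(f"pre{ln}={w[:ln]}")
                f.append(f"suf{ln}={w[-ln:]}")
        if w[0].isupper():
            f.append("init_upper")
        if w.isupper():
            f.append("all_upper")
        if w.islower():
            f.append("all_lower")
        if any(c.isdigit() for c in w):
            f.append("has_digit")
        if w.isdigit():
            f.append("all_digit")
        if not any(c.isalnum() for c in w):
            f.append("punct")
        for off in (-2, -1, 1, 2):
            j = t + off
            f.append(f"wl[{off}]={lowers[j]}" if 0 <= j < n else f"edge[{off}]")
        feats.append(f)
    return feats


# ---------------------------------------------------------------------------
# Model


@dataclass
class CRFModel:
    """Weights for a linear-chain CRF over LABELS.

    ``direction == "backward"`` means the model was trained on reversed token
    sequences; :func:`decode_nbest` transparently reverses input and
    re-reverses the output labelings to sentence order.
    """

    direction: str = "forward"
    feature_index: dict[str, int] = field(default_factory=dict)
    emission: np.ndarray | None = None   # (n_features, 3)
    transition: np.ndarray | None = None  # (3, 3)
    start: np.ndarray | None = None      # (3,)
    end: np.ndarray | None = None        # (3,)

    def _emit_matrix(self, surfaces: list[str]) -> np.ndarray:
        feats = extract_features(surfaces)
        emit = np.zeros((len(surfaces), 3))
        for t, fs in enumerate(feats):
            for f in fs:
                j = self.feature_index.get(f)
                if j is not None:
                    emit[t] += self.emission[j]
        return emit

    def sequence_score(self, surfaces: list[str], labels) -> float:
        """Joint (unnormalized, log-domain) score of one labeling in the
        model's own parsing order."""
        emit = self._emit_matrix(surfaces)
        idx = [_LIDX[lab] for lab in labels]
        s = self.start[idx[0]] + self.end[idx[-1]]
        for t, li in enumerate(idx):
            s += emit[t, li]
            if t:
                s += self.transition[idx[t - 1], li]
        return float(s)

    # -- serialization: versioned flat text format
    def save(self, path) -> None:
        payload = {
            "format": "softgn-crf/1",
            "direction": self.direction,
            "labels": list(LABELS),
            "features": list(self.feature_index.keys()),
            "emission": self.emission.tolist(),
            "transition": self.transition.tolist(),
            "start": self.start.tolist(),
            "end": self.end.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "CRFModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "softgn-crf/1":
            raise ValueError("unrecognized CRF model file format")
        return cls(
            direction=payload["direction"],
            feature_index={f: i for i, f in enumerate(payload["features"])},
            emission=np.array(payload["emission"]),
            transition=np.array(payload["transition"]),
            start=np.array(payload["start"]),
            end=np.array(payload["end"]),
        )


def reverse_labels(labels, n: int | None = None) -> tuple[str, ...]:
    """Map an IOB2 labeling to the reversed token order, re-encoding spans so
    the result is again valid IOB2."""
    labs = list(labels)
    n = len(labs) if n is None else n
    spans = _label_runs(labs)
    out = ["O"] * n
    for s, e in spans:
        rs, re_ = n - e, n - s
        out[rs] = "B"
        for t in range(rs + 1, re_):
            out[t] = "I"
    return tuple(out)


def _label_runs(labels) -> list[tuple[int, int]]:
    runs = []
    start = None
    for t, lab in enumerate(labels):
        if lab == "B":
            if start is not None:
                runs.append((start, t))
            start = t
        elif lab == "I":
            if start is None:
                raise ValueError("invalid IOB2: I without preceding B")
        else:
            if start is not None:
                runs.append((start, t))
                start = None
    if start is not None:
        runs.append((start, len(labels)))
    return runs


# ---------------------------------------------------------------------------
# Training: L2-regularized maximum likelihood via L-BFGS


def train_crf(corpus, direction: str = "forward", l2: float = 1.0,
              max_iter: int = 200) -> CRFModel:
    """Fit a CRF on ``corpus`` = list of (token surfaces, IOB2 labels).

    Backward models are fit on reversed sequences with span-consistent
    relabeling.  Deterministic (zero initialization, L-BFGS).
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    _validate_corpus(corpus)

    prepared = []
    for tokens, labels in corpus:
        surfaces = [t if isinstance(t, str) else t.surface for t in tokens]
        labels = tuple(labels)
        if direction == "backward":
            surfaces = surfaces[::-1]
            labels = reverse_labels(labels)
        prepared.append((surfaces, labels))

    feature_index: dict[str, int] = {}
    sent_feats = []
    for surfaces, labels in prepared:
        rows = []
        for fs in extract_features(surfaces):
            row = []
            for f in fs:
                j = feature_index.setdefault(f, len(feature_index))
                row.append(j)
            rows.append(np.array(row, dtype=np.int64))
        sent_feats.append((rows, np.array([_LIDX[lab] for lab in labels])))

    nf = len(feature_index)
    n_params = nf * 3 + 9 + 3 + 3

    def unpack(theta):
        em = theta[: nf * 3].reshape(nf, 3)
        tr = theta[nf * 3: nf * 3 + 9].reshape(3, 3)
        st = theta[nf * 3 + 9: nf * 3 + 12]
        en = theta[nf * 3 + 12:]
        return em, tr, st, en

    def objective(theta):
        em, tr, st, en = unpack(theta)
        g_em = np.zeros_like(em)
        g_tr = np.zeros_like(tr)
        g_st = np.zeros_like(st)
        g_en = np.zeros_like(en)
        nll = 0.0
        for rows, y in sent_feats:
            n = len(rows)
            emit = np.empty((n, 3))
            for t, r in enumerate(rows):
                emit[t] = em[r].sum(axis=0)
            # forward
            alpha = np.empty((n, 3))
            alpha[0] = st + emit[0]
            for t in range(1, n):
                alpha[t] = emit[t] + logsumexp(alpha[t - 1][:, None] + tr, axis=0)
            logz = logsumexp(alpha[-1] + en)
            # backward
            beta = np.empty((n, 3))
            beta[-1] = en
            for t in range(n - 2, -1, -1):
                beta[t] = logsumexp(tr + (emit[t + 1] + beta[t + 1])[None, :], axis=1)
            # gold score
            gold = st[y[0]] + en[y[-1]] + emit[np.arange(n), y].sum()
            if n > 1:
                gold += tr[y[:-1], y[1:]].sum()
            nll += logz - gold
            # marginals
            node_m = np.exp(alpha + beta - logz)
            for t, r in enumerate(rows):
                g_em[r] += node_m[t]
                g_em[r, y[t]] -= 1.0
            g_st += node_m[0]
            g_st[y[0]] -= 1.0
            g_en += node_m[-1]
            g_en[y[-1]] -= 1.0
            for t in range(1, n):
                pair = np.exp(
                    alpha[t - 1][:, None] + tr + (emit[t] + beta[t])[None, :] - logz
                )
                g_tr += pair
                g_tr[y[t - 1], y[t]] -= 1.0
        nll += 0.5 * l2 * float(theta @ theta)
        grad = np.concatenate(
            [g_em.ravel(), g_tr.ravel(), g_st, g_en]
        ) + l2 * theta
        return nll, grad

    res = minimize(
        objective,
        np.zeros(n_params),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-9},
    )
    em, tr, st, en = unpack(res.x)
    return CRFModel(
        direction=direction,
        feature_index=feature_index,
        emission=em,
        transition=tr,
        start=st,
        end=en,
    )


# ---------------------------------------------------------------------------
# Exact n-best decoding


def decode_nbest(model: CRFModel, tokens, k: int = 20,
                 valid_only: bool = False) -> list[TagSolution]:
    """Return the top-``k`` labelings by joint score, exactly.

    Per-state k-best list Viterbi; ties are broken lexicographically on the
    label string with B < I < O, making the ordering a total order and the
    enumeration oracle-checkable.  With ``valid_only`` the search space is
    restricted to valid IOB2 sequences (no I at the start, no I after O).
    Backward models receive the tokens in sentence order and return labelings
    re-reversed to sentence order.
    """
    surfaces = [t if isinstance(t, str) else t.surface for t in tokens]
    if not surfaces:
        raise ValueError("cannot decode an empty token list")
    if k < 1:
        raise ValueError("k must be >= 1")
    if model.direction == "backward":
        surfaces = surfaces[::-1]

    emit = model._emit_matrix(surfaces)
    n = len(surfaces)
    # hypothesis: (score, label_index_tuple); beams[lab] sorted best-first
    beams: list[list[tuple[float, tuple[int, ...]]]] = [[] for _ in range(3)]
    for lab in range(3):
        if valid_only and lab == I:
            continue
        beams[lab] = [(float(model.start[lab] + emit[0, lab]), (lab,))]
    for t in range(1, n):
        new_beams: list[list[tuple[float, tuple[int, ...]]]] = []
        for lab in range(3):
            cands: list[tuple[float, tuple[int, ...]]] = []
            for prev in range(3):
                if valid_only and lab == I and prev == O:
                    continue
                step = float(model.transition[prev, lab] + emit[t, lab])
                for score, labs in beams[prev]:
                    cands.append((score + step, labs + (lab,)))
            cands.sort(key=lambda h: (-h[0], h[1]))
            new_beams.append(cands[:k])
        beams = new_beams
    finals: list[tuple[float, tuple[int, ...]]] = []
    for lab in range(3):
        e = float(model.end[lab])
        finals.extend((score + e, labs) for score, labs in beams[lab])
    finals.sort(key=lambda h: (-h[0], h[1]))
    finals = finals[:k]

    out = []
    for score, labs in finals:
        labels = tuple(LABELS[i] for i in labs)
        if model.direction == "backward":
            labels = reverse_labels(labels)
        out.append(TagSolution(labels, score))
    return out


def combine_solutions(fwd: list[TagSolution], bwd: list[TagSolution]
                      ) -> list[TagSolution]:
    """Concatenate forward- and backward-model solution lists (the combined
    multiset; duplicates retained — frequency counting relies on them)."""
    lengths = {len(s.labels) for s in fwd} | {len(s.labels) for s in bwd}
    if len(lengths) > 1:
        raise ValueError("solution lists decode different token counts")
    return list(fwd) + list(bwd)


def ibo2_to_mentions(solution: TagSolution, tokens,
                     sentence_text: str | None = None) -> list[MentionSpan]:
    """Decode each maximal B(I)* run into a mention span over the sentence.

    With ``sentence_text`` the mention text is the exact sentence slice;
    otherwise it is reconstructed from token offsets (whitespace gaps become
    single spaces per gap column, which is exact for space-separated text).
    """
    if len(solution.labels) != len(tokens):
        raise ValueError("labeling length does not match token count")
    runs = _label_runs(solution.labels)  # raises on invalid IOB2
    out = []
    for s, e in runs:
        start = tokens[s].start
        end = tokens[e - 1].end
        if sentence_text is not None:
            text = sentence_text[start:end]
        else:
            buf = [" "] * (end - start)
            for tok in tokens[s:e]:
                buf[tok.start - start: tok.end - start] = tok.surface
            text = "".join(buf)
        out.append(MentionSpan(text, start, end))
    return out


# ---------------------------------------------------------------------------
# CoNLL-style corpus I/O (token TAB label, blank line between sentences)


def read_conll(path) -> list[tuple[list[str], list[str]]]:
    corpus = []
    tokens: list[str] = []
    labels: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if tokens:
                    corpus.append((tokens, labels))
                    tokens, labels = [], []
                continue
            tok, lab = line.split("\t")
            tokens.append(tok)
            labels.append(lab)
    if tokens:
        corpus.append((tokens, labels))
    return corpus


def write_conll(corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, labels in corpus:
            for tok, lab in zip(tokens, labels):
                surface = tok if isinstance(tok, str) else tok.surface
                fh.write(f"{surface}\t{lab}\n")
            fh.write("\n")
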