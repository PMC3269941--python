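"""End-to-end gene normalization: parse -> soft-tag -> score/filter ->
abbreviation filter -> species designation -> dictionary resolution.

The run is deterministic given fixed models, dictionaries and seed.  Stage
counts (variants extracted / after threshold / after abbreviation filter /
resolved) are logged per article so the precision-recall funnel is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import abbrev, species
from .corpus import Document, filter_sections, parse_article
from .crf import CRFModel, combine_solutions, decode_nbest, train_crf
from .genedict import GeneIndex, compile_query, disambiguate_overlapping, \
    regex_filter, resolve
from .variants import (
    GN_THRESHOLD_DEFAULT,
    ScorerModel,
    Variant,
    build_training_set,
    extract_variants,
    score_and_filter,
    train_scorer,
    variants_overlap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "GNResult",
    "TaggingModels",
    "train_models",
    "run_pipeline",
    "run_document",
    "write_results",
    "merge_runs",
]


@dataclass
class PipelineConfig:
    k: int = 20                      # n-best size per parsing direction
    gn_threshold: float = GN_THRESHOLD_DEFAULT
    retrieval_cap: int = 50
    species_rules: frozenset[int] = frozenset({1, 2, 3})
    use_abbrev_filter: bool = True
    default_taxid: str | None = None
    taxid_redirects: dict[str, str] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class GNResult:
    article_id: str
    geneid: str
    score: float
    taxid: str
    variant_text: str
    start: int
    end: int
    species_rule: int


@dataclass
class TaggingModels:
    forward: CRFModel
    backward: CRFModel
    scorer: ScorerModel


def train_models(corpus, k: int = 20, seed: int = 0,
                 l2: float = 1.0, max_iter: int = 150) -> TaggingModels:
    """Train the forward/backward CRFs and the variant confidence scorer on a
    tagged corpus (TaggedSentence-like objects with .tokens, .labels,
    .acceptable, .text)."""
    pairs = [([t.surface for t in s.tokens], list(s.labels)) for s in corpus]
    fwd = train_crf(pairs, "forward", l2=l2, max_iter=max_iter)
    bwd = train_crf(pairs, "backward", l2=l2, max_iter=max_iter)
    items = []
    for s in corpus:
        sols = combine_solutions(
            decode_nbest(fwd, s.tokens, k, valid_only=True),
            decode_nbest(bwd, s.tokens, k, valid_only=True),
        )
        from .corpus import Sentence
        sent = Sentence(s.text, 0, len(s.text), tokens=list(s.tokens))
        items.append((sent, sols, s.acceptable))
    X, y = build_training_set(items)
    scorer = train_scorer(X, y, seed=seed)
    return TaggingModels(fwd, bwd, scorer)


def _soft_tag_document(doc: Document, models: TaggingModels,
                       config: PipelineConfig):
    """Scored, threshold-filtered variants per (section, sentence)."""
    out: list[tuple[int, int, Variant]] = []
    n_raw = 0
    for si, ti, sentence in doc.iter_sentences():
        if not sentence.tokens:
            continue
        sols = combine_solutions(
            decode_nbest(models.forward, sentence.tokens, config.k,
                         valid_only=True),
            decode_nbest(models.backward, sentence.tokens, config.k,
                         valid_only=True),
        )
        variants = extract_variants(sols, sentence)
        n_raw += len(variants)
        kept = score_and_filter(variants, sentence, models.scorer,
                                config.gn_threshold)
        out.extend((si, ti, v) for v in kept)
    return out, n_raw


def _overlap_groups(variants: list[Variant]) -> list[list[Variant]]:
    """Connected components of the overlap graph within one sentence."""
    groups: list[list[Variant]] = []
    for v in sorted(variants, key=lambda v: (v.start, v.end)):
        if groups and any(variants_overlap(v, u) for u in groups[-1]):
            groups[-1].append(v)
        else:
            groups.append([v])
    return groups


def run_document(doc: Document, models: TaggingModels, index: GeneIndex,
                 sdict: species.SpeciesDict, config: PipelineConfig
                 ) -> list[GNResult]:
    """Normalize one parsed article (sections already filtered)."""
    tagged, n_raw = _soft_tag_document(doc, models, config)

    if config.use_abbrev_filter:
        pairs = abbrev.detect_pairs(doc)
        tagged = abbrev.filter_by_abbrev(tagged, pairs)
    n_after_abbrev = len(tagged)

    mentions = species.find_species_mentions(doc, sdict)

    # species designation + per-variant resolution, grouped by overlap
    results: dict[str, GNResult] = {}
    n_resolved = 0
    by_sentence: dict[tuple[int, int], list[Variant]] = {}
    for si, ti, v in tagged:
        by_sentence.setdefault((si, ti), []).append(v)
    for loc, vs in sorted(by_sentence.items()):
        for group in _overlap_groups(vs):
            pairs_resolved: list[tuple[Variant, str | None]] = []
            assignments: dict[tuple[int, int], species.TaxAssignment] = {}
            for v in group:
                assignment = species.designate(
                    v, loc, mentions, sdict, rules=config.species_rules,
                    default_taxid=config.default_taxid,
                )
                if assignment is None:
                    logger.warning(
                        "article %s: no species for variant %r; dropped",
                        doc.article_id, v.text,
                    )
                    continue
                taxid = config.taxid_redirects.get(assignment.taxid,
                                                   assignment.taxid)
                query = compile_query(v.text, taxid)
                cands = index.retrieve(query, cap=config.retrieval_cap)
                geneid = resolve(regex_filter(cands, v.text))
                pairs_resolved.append((v, geneid))
                assignments[v.span] = assignment
            choice = disambiguate_overlapping(pairs_resolved)
            if choice is None:
                continue
            geneid, score = choice
            n_resolved += 1
            winner = max(
                (v for v, gid in pairs_resolved if gid == geneid),
                key=lambda v: len(v.text),
            )
            assignment = assignments[winner.span]
            prev = results.get(geneid)
            if prev is None or score > prev.score:
                results[geneid] = GNResult(
                    doc.article_id, geneid, score,
                    config.taxid_redirects.get(assignment.taxid,
                                               assignment.taxid),
                    winner.text, winner.start, winner.end, assignment.rule,
                )
    logger.info(
        "article %s: %d raw variants, %d after threshold+abbrev, "
        "%d groups resolved, %d gene ids",
        doc.article_id, n_raw, n_after_abbrev, n_resolved, len(results),
    )
    out = sorted(results.values(),
                 key=lambda r: (-r.score, r.geneid))
    return out


def run_pipeline(article_paths, models: TaggingModels, index: GeneIndex,
                 sdict: species.SpeciesDict,
                 config: PipelineConfig | None = None) -> list[GNResult]:
    """Run the full pipeline over article files (XML or plain text).

    Per-article failures are logged and skipped; the run continues.
    """
    import os

    config = config or PipelineConfig()
    results: list[GNResult] = []
    for path in article_paths:
        art_id = os.path.splitext(os.path.basename(str(path)))[0]
        try:
            with open(path, encoding="utf-8") as fh:
                doc = parse_article(fh.read(), article_id=art_id)
            doc = filter_sections(doc)
            results.extend(run_document(doc, models, index, sdict, config))
        except Exception:
            logger.exception("article %s failed; skipping", art_id)
    return results


_HEADER = ("article_id", "gene_id", "score", "taxid", "variant",
           "start", "end", "species_rule")


def write_results(results: list[GNResult], path) -> None:
    """Stable TSV dump: header plus one row per (article, GeneID)."""
    rows = sorted(results, key=lambda r: (r.article_id, -r.score, r.geneid))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for r in rows:
            fh.write(
                f"{r.article_id}\t{r.geneid}\t{r.score:.6f}\t{r.taxid}\t"
                f"{r.variant_text}\t{r.start}\t{r.end}\t{r.species_rule}\n"
            )


def merge_runs(*runs: list[GNResult]) -> list[GNResult]:
    """Union of runs; when the same (article, GeneID) appears in several runs
    the maximum-score row is kept."""
    best: dict[tuple[str, str], GNResult] = {}
    for run in runs:
        for r in run:
            key = (r.article_id, r.geneid)
            if key not in best or r.score > best[key].score:
                best[key] = r
    return sorted(best.values(),
                  key=lambda r: (r.article_id, -r.score, r.geneid))
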