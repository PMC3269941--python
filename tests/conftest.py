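"""Shared fixtures: a small synthetic world with trained models.

Model training is the expensive step, so it happens once per session; every
test that needs a trained tagger/scorer shares the same deterministic world
(seed 5, 120 sentences).
"""

from __future__ import annotations

import pytest

from softgn.fixtures import (
    SyntheticCorpusSpec,
    make_articles,
    make_gene_dict,
    make_species_dict,
    make_tagged_corpus,
)
from softgn.genedict import GeneIndex, load_gene_info
from softgn.pipeline import train_models
from softgn.species import load_species_dict

WORLD_SPEC = SyntheticCorpusSpec(n_sentences=120, seed=5)


@pytest.fixture(scope="session")
def world_spec() -> SyntheticCorpusSpec:
    return WORLD_SPEC


@pytest.fixture(scope="session")
def tagged_corpus(world_spec):
    return make_tagged_corpus(world_spec)


@pytest.fixture(scope="session")
def models(tagged_corpus):
    return train_models(tagged_corpus, k=20, seed=0, max_iter=120)


@pytest.fixture(scope="session")
def gene_index(world_spec, tmp_path_factory) -> GeneIndex:
    path = tmp_path_factory.mktemp("dict") / "gene_info.tsv"
    path.write_text(make_gene_dict(world_spec), encoding="utf-8")
    return GeneIndex(load_gene_info(path))


@pytest.fixture(scope="session")
def species_dict(world_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("dict") / "species.tsv"
    path.write_text(make_species_dict(world_spec), encoding="utf-8")
    return load_species_dict(path)


@pytest.fixture(scope="session")
def articles(world_spec):
    return make_articles(world_spec, n_articles=8)
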