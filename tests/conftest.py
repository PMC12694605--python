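"""Shared fixtures: hand-built toy graphs, generated fixture directories, and
session-scoped trained models for the end-to-end study checks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from adjurank.baselines import random_ranker, text_similarity_ranker
from adjurank.evaluate import per_disease_metrics
from adjurank.kg import Edge, HeteroGraph, Node
from adjurank.model import ModelConfig, load_dataset
from adjurank.synthetic import make_fixture
from adjurank.train import fit


@pytest.fixture
def toy_graph() -> HeteroGraph:
    """1 disease, 1 vaccine, 1 adjuvant, 1 platform; 3 edges."""
    nodes = [
        Node("brucellosis", "Disease", "disease caused by intracellular bacterium"),
        Node("vx1", "Vaccine", "live attenuated vaccine"),
        Node("VO:0000001", "Adjuvant", "cpg odn TLR9 agonist"),
        Node("plat1", "Platform", "subunit platform"),
    ]
    edges = [
        Edge("vx1", "vaccine-targets-disease", "brucellosis"),
        Edge("vx1", "vaccine-uses-adjuvant", "VO:0000001"),
        Edge("vx1", "vaccine-on-platform", "plat1"),
    ]
    return HeteroGraph(nodes, edges)


@pytest.fixture(scope="session")
def tiny_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "tiny"
    make_fixture("tiny", out, seed=7)
    return out


@pytest.fixture(scope="session")
def default_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "default"
    make_fixture("default", out, seed=0)
    return out


@pytest.fixture(scope="session")
def null_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "null"
    make_fixture("null", out, seed=0)
    return out


@pytest.fixture(scope="session")
def default_setup(default_dir):
    cfg = ModelConfig()
    pipeline, queries, splits = load_dataset(default_dir, cfg)
    return cfg, pipeline, queries, splits


@pytest.fixture(scope="session")
def trained_full(default_setup):
    """Full model (graded gains, hybrid loss, gamma grid) on the default fixture."""
    cfg, pipeline, queries, splits = default_setup
    return fit(pipeline, queries, splits["transductive"], cfg, seed=1)


@pytest.fixture(scope="session")
def trained_ablations(default_setup, trained_full):
    """ListNet-only ablations (graded and binary gains) at the full model's gamma."""
    cfg, pipeline, queries, splits = default_setup
    gamma = trained_full.params.gamma
    graded_base = fit(pipeline, queries, splits["transductive"],
                      dataclasses.replace(cfg, mix_w=0.0), seed=1, gamma=gamma)
    binary_base = fit(pipeline, queries, splits["transductive"],
                      dataclasses.replace(cfg, mix_w=0.0, binary_gains=True),
                      seed=1, gamma=gamma)
    return graded_base, binary_base


def eval_inductive(pipeline, queries, splits, rank_fn):
    diseases = sorted(d for d in splits["inductive"] if d in queries.gains)
    return per_disease_metrics(rank_fn, queries, diseases)


@pytest.fixture(scope="session")
def inductive_tables(default_setup, trained_full):
    """Per-disease metric tables on the inductive split: model + both baselines."""
    cfg, pipeline, queries, splits = default_setup
    model_fn = lambda d: [a for a, _ in pipeline.rank(d, trained_full.params)]  # noqa: E731
    root = np.random.SeedSequence(2)
    seeds = {d: s for d, s in zip(sorted(queries.gains), root.spawn(len(queries.gains)))}
    rand_fn = lambda d: random_ranker(queries.candidates, seeds[d])  # noqa: E731
    text_fn = lambda d: text_similarity_ranker(d, queries.candidates, pipeline.features)  # noqa: E731
    return {
        "model": eval_inductive(pipeline, queries, splits, model_fn),
        "random": eval_inductive(pipeline, queries, splits, rand_fn),
        "text": eval_inductive(pipeline, queries, splits, text_fn),
    }
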