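"""Shared fixtures: synthetic systems and one trained model per session."""

from __future__ import annotations

import numpy as np
import pytest

from hrnetx.hegt import EncoderConfig, metapath_forward
from hrnetx.io_graph import HRNet, TypedEdgeSet
from hrnetx.pipeline import DEFAULT_CONFIG, prepare_labels
from hrnetx.synthetic import SyntheticSpec, generate
from hrnetx.training import LossConfig, RetentionConfig, build_hrnet, \
    train


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic regulatory system (seed 7, noise sd 0.3)."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate(SyntheticSpec(seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def labels_and_heldout(dataset):
    return prepare_labels(dataset.graph, dataset.features,
                          DEFAULT_CONFIG["labels"], seed=7)


@pytest.fixture(scope="session")
def trained(dataset, labels_and_heldout):
    """One full training run on the default fixture, shared by all tests."""
    labels, heldout = labels_and_heldout
    result = train(dataset.graph, dataset.features, labels,
                   LossConfig(seed=7), EncoderConfig())
    emb, attention = metapath_forward(dataset.graph, dataset.features,
                                      result.params)
    hrnet = build_hrnet(dataset.graph, dataset.features, result,
                        RetentionConfig())
    return {"result": result, "emb": emb, "attention": attention,
            "hrnet": hrnet, "labels": labels, "heldout": heldout}


def truth_hrnet(data) -> HRNet:
    """An HRNet built directly from the planted truth (weights in [0,1])."""
    def clipped(eset):
        return eset.reweighted(np.clip(np.abs(eset.weights) / 2.0, 0, 1))

    return HRNet({
        "TF-CRE": clipped(data.truth["TF-CRE"]),
        "CRE-CRE": TypedEdgeSet("CRE-CRE",
                                list(data.truth["CRE-CRE"].pairs),
                                np.clip(data.truth["CRE-CRE"].weights,
                                        0, 1)),
        "CRE-TG": clipped(data.truth["CRE-TG"]),
        "TF-TF": TypedEdgeSet("TF-TF", []),
    }, nodes=data.graph.nodes)
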