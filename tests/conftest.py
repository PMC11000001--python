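"""Shared fixtures: the synthetic recovery study, trained once per session.

The flagship fixture is a ~40-node signaling network with 10 drugs, 12
TFs, one planted (withheld) off-target interaction, and a 10-model
ensemble trained at lambda_DT = 5e-3.  Training runs at 1000 epochs —
enough for the toy problem to converge — so the whole suite stays fast;
heavier variants only differ by seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from drugsignet.attribution import error_curve_cutoff
from drugsignet.synthetic import (generate_ground_truth, generate_toy_network,
                                  simulate_dataset)
from drugsignet.training import TrainConfig, train_ensemble

FIXTURE_SEED = 1
ENSEMBLE_SEED = 11
FLAGSHIP_EPOCHS = 1000
FLAGSHIP_SIZE = 10
LAMBDA_DT = 5e-3


@pytest.fixture(scope="session")
def toy_net():
    return generate_toy_network(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def ground_truth(toy_net):
    return generate_ground_truth(toy_net, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def dataset(ground_truth):
    return simulate_dataset(ground_truth, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def second_dataset(ground_truth):
    """Same ground truth, fresh noise draw — a second 'cell line'."""
    return simulate_dataset(ground_truth, seed=77)


@pytest.fixture(scope="session")
def pair_sets(ground_truth, toy_net):
    truth = set(zip(ground_truth.truth.drug, ground_truth.truth.target))
    prior = set(zip(ground_truth.prior.drug, ground_truth.prior.target))
    drugs = list(ground_truth.fingerprints.drug_ids)
    universe = {(g, t) for g in drugs for t in toy_net.target_nodes}
    planted = {(g, t) for g, t, _ in ground_truth.planted_offtargets}
    return {"truth": truth, "prior": prior, "universe": universe, "planted": planted}


@pytest.fixture(scope="session")
def flagship_ensemble(dataset, toy_net, ground_truth):
    cond, tf = dataset
    cfg = TrainConfig(epochs=FLAGSHIP_EPOCHS, ensemble_size=FLAGSHIP_SIZE,
                      lambda_dt=LAMBDA_DT)
    return train_ensemble(cond, tf, toy_net, ground_truth.prior,
                          ground_truth.sim, config=cfg, seed=ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def flagship_inference(flagship_ensemble, dataset):
    cond, tf = dataset
    return [error_curve_cutoff(m.model, cond, tf)
            for m in flagship_ensemble.members]


@pytest.fixture(scope="session")
def sweep_ensembles(dataset, toy_net, ground_truth, flagship_ensemble):
    """Ensembles (3 members) per lambda_DT level; 5e-3 reuses flagship members."""
    cond, tf = dataset
    out = {LAMBDA_DT: flagship_ensemble}
    for lam in (0.0, float("inf")):
        cfg = TrainConfig(epochs=FLAGSHIP_EPOCHS, ensemble_size=3, lambda_dt=lam)
        out[lam] = train_ensemble(cond, tf, toy_net, ground_truth.prior,
                                  ground_truth.sim, config=cfg, seed=ENSEMBLE_SEED)
    return out
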