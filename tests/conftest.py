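"""Shared fixtures: fixture corpora, priors, and the desk-scale RL study.

Priors are trained at desk scale (small LSTM, 500-molecule combinatorial
corpus) so the whole suite runs on one CPU, and the oracle-budgeted RL runs
that several tests interrogate are executed once per session. Everything is
seeded.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from augmem import chemio
from augmem.bench import fixture_similarity_task
from augmem.learn import RLConfig, TrainingState, run_epoch
from augmem.memory import DiversityFilter
from augmem.objective import ObjectiveFunction, tanimoto_similarity_component
from augmem.seqmodel import train_prior

#: Conditions of the desk-scale rediscovery study: oracle budget, the
#: similarity cap of the fixture task, and the epoch cap that terminates
#: converged runs which stop paying for new molecules.
BUDGET = 3000
SIMILARITY_THRESHOLD = 0.6
MAX_EPOCHS = 188
CROSSING_REWARD = 0.8


def run_study_arm(
    prior,
    target,
    algorithm="augmented_memory",
    seed=0,
    diversity_filter=False,
    selective_purge=False,
    stop_at_crossing=False,
    snapshot_every=0,
):
    """One oracle-budgeted fine-tuning run of the fixture similarity task."""
    objective = ObjectiveFunction(
        [tanimoto_similarity_component(target, threshold=SIMILARITY_THRESHOLD)]
    )
    cfg = RLConfig(algorithm=algorithm, seed=seed, max_length=64)
    df = DiversityFilter(bucket_size=25) if diversity_filter else None
    state = TrainingState.create(prior, cfg, df=df, selective_purge=selective_purge)
    means: list[float] = []
    snapshots = [state.agent.copy()] if snapshot_every else []
    crossing = None
    while state.epoch < MAX_EPOCHS and state.ledger.call_count + cfg.batch_size <= BUDGET:
        state = run_epoch(state, objective)
        means.append(state.last_stats.mean_reward)
        if snapshot_every and state.epoch % snapshot_every == 0:
            snapshots.append(state.agent.copy())
        if crossing is None and means[-1] >= CROSSING_REWARD:
            crossing = state.ledger.call_count
            if stop_at_crossing:
                break
    scaffolds = {chemio.scaffold(smi) for _, smi, _ in state.ledger.history}
    return SimpleNamespace(
        state=state,
        means=means,
        crossing=crossing,
        scaffolds=scaffolds,
        snapshots=snapshots,
    )


@pytest.fixture(scope="session")
def fixture_task():
    """(corpus, held-out target) of the mini-rediscovery task."""
    return fixture_similarity_task()


@pytest.fixture(scope="session")
def tiny_prior(fixture_task):
    """A small, quickly trained prior for unit tests (not for RL quality)."""
    corpus, _ = fixture_task
    return train_prior(
        corpus[:120],
        epochs=20,
        lr=5e-3,
        rng=np.random.default_rng(7),
        embedding_dim=32,
        hidden_size=64,
        num_layers=1,
    )


@pytest.fixture(scope="session")
def augmented_prior(fixture_task):
    """Fixture prior trained on randomized SMILES (representation-invariant).

    This is the prior the augmentation-based RL experiments use: it assigns
    comparable likelihood to every writing of a molecule.
    """
    corpus, _ = fixture_task
    return train_prior(
        corpus,
        epochs=250,
        lr=5e-3,
        final_lr=5e-4,
        rng=np.random.default_rng(42),
        embedding_dim=64,
        hidden_size=256,
        num_layers=1,
        augment=True,
    )


@pytest.fixture(scope="session")
def exploitation_run(augmented_prior, fixture_task):
    """Augmented Memory, seed 0, no diversity filter, run to the budget cap.

    Serves both as the pure-exploitation arm of the diversity study and as
    the seed-0 entry of the sample-efficiency comparison.
    """
    _, target = fixture_task
    return run_study_arm(augmented_prior, target, seed=0, snapshot_every=25)


@pytest.fixture(scope="session")
def crossing_table(augmented_prior, fixture_task, exploitation_run):
    """First-crossing oracle-call counts (mean batch reward 0.8) per arm.

    Three matched seeds per algorithm; a run that never crosses within the
    budget is recorded at the full budget.
    """
    _, target = fixture_task
    table = {("augmented_memory", 0): exploitation_run.crossing}
    for seed in (1, 2):
        table[("augmented_memory", seed)] = run_study_arm(
            augmented_prior, target, seed=seed, stop_at_crossing=True
        ).crossing
    for algorithm in ("ahc", "reinvent"):
        for seed in (0, 1, 2):
            table[(algorithm, seed)] = run_study_arm(
                augmented_prior, target, algorithm=algorithm, seed=seed, stop_at_crossing=True
            ).crossing
    return {k: (v if v is not None else BUDGET) for k, v in table.items()}


@pytest.fixture(scope="session")
def purge_run(augmented_prior, fixture_task):
    """Augmented Memory with diversity filter and Selective Memory Purge."""
    _, target = fixture_task
    return run_study_arm(
        augmented_prior, target, seed=0, diversity_filter=True, selective_purge=True
    )


@pytest.fixture(scope="session")
def df_only_run(augmented_prior, fixture_task):
    """Augmented Memory with the diversity filter but no purge."""
    _, target = fixture_task
    return run_study_arm(augmented_prior, target, seed=0, diversity_filter=True)
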