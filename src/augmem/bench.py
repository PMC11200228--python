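"""Run configuration, fixture chemical space, and the end-to-end experiment driver.

The fixture corpus generator enumerates a small combinatorial chemical space
(ring-system templates decorated with substituent fragments) so that the full
stack — prior training, RL fine-tuning, metrics — can be exercised with cheap
oracles and no external data. The canned "mini-rediscovery" task asks the
policy to maximize Tanimoto similarity to one held-out member of that space:
a dense-reward exploitation task in miniature.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator
from rdkit import Chem

from . import chemio, evalx
from .learn import ALGORITHMS, RLConfig, TrainingState, run_epoch
from .memory import DiversityFilter
from .objective import (
    ObjectiveFunction,
    mw_threshold_component,
    qed_component,
    tanimoto_similarity_component,
)
from .seqmodel import PolicyNetwork, load_policy, save_policy, train_prior

# ---------------------------------------------------------------------------
# Fixture chemical space

#: Two drug-like ring-system templates, each with two attachment points
#: (atom-mapped dummy atoms).
DEFAULT_TEMPLATES: tuple[str, ...] = (
    "O=C(c1ccc([*:1])cc1)N1CCC([*:2])CC1",  # benzamide-piperidine
    "Cc1nc2n(c1[*:1])CCN(C2=O)[*:2]",  # fused pyrazinone
)

#: Thirty substituent fragments (attached through their first atom): small
#: alkyl/polar groups plus several ring-bearing fragments so that products
#: span many distinct Bemis-Murcko scaffolds.
DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CO", "OC", "N", "F", "Cl", "O",
    "CCO", "OCC", "N(C)C", "C(F)(F)F", "C(=O)C", "C(=O)N", "S(C)(=O)=O",
    "C#N", "CN", "CCN", "c1ccccc1", "c1ccncc1", "c1ccco1", "c1cccs1",
    "C1CC1", "C1CCC1", "N1CCCC1", "N1CCOCC1", "c1ccc(F)cc1", "Cn1cccc1",
)

#: Held-out rediscovery target of the fixture similarity task (a member of
#: the default space: template 1 + furan-2-yl + ethyl).
FIXTURE_TARGET = "CCC1CCN(C(=O)c2ccc(-c3ccco3)cc2)CC1"


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a fixture corpus."""

    templates: tuple[str, ...] = DEFAULT_TEMPLATES
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    n_molecules: int = 500
    seed: int = 0


def _attach(template: str, fragments: Sequence[str]) -> str | None:
    """Bond each fragment (through its first atom) to the matching mapped
    dummy atom of the template; returns canonical SMILES or None."""
    tmpl = Chem.MolFromSmiles(template)
    if tmpl is None:
        raise ValueError(f"unparseable template: {template!r}")
    maps = sorted(
        a.GetAtomMapNum() for a in tmpl.GetAtoms() if a.GetAtomicNum() == 0 and a.GetAtomMapNum()
    )
    if len(maps) != len(fragments):
        raise ValueError(f"template {template!r} has {len(maps)} attachment points")
    if not maps:
        return Chem.MolToSmiles(tmpl)
    combo = tmpl
    for map_num, frag in zip(maps, fragments):
        fmol = Chem.MolFromSmiles(f"[*:{map_num}]{frag}")
        if fmol is None:
            raise ValueError(f"unparseable substituent: {frag!r}")
        combo = Chem.CombineMols(combo, fmol)
    try:
        product = Chem.molzip(combo)
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return Chem.MolToSmiles(product)


def enumerate_fixture_space(spec: FixtureSpec) -> list[str]:
    """All unique valid products of the template x substituent enumeration,
    in deterministic first-seen order."""
    seen: dict[str, None] = {}
    for template in spec.templates:
        tmpl = Chem.MolFromSmiles(template)
        n_sites = sum(
            1 for a in tmpl.GetAtoms() if a.GetAtomicNum() == 0 and a.GetAtomMapNum()
        )
        for frags in itertools.product(spec.substituents, repeat=n_sites):
            smi = _attach(template, frags)
            if smi is not None:
                seen.setdefault(smi, None)
    return list(seen)


def generate_fixture_corpus(spec: FixtureSpec, exclude: Sequence[str] = ()) -> list[str]:
    """A deterministic random subset of the fixture space, ``n_molecules`` strong.

    Raises ``ValueError`` when the combinatorial space (minus exclusions) is
    too small.
    """
    space = [s for s in enumerate_fixture_space(spec) if s not in set(exclude)]
    if len(space) < spec.n_molecules:
        raise ValueError(
            f"fixture space has {len(space)} molecules; {spec.n_molecules} requested"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(space))
    return [space[i] for i in order[: spec.n_molecules]]


def fixture_similarity_task(
    n_molecules: int = 500, seed: int = 0
) -> tuple[list[str], str]:
    """(prior corpus, held-out target) of the mini-rediscovery task.

    The target is a member of the fixture space excluded from the corpus, so
    the Prior can spell it but has never seen it.
    """
    spec = FixtureSpec(n_molecules=n_molecules, seed=seed)
    corpus = generate_fixture_corpus(spec, exclude=[FIXTURE_TARGET])
    return corpus, FIXTURE_TARGET


# ---------------------------------------------------------------------------
# Run configuration

class ComponentConfig(BaseModel):
    type: Literal["tanimoto_similarity", "qed", "mw_threshold"]
    weight: float = 1.0
    reference: Optional[str] = None  # tanimoto_similarity
    threshold: float = 1.0  # tanimoto_similarity cap
    limit: float = 500.0  # mw_threshold


class TaskConfig(BaseModel):
    components: list[ComponentConfig] = Field(min_length=1)


class PriorTrainingConfig(BaseModel):
    """Desk-scale prior recipe: small LSTM, randomized-SMILES training."""

    corpus: Optional[str] = None  # .smi/CSV path; None -> built-in fixture corpus
    n_molecules: int = 500
    epochs: int = 250
    learning_rate: float = 5e-3
    final_learning_rate: Optional[float] = 5e-4
    batch_size: int = 64
    embedding_dim: int = 64
    hidden_size: int = 256
    num_layers: int = 1
    augment: bool = True
    seed: int = 0


class RunConfig(BaseModel):
    """Everything one benchmark run needs; loadable from YAML/JSON."""

    task: TaskConfig
    budget: int = Field(gt=0, default=3000)
    seeds: list[int] = Field(min_length=1, default_factory=lambda: [0])
    output_dir: str = "runs/out"
    algorithm: Literal["reinvent", "ahc", "bar", "augmented_memory"] = "augmented_memory"
    sigma: float = 128.0
    batch_size: int = 64
    learning_rate: float = 1e-4
    augmentation_rounds: int = 2
    ahc_topk_fraction: float = 0.5
    bar_alpha: float = 0.5
    replay_sample_size: int = 10
    buffer_capacity: int = 100
    max_length: int = 64
    diversity_filter: bool = False
    bucket_size: int = 25
    selective_purge: bool = False
    prior: Optional[str] = None  # checkpoint path; None -> train per prior_training
    prior_training: PriorTrainingConfig = Field(default_factory=PriorTrainingConfig)
    max_epochs: Optional[int] = None
    checkpoint_every: int = 0
    stop_at_mean_reward: Optional[float] = None

    @field_validator("algorithm")
    @classmethod
    def _known_algorithm(cls, v):
        assert v in ALGORITHMS
        return v

    def rl_config(self, seed: int) -> RLConfig:
        return RLConfig(
            sigma=self.sigma,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            augmentation_rounds=self.augmentation_rounds,
            algorithm=self.algorithm,
            ahc_topk_fraction=self.ahc_topk_fraction,
            bar_alpha=self.bar_alpha,
            replay_sample_size=self.replay_sample_size,
            buffer_capacity=self.buffer_capacity,
            max_length=self.max_length,
            seed=seed,
        )


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def build_objective(task: TaskConfig) -> ObjectiveFunction:
    components = []
    for comp in task.components:
        if comp.type == "tanimoto_similarity":
            if not comp.reference:
                raise ValueError("tanimoto_similarity component needs a 'reference' SMILES")
            components.append(
                tanimoto_similarity_component(
                    comp.reference, weight=comp.weight, threshold=comp.threshold
                )
            )
        elif comp.type == "qed":
            components.append(qed_component(weight=comp.weight))
        elif comp.type == "mw_threshold":
            components.append(mw_threshold_component(limit=comp.limit, weight=comp.weight))
    return ObjectiveFunction(components=components)


def _get_prior(config: RunConfig) -> PolicyNetwork:
    if config.prior:
        return load_policy(config.prior)
    pt = config.prior_training
    if pt.corpus:
        corpus = chemio.read_smiles(pt.corpus)
    else:
        corpus, _ = fixture_similarity_task(n_molecules=pt.n_molecules, seed=pt.seed)
    return train_prior(
        corpus,
        epochs=pt.epochs,
        lr=pt.learning_rate,
        final_lr=pt.final_learning_rate,
        rng=np.random.default_rng(pt.seed),
        batch_size=pt.batch_size,
        embedding_dim=pt.embedding_dim,
        hidden_size=pt.hidden_size,
        num_layers=pt.num_layers,
        augment=pt.augment,
    )


# ---------------------------------------------------------------------------
# Experiment driver

@dataclass
class RunResult:
    seed: int
    out_dir: Path
    state: TrainingState
    epoch_stats: list
    auc_top10: float
    intdiv1: Optional[float]


def run_single(
    config: RunConfig,
    seed: int,
    prior: PolicyNetwork,
    out_dir: str | Path | None = None,
) -> RunResult:
    """One seed of a run: epochs until the oracle budget would be exceeded.

    An epoch is only started while ``call_count + batch_size <= budget``, so
    the ledger can never exceed the budget. Runs are additionally capped at
    ``max_epochs`` (generous default) because a fully converged policy stops
    paying for new molecules and would otherwise loop forever.
    """
    cfg = config.rl_config(seed)
    objective = build_objective(config.task)
    df = DiversityFilter(bucket_size=config.bucket_size) if config.diversity_filter else None
    state = TrainingState.create(prior, cfg, df=df, selective_purge=config.selective_purge)
    max_epochs = config.max_epochs
    if max_epochs is None:
        max_epochs = 4 * -(-config.budget // config.batch_size)

    out = Path(out_dir) if out_dir is not None else Path(config.output_dir) / f"seed_{seed}"
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "epoch_log.jsonl"
    snap_dir = out / "checkpoints"
    stats = []
    with open(log_path, "w") as log:
        while (
            state.epoch < max_epochs
            and state.ledger.call_count + config.batch_size <= config.budget
        ):
            state = run_epoch(state, objective)
            s = state.last_stats
            stats.append(s)
            log.write(json.dumps(s.__dict__) + "\n")
            state.buffer.to_csv(out / "buffer.csv")
            if config.checkpoint_every and state.epoch % config.checkpoint_every == 0:
                snap_dir.mkdir(exist_ok=True)
                save_policy(state.agent, snap_dir / f"agent_epoch{state.epoch:04d}.npz")
            if (
                config.stop_at_mean_reward is not None
                and s.mean_reward >= config.stop_at_mean_reward
            ):
                break

    # generated-molecule log: one row per distinct oracle-scored molecule
    with open(out / "molecules.csv", "w") as fh:
        fh.write("call_index,smiles,reward\n")
        for idx, smi, reward in state.ledger.history:
            fh.write(f"{idx},{smi},{reward!r}\n")

    history = evalx.RunHistory.from_ledger(state.ledger)
    auc = evalx.auc_topk(history, k=10, budget=config.budget) if len(history) else 0.0
    unique = [smi for _, smi, _ in state.ledger.history]
    idiv = evalx.intdiv1(unique) if unique else None
    with open(out / "metrics.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "algorithm": config.algorithm,
                "oracle_calls": state.ledger.call_count,
                "epochs": state.epoch,
                "auc_top10": auc,
                "intdiv1": idiv,
            },
            fh,
            indent=2,
        )
    return RunResult(
        seed=seed, out_dir=out, state=state, epoch_stats=stats, auc_top10=auc, intdiv1=idiv
    )


def run_experiment(config: RunConfig, prior: PolicyNetwork | None = None) -> list[RunResult]:
    """All seeds of a configured run; returns one :class:`RunResult` per seed.

    A prior may be passed in to reuse an already-trained model; otherwise it
    is loaded from ``config.prior`` or trained per ``config.prior_training``.
    """
    if prior is None:
        prior = _get_prior(config)
    results = []
    for seed in config.seeds:
        results.append(run_single(config, seed, prior))
    return results
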