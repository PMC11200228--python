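"""Scoring components, multi-parameter aggregation, and oracle-call accounting.

An objective function is a weighted set of scoring components, each mapping a
canonical SMILES to a raw value and then through a monotone transform onto
[0, 1]. Component scores are combined with a weighted geometric mean into the
reward S(A) in [0, 1]; any zero component therefore zeroes the reward, which
is the behaviour wanted for hard constraints such as a molecular-weight cap.

Oracle accounting follows the budgeted-benchmark convention: one call per
distinct canonical SMILES ever scored. Duplicates, and in particular
alternative augmented SMILES representations of an already-scored molecule,
are free — this is what lets a score bought once be reused for many policy
updates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors, QED

from . import chemio
from .memory import ScoredMolecule

log = logging.getLogger(__name__)


@dataclass
class ScoringComponent:
    """One property oracle: raw function, transform to [0,1], and weight."""

    name: str
    raw_function: Callable[[str], float]
    transform: Callable[[float], float] = lambda x: float(x)
    weight: float = 1.0

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError(f"component {self.name}: weight must be nonnegative")

    def __call__(self, canonical_smiles: str) -> float:
        value = self.transform(self.raw_function(canonical_smiles))
        return float(min(1.0, max(0.0, value)))


@dataclass
class ObjectiveFunction:
    """Weighted-geometric-mean aggregation of scoring components."""

    components: list[ScoringComponent]

    def score(self, canonical_smiles: str) -> tuple[float, dict[str, float]]:
        """Reward in [0,1] plus the per-component transformed scores.

        A component whose raw function raises scores 0 (and the failure is
        logged), which zeroes the aggregate.
        """
        scores: dict[str, float] = {}
        for comp in self.components:
            try:
                scores[comp.name] = comp(canonical_smiles)
            except Exception:  # noqa: BLE001 - external oracles may fail arbitrarily
                log.warning("component %s failed on %s", comp.name, canonical_smiles, exc_info=True)
                scores[comp.name] = 0.0
        total_w = sum(c.weight for c in self.components)
        if total_w == 0:
            return 0.0, scores
        if any(scores[c.name] == 0.0 and c.weight > 0 for c in self.components):
            return 0.0, scores
        log_mean = sum(
            c.weight * math.log(scores[c.name]) for c in self.components if c.weight > 0
        ) / total_w
        return float(math.exp(log_mean)), scores


class OracleLedger:
    """Cache + call counter: one charged call per distinct canonical SMILES.

    ``history`` records (call_index, smiles, reward) in scoring order, one
    entry per distinct molecule, for budget-curve metrics.
    """

    def __init__(self):
        self.cache: dict[str, tuple[float, dict[str, float]]] = {}
        self.history: list[tuple[int, str, float]] = []

    @property
    def call_count(self) -> int:
        return len(self.cache)

    def lookup(self, canonical_smiles: str):
        return self.cache.get(canonical_smiles)

    def record(self, canonical_smiles: str, reward: float, components: dict[str, float]) -> None:
        if canonical_smiles in self.cache:
            return
        self.cache[canonical_smiles] = (reward, components)
        self.history.append((len(self.cache), canonical_smiles, reward))


def score_batch(
    objective: ObjectiveFunction,
    smiles: Sequence[str],
    ledger: OracleLedger,
) -> list[ScoredMolecule]:
    """Score a batch of (possibly raw, possibly invalid) SMILES.

    Invalid strings get reward 0 and cost nothing; cache hits are free; each
    new distinct valid canonical SMILES charges the ledger exactly once.
    """
    out: list[ScoredMolecule] = []
    for s in smiles:
        mol = chemio.canonicalize(s)
        if not mol.valid:
            out.append(ScoredMolecule(canonical_smiles=None, reward=0.0))
            continue
        can = mol.canonical_smiles
        cached = ledger.lookup(can)
        if cached is None:
            reward, comps = objective.score(can)
            ledger.record(can, reward, comps)
        else:
            reward, comps = cached
        out.append(
            ScoredMolecule(
                canonical_smiles=can,
                reward=reward,
                scaffold=chemio.scaffold(can),
                components=dict(comps),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Component constructors


def tanimoto_similarity_component(
    reference: str,
    name: str = "tanimoto_similarity",
    weight: float = 1.0,
    threshold: float = 1.0,
) -> ScoringComponent:
    """Tanimoto similarity (Morgan r=2, 2048 bits) to a reference molecule.

    With the default ``threshold=1.0`` the transform is the identity. A lower
    threshold applies the rediscovery-benchmark convention
    ``min(1, similarity / threshold)``: any molecule at least that similar to
    the reference earns the full reward, which keeps the top of the reward
    landscape populated when the accessible chemical space is small.
    """
    ref = chemio.canonicalize(reference)
    if not ref.valid:
        raise ValueError(f"unparseable reference SMILES: {reference!r}")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ref_fp = chemio.morgan_fingerprint(ref.canonical_smiles)

    def raw(smiles: str) -> float:
        return chemio.tanimoto(chemio.morgan_fingerprint(smiles), ref_fp)

    return ScoringComponent(
        name=name,
        raw_function=raw,
        transform=lambda sim: min(1.0, sim / threshold),
        weight=weight,
    )


def qed_component(name: str = "qed", weight: float = 1.0) -> ScoringComponent:
    """QED drug-likeness (already in [0,1]; identity transform)."""

    def raw(smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return 0.0
        return float(QED.qed(mol))

    return ScoringComponent(name=name, raw_function=raw, weight=weight)


def mw_threshold_component(
    limit: float = 500.0, name: str = "mw_below", weight: float = 1.0
) -> ScoringComponent:
    """Hard molecular-weight step: 1 if MW < limit (Da), else 0."""
    if limit <= 0:
        raise ValueError("limit must be > 0")

    def raw(smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return float("inf")
        return float(Descriptors.MolWt(mol))

    return ScoringComponent(
        name=name, raw_function=raw, transform=lambda mw: 1.0 if mw < limit else 0.0, weight=weight
    )


def reverse_sigmoid(midpoint: float, steepness: float = 1.0) -> Callable[[float], float]:
    """Decreasing logistic transform for minimized quantities (e.g. docking scores).

    Maps the midpoint to 0.5; lower raw values map strictly higher.
    """

    def transform(x: float) -> float:
        return float(1.0 / (1.0 + math.exp(steepness * (x - midpoint))))

    return transform


def sa_score_transform(x: float) -> float:
    """Map the synthetic-accessibility scale [1, 10] reversed onto [0, 1]."""
    return float(min(1.0, max(0.0, (10.0 - x) / 9.0)))


def external_oracle_component(
    kind: str,
    raw_function: Callable[[str], float],
    weight: float = 1.0,
    midpoint: float = 0.0,
    steepness: float = 1.0,
    name: str | None = None,
) -> ScoringComponent:
    """Wrap an external property oracle (docking, xTB IP, SA score).

    The adapters are interface-only: ``raw_function`` is user-supplied (a
    subprocess wrapper or a deterministic stub). ``docking`` and ``xtb_ip``
    are minimized quantities and get a reverse sigmoid with configurable
    midpoint/steepness; ``sa_score`` gets the reversed linear [1,10] map.
    An oracle failure scores the molecule 0 (handled in ObjectiveFunction).
    """
    if kind not in ("docking", "xtb_ip", "sa_score"):
        raise ValueError(f"unknown external oracle kind: {kind!r}")
    transform = sa_score_transform if kind == "sa_score" else reverse_sigmoid(midpoint, steepness)
    return ScoringComponent(
        name=name or kind, raw_function=raw_function, transform=transform, weight=weight
    )


#: Reference DRD2 inverse agonist used by the drug-discovery worked example
#: (QED 0.66, MW ~410 Da).
RISPERIDONE = "CC1=C(CCN2CCC(CC2)c2noc3cc(F)ccc23)C(=O)N2CCCCC2=N1"
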