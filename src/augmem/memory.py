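"""Experience replay buffer, scaffold diversity filter, and selective memory purge.

The replay buffer keeps the highest-rewarded unique molecules sampled so far
(capacity 100 by default). The diversity filter (DF) assigns each Bemis–Murcko
scaffold a "bucket" of fixed size (25 by default); once a bucket is full,
further molecules with that scaffold receive zero reward. Selective memory
purge removes buffer entries whose scaffold the DF has penalized, so that
replay-driven policy updates never keep reinforcing a scaffold that no longer
earns reward — the mechanism that rescues replay-heavy training from mode
collapse.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import chemio


@dataclass(frozen=True)
class ScoredMolecule:
    """A scored sample: canonical SMILES, reward in [0,1], scaffold, components.

    Invalid samples are represented with ``canonical_smiles=None`` and reward
    0 so they can travel through a training batch without entering the buffer.
    """

    canonical_smiles: str | None
    reward: float
    scaffold: str | None = None
    components: dict[str, float] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.canonical_smiles is not None

    def with_reward(self, reward: float) -> "ScoredMolecule":
        return replace(self, reward=reward)


class ReplayBuffer:
    """Capacity-bounded, reward-sorted, deduplicated store of best molecules.

    Sorted by reward descending with stable insertion-order tie-breaking.
    Zero-reward molecules are never inserted.
    """

    def __init__(self, capacity: int = 100):
        if capacity < 0:
            raise ValueError("capacity must be >= 0")
        self.capacity = capacity
        self._entries: list[ScoredMolecule] = []
        self._counter = 0  # insertion stamps for stable tie-breaks
        self._stamps: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    @property
    def entries(self) -> list[ScoredMolecule]:
        return list(self._entries)

    def update(self, batch: Sequence[ScoredMolecule]) -> None:
        """Merge a batch: dedupe by canonical SMILES (keep the max reward),
        re-sort, truncate to capacity."""
        best: dict[str, ScoredMolecule] = {m.canonical_smiles: m for m in self._entries}
        for mol in batch:
            if not mol.valid or mol.reward <= 0.0:
                continue
            prev = best.get(mol.canonical_smiles)
            if prev is None:
                self._counter += 1
                self._stamps.setdefault(mol.canonical_smiles, self._counter)
                best[mol.canonical_smiles] = mol
            elif mol.reward > prev.reward:
                best[mol.canonical_smiles] = mol
        ordered = sorted(
            best.values(), key=lambda m: (-m.reward, self._stamps[m.canonical_smiles])
        )
        self._entries = ordered[: self.capacity]

    def sample(self, n: int, rng: np.random.Generator) -> list[ScoredMolecule]:
        """Uniform sample without replacement of size min(n, len(buffer))."""
        if n <= 0 or not self._entries:
            return []
        k = min(n, len(self._entries))
        idx = rng.choice(len(self._entries), size=k, replace=False)
        return [self._entries[i] for i in idx]

    def augment(self, rng: np.random.Generator) -> list[tuple[str, float]]:
        """One freshly randomized SMILES per entry, paired with the stored reward.

        No oracle is consulted: the reward attached to each augmented string is
        the one already paid for when the molecule was first scored.
        """
        return [
            (chemio.randomize_smiles(m.canonical_smiles, rng), m.reward) for m in self._entries
        ]

    def purge(self, penalized_scaffolds: set[str]) -> int:
        """Drop entries whose scaffold is penalized; returns how many were removed."""
        before = len(self._entries)
        self._entries = [m for m in self._entries if m.scaffold not in penalized_scaffolds]
        return before - len(self._entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["smiles", "reward", "scaffold"])
            for m in self._entries:
                w.writerow([m.canonical_smiles, repr(m.reward), m.scaffold])


class DiversityFilter:
    """Scaffold -> sample-count map with fixed bucket size.

    Counts only ever increase, and only valid molecules increment a bucket.
    A scaffold is penalized once its count has reached ``bucket_size``.
    """

    def __init__(self, bucket_size: int = 25):
        if bucket_size < 0:
            raise ValueError("bucket_size must be >= 0")
        self.bucket_size = bucket_size
        self.bucket_counts: dict[str, int] = {}

    def is_penalized(self, scaffold_key: str) -> bool:
        return self.bucket_counts.get(scaffold_key, 0) >= self.bucket_size

    @property
    def penalized_scaffolds(self) -> set[str]:
        return {s for s, c in self.bucket_counts.items() if c >= self.bucket_size}

    def apply(self, batch: Sequence[ScoredMolecule]) -> list[ScoredMolecule]:
        """Zero the reward of molecules whose scaffold bucket is already full.

        Processing is order-dependent within the batch: each valid molecule
        first consults its bucket, then increments it, so the (bucket_size+1)-th
        occurrence of a scaffold is the first to be zeroed.
        """
        out: list[ScoredMolecule] = []
        for mol in batch:
            if not mol.valid or mol.scaffold is None:
                out.append(mol)
                continue
            if self.is_penalized(mol.scaffold):
                mol = mol.with_reward(0.0)
            self.bucket_counts[mol.scaffold] = self.bucket_counts.get(mol.scaffold, 0) + 1
            out.append(mol)
        return out


# module-level aliases matching the operation vocabulary used elsewhere


def buffer_update(buffer: ReplayBuffer, batch: Sequence[ScoredMolecule]) -> ReplayBuffer:
    buffer.update(batch)
    return buffer


def buffer_sample(buffer: ReplayBuffer, n: int, rng: np.random.Generator) -> list[ScoredMolecule]:
    return buffer.sample(n, rng)


def buffer_augment(buffer: ReplayBuffer, rng: np.random.Generator) -> list[tuple[str, float]]:
    return buffer.augment(rng)


def df_apply(df: DiversityFilter, batch: Sequence[ScoredMolecule]) -> list[ScoredMolecule]:
    return df.apply(batch)


def selective_memory_purge(buffer: ReplayBuffer, df: DiversityFilter) -> ReplayBuffer:
    """Remove every buffer entry whose scaffold the DF penalizes (order kept)."""
    buffer.purge(df.penalized_scaffolds)
    return buffer
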