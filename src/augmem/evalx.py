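"""Evaluation metrics for oracle-budgeted generative runs.

* ``auc_topk`` — the budgeted-benchmark headline metric: the running mean of
  the top-k rewards seen so far, evaluated after every oracle call,
  step-integrated over the call budget and normalized by it. Rewards high
  scores found *early*.
* ``intdiv1`` — internal diversity of a generated set: 1 minus the mean
  pairwise Tanimoto similarity (self-pairs included, power mean p=1).
* ``filter_pass`` — triage counting: how many molecules satisfy a list of
  per-component threshold rules.
* ``compare_runs`` — Welch's t-test across seeds for algorithm comparisons.
"""

from __future__ import annotations

import heapq
import operator
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import chemio


@dataclass(frozen=True)
class RunHistory:
    """Ordered (oracle_call_index, canonical_smiles, reward) records of a run.

    One record per distinct molecule, call indices strictly increasing —
    exactly what :class:`~augmem.objective.OracleLedger` accumulates.
    """

    records: tuple[tuple[int, str, float], ...]

    @classmethod
    def from_ledger(cls, ledger) -> "RunHistory":
        return cls(records=tuple(ledger.history))

    def __len__(self) -> int:
        return len(self.records)


def auc_topk(history: RunHistory | Sequence[tuple[int, str, float]], k: int = 10, budget: int = 10000) -> float:
    """AUC of the running top-k mean reward over the oracle-call budget.

    After each oracle call the mean of the k best rewards seen so far (or of
    all rewards, while fewer than k exist) is the curve value; the curve is a
    step function carried forward to the budget if the run ended early, and
    the area is divided by ``budget``.
    """
    records = history.records if isinstance(history, RunHistory) else tuple(history)
    if not records or k < 1:
        raise ValueError("history must be nonempty and k >= 1")
    heap: list[float] = []  # min-heap of the current top-k
    top_sum = 0.0
    area = 0.0
    prev_call = 0
    value = 0.0
    for call_idx, _smiles, reward in records:
        if call_idx > budget:
            break
        area += value * (call_idx - prev_call - 1)  # calls with no new record...
        # (call indices are consecutive per distinct molecule, so this is 0 in
        # practice; kept for histories with gaps)
        if len(heap) < k:
            heapq.heappush(heap, reward)
            top_sum += reward
        elif reward > heap[0]:
            top_sum += reward - heapq.heappushpop(heap, reward)
        value = top_sum / len(heap)
        area += value
        prev_call = call_idx
    area += value * (budget - prev_call)  # carry the final value forward
    return area / budget


def intdiv1(smiles: Sequence[str]) -> float:
    """Internal diversity: 1 - mean pairwise Tanimoto over all ordered pairs.

    Self-pairs are included, so a set of n copies of one molecule scores 0
    and two disjoint-fingerprint molecules score 0.5. Invalid SMILES are
    ignored; raises if nothing is valid.
    """
    fps = chemio.fingerprint_matrix(smiles)
    n = fps.shape[0]
    if n == 0:
        raise ValueError("intdiv1 needs at least one valid molecule")
    a = fps.astype(np.float32)
    inter = a @ a.T
    pop = a.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    # a molecule with an empty fingerprint is identical to itself
    empty = pop == 0
    if empty.any():
        sim[np.ix_(empty, empty)] = 1.0
    return float(1.0 - sim.sum() / (n * n))


_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


def filter_pass(
    molecules: Sequence[dict],
    rules: Sequence[tuple[str, str, float]],
) -> tuple[int, list[dict]]:
    """Count and return the molecules satisfying ALL (component, cmp, threshold) rules.

    Each molecule is a mapping with at least the component keys named by the
    rules (e.g. the ``components`` dict of a scored molecule, optionally with
    'smiles'/'reward' entries). A missing component raises ``KeyError``.
    """
    survivors = []
    for mol in molecules:
        ok = True
        for component, cmp_name, threshold in rules:
            if component not in mol:
                raise KeyError(f"component {component!r} missing from molecule record")
            if cmp_name not in _COMPARATORS:
                raise ValueError(f"unknown comparator {cmp_name!r}")
            if not _COMPARATORS[cmp_name](mol[component], threshold):
                ok = False
                break
        if ok:
            survivors.append(mol)
    return len(survivors), survivors


def compare_runs(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, bool]:
    """Welch's t-test between two sets of per-seed metric values.

    Returns (t statistic, p value, significant at the 95% confidence level).
    """
    t, p = stats.ttest_ind(list(values_a), list(values_b), equal_var=False)
    return float(t), float(p), bool(p < 0.05)
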