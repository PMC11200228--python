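"""Chemistry substrate: SMILES handling, scaffolds, fingerprints, similarity.

All other modules speak SMILES through this one. RDKit does the parsing,
canonicalization and graph work; molecules that fail to parse are carried
as explicit invalid markers rather than exceptions, because a generative
policy routinely emits unparseable strings and downstream code must treat
them as zero-reward samples, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

# RDKit parse warnings would flood logs when scoring generated batches.
RDLogger.DisableLog("rdApp.*")

#: Fingerprint convention used throughout: extended-connectivity (Morgan)
#: radius 2, 2048 bits — the GuacaMol/MOSES standard for similarity oracles
#: and internal-diversity metrics.
FP_RADIUS = 2
FP_NBITS = 2048

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_NBITS)


@dataclass(frozen=True)
class Molecule:
    """A parse result: canonical SMILES if valid, an invalid marker otherwise."""

    canonical_smiles: str | None
    valid: bool

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid


INVALID = Molecule(canonical_smiles=None, valid=False)


@lru_cache(maxsize=200_000)
def canonicalize(smiles: str) -> Molecule:
    """Parse ``smiles`` and return its toolkit-canonical form.

    Unparseable input yields ``Molecule(None, valid=False)``; no exception
    is raised. Stereochemistry is preserved. Memoized (the result is an
    immutable value object): converged policies resample the same strings
    every epoch.
    """
    if not isinstance(smiles, str) or not smiles:
        return INVALID
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return INVALID
    return Molecule(canonical_smiles=Chem.MolToSmiles(mol), valid=True)


def randomize_smiles(smiles: str, rng: np.random.Generator) -> str:
    """Write the molecule as a random non-canonical SMILES.

    The atom numbering of the molecular graph is shuffled uniformly and the
    depth-first SMILES writer is run on the renumbered graph, so repeated
    calls enumerate alternative string representations of the same molecule.
    Deterministic given the generator state.

    Raises ``ValueError`` on unparseable input. In the (unexpected) event
    that the randomized string fails to re-parse, the canonical SMILES is
    returned instead so callers always receive a valid representation.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot randomize unparseable SMILES: {smiles!r}")
    perm = rng.permutation(mol.GetNumAtoms())
    shuffled = Chem.RenumberAtoms(mol, [int(i) for i in perm])
    out = Chem.MolToSmiles(shuffled, canonical=False)
    if Chem.MolFromSmiles(out) is None:  # guard: should not occur
        return Chem.MolToSmiles(mol)
    return out


@lru_cache(maxsize=200_000)
def scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold (ring systems + linkers, heavy atoms) as canonical SMILES.

    Acyclic molecules have an empty framework; by convention their own
    canonical SMILES is returned so each acyclic molecule occupies its own
    diversity-filter bucket instead of all sharing one empty key.
    Memoized: generative runs recompute scaffolds of the same molecules every
    epoch.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot compute scaffold of unparseable SMILES: {smiles!r}")
    core = MurckoScaffold.GetScaffoldForMol(mol)
    key = Chem.MolToSmiles(core) if core is not None else ""
    if not key:
        key = Chem.MolToSmiles(mol)
    return key


def morgan_fingerprint(smiles: str) -> np.ndarray:
    """ECFP-like Morgan fingerprint (radius 2, 2048 bits) as a boolean vector.

    Raises ``ValueError`` on unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint unparseable SMILES: {smiles!r}")
    fp = _MORGAN.GetFingerprint(mol)
    arr = np.zeros(FP_NBITS, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two bit vectors.

    Defined as 0.0 when both vectors are empty. Raises ``ValueError`` on a
    length mismatch.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def fingerprint_matrix(smiles: Sequence[str]) -> np.ndarray:
    """Stack fingerprints of valid molecules into an (n, 2048) boolean matrix.

    Invalid SMILES are silently dropped (the caller is expected to have
    filtered already; this keeps batch metrics robust).
    """
    rows = []
    for s in smiles:
        if Chem.MolFromSmiles(s) is not None:
            rows.append(morgan_fingerprint(s))
    if not rows:
        return np.zeros((0, FP_NBITS), dtype=bool)
    return np.stack(rows)


# ---------------------------------------------------------------------------
# File I/O: .smi (one SMILES per line, optional tab-separated name) and CSV
# with a `smiles` column.

def read_smiles(path: str | Path) -> list[str]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path}: CSV input needs a 'smiles' column")
        return [str(s) for s in df["smiles"].tolist()]
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t")[0].split(" ")[0])
    return out


def write_smiles(path: str | Path, smiles: Iterable[str]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame({"smiles": list(smiles)}).to_csv(path, index=False)
    else:
        path.write_text("".join(f"{s}\n" for s in smiles))
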