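"""Population-level evaluation of generated molecule sets.

Five coefficients -- validity, accuracy (scaffold containment),
desirability, uniqueness, novelty -- plus Solow-Polasky diversity
I(A) = (1/m) e^T F^-1 e with kernel f(d) = exp(-theta d) over pairwise
Tanimoto distances of ECFP6 fingerprints.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

SOLOW_POLASKY_THETA = 0.5


def tanimoto_distance(fp_i: frozenset, fp_j: frozenset) -> float:
    """1 - |i & j| / |i | j|; 0 for two empty fingerprints."""
    union = len(fp_i | fp_j)
    if union == 0:
        return 0.0
    return 1.0 - len(fp_i & fp_j) / union


def contains_scaffold(mol_smiles: str, scaffold: str) -> bool:
    """True iff every fragment of the scaffold is a substructure of the molecule.

    Matching is attempted on both the aromatic-perceived and the kekulized
    form of the molecule; failing under both counts as a miss.  (Growing an
    aliphatic scaffold into a ring that is later aromatized can therefore
    legitimately break containment -- e.g. 'CCC' grown into toluene.)
    """
    mol = Chem.MolFromSmiles(mol_smiles)
    if mol is None:
        return False
    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Exception:
        kek = None
    for frag in scaffold.split("."):
        query = Chem.MolFromSmiles(frag)
        if query is None:
            raise ValueError(f"unparsable scaffold fragment {frag!r}")
        if mol.HasSubstructMatch(query):
            continue
        if kek is not None and kek.HasSubstructMatch(query):
            continue
        return False
    return True


@dataclass
class MetricsReport:
    """The five population coefficients plus diversity and raw counts."""

    n_total: int
    n_valid: int
    n_accurate: int
    n_desired: int
    n_unique: int
    n_novel: int
    diversity: float

    @property
    def validity(self) -> float:
        return self.n_valid / self.n_total

    @property
    def accuracy(self) -> float:
        return self.n_accurate / self.n_total

    @property
    def desirability(self) -> float:
        return self.n_desired / self.n_total

    @property
    def uniqueness(self) -> float:
        return self.n_unique / self.n_total

    @property
    def novelty(self) -> float:
        return self.n_novel / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "validity": self.validity,
            "accuracy": self.accuracy,
            "desirability": self.desirability,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "diversity": self.diversity,
        }


def solow_polasky_diversity(
    fingerprints: Sequence[frozenset], theta: float = SOLOW_POLASKY_THETA
) -> float:
    """Solow-Polasky diversity, normalized by population size into (0, 1].

    Exact duplicates (distance-0 pairs) make the kernel matrix singular and
    are collapsed first; m counts distinct members.  A single molecule has
    diversity exactly 1.
    """
    distinct = list(dict.fromkeys(fingerprints))
    m = len(distinct)
    if m == 0:
        raise ValueError("empty population")
    if m == 1:
        return 1.0
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = tanimoto_distance(distinct[i], distinct[j])
    kernel = np.exp(-theta * dist)
    try:
        x = np.linalg.solve(kernel, np.ones(m))
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(kernel)
        raise ValueError(
            f"singular similarity kernel after deduplication (cond={cond:.3e})"
        ) from exc
    return float(x.sum() / m)


def population_metrics(
    generated: Sequence[tuple[str, str]],
    reference: set[str],
    desired_flags: Optional[Sequence[bool]] = None,
    theta: float = SOLOW_POLASKY_THETA,
) -> MetricsReport:
    """Compute the five coefficients and diversity for a generated set.

    ``generated`` holds (smiles, input_scaffold) pairs; ``reference`` is the
    set of canonical training-corpus SMILES used for novelty.  Uniqueness
    counts distinct canonical structures; novelty counts the unique ones
    absent from the reference.
    """
    from .environment import ecfp6_bitset

    n_total = len(generated)
    if n_total == 0:
        raise ValueError("empty generated population")
    desired_flags = (
        [False] * n_total if desired_flags is None else list(desired_flags)
    )
    canon: list[Optional[str]] = []
    n_valid = n_accurate = 0
    for smiles, scaffold in generated:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            canon.append(None)
            continue
        n_valid += 1
        canon.append(Chem.MolToSmiles(mol))
        if scaffold and contains_scaffold(smiles, scaffold):
            n_accurate += 1
    distinct = {c for c in canon if c is not None}
    n_unique = len(distinct)
    reference_canon = {Chem.CanonSmiles(s) for s in reference}
    n_novel = len(distinct - reference_canon)
    n_desired = int(np.sum(np.asarray(desired_flags, dtype=bool)))
    fps = [ecfp6_bitset(c) for c in distinct]
    diversity = solow_polasky_diversity(fps, theta) if fps else 0.0
    return MetricsReport(
        n_total=n_total,
        n_valid=n_valid,
        n_accurate=n_accurate,
        n_desired=n_desired,
        n_unique=n_unique,
        n_novel=n_novel,
        diversity=diversity,
    )
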