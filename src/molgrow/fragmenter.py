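"""BRICS leaf fragmentation and scaffold-molecule training pairs.

Molecules are cut at the 16 BRICS retrosynthetic bond environments; the
resulting leaf fragments (attachment dummies stripped, open valences
hydrogen-capped) become "scaffolds": '.'-joined combinations of fragments
the generator must reproduce inside its output molecule.  A molecule with
n <= 4 leaves yields one pair per non-empty fragment subset, 2^n - 1 in
total; when more than four leaves exist, the four largest by heavy-atom
count are kept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .chem_io import InputError, MoleculeRecord

logger = logging.getLogger("molgrow")

MAX_FRAGMENTS = 4


@dataclass(frozen=True)
class FragmentSet:
    """BRICS leaf fragments of one molecule, largest-first, n <= 4."""

    molecule: MoleculeRecord
    fragments: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class ScaffoldPair:
    """A '.'-joined fragment combination paired with its source molecule."""

    scaffold: str
    molecule_smiles: str
    subset_size: int

    @property
    def scaffold_key(self) -> str:
        """Order-independent scaffold identity (sorted canonical fragments)."""
        return ".".join(sorted(self.scaffold.split(".")))


def strip_attachment_points(frag_smiles: str) -> str:
    """Remove BRICS dummy atoms ([n*]) and cap the open valences with H."""
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:
        raise InputError(f"unparsable fragment: {frag_smiles!r}")
    rw = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        neighbor = rw.GetAtomWithIdx(idx).GetNeighbors()[0]
        # aromatic N loses its implicit-H bookkeeping when the dummy goes
        if neighbor.GetIsAromatic() and neighbor.GetSymbol() == "N":
            neighbor.SetNumExplicitHs(neighbor.GetNumExplicitHs() + 1)
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def brics_leaf_fragments(mol: MoleculeRecord) -> FragmentSet:
    """Decompose into BRICS leaf fragments (the non-cleavable pieces).

    Fragments are ranked by heavy-atom count (ties broken by canonical
    SMILES) and at most the four largest are kept.
    """
    rdmol = mol.mol()
    if rdmol.GetNumAtoms() == 0:
        raise InputError("molecule has no atoms")
    leaves = BRICS.BRICSDecompose(rdmol, keepNonLeafNodes=False)
    capped = sorted({strip_attachment_points(s) for s in leaves})
    capped = [s for s in capped if Chem.MolFromSmiles(s).GetNumHeavyAtoms() > 0]
    if not capped:
        capped = [Chem.MolToSmiles(rdmol)]
    ranked = sorted(
        capped,
        key=lambda s: (-Chem.MolFromSmiles(s).GetNumHeavyAtoms(), s),
    )
    return FragmentSet(molecule=mol, fragments=tuple(ranked[:MAX_FRAGMENTS]))


def enumerate_pairs(fs: FragmentSet, rng_seed: int) -> list[ScaffoldPair]:
    """All 2^n - 1 non-empty fragment subsets, each paired with the molecule.

    Fragment order inside each scaffold is randomized by ``rng_seed``; the
    set of pairs (and their count) is seed-invariant.
    """
    rng = np.random.default_rng(rng_seed)
    pairs = []
    for size in range(1, fs.n + 1):
        for subset in combinations(fs.fragments, size):
            order = rng.permutation(size)
            scaffold = ".".join(subset[i] for i in order)
            pairs.append(
                ScaffoldPair(
                    scaffold=scaffold,
                    molecule_smiles=fs.molecule.smiles,
                    subset_size=size,
                )
            )
    return pairs


def scaffold_split(
    pairs: list[ScaffoldPair],
    ratios: tuple[int, int, int] = (8, 1, 1),
    rng_seed: int = 0,
) -> tuple[list[ScaffoldPair], list[ScaffoldPair], list[ScaffoldPair]]:
    """Partition pairs 8:1:1 by distinct scaffold identity.

    Every pair follows its scaffold's partition, so no scaffold string
    appears in two partitions.  On small sets validation and test each get
    ceil(N * ratio / total) scaffolds and the remainder goes to training.
    """
    if ratios != (8, 1, 1):
        total = sum(ratios)
    else:
        total = 10
    keys = sorted({p.scaffold_key for p in pairs})
    if len(keys) < 3:
        raise InputError(f"need >= 3 distinct scaffolds, got {len(keys)}")
    rng = np.random.default_rng(rng_seed)
    order = [keys[i] for i in rng.permutation(len(keys))]
    n_valid = ceil(len(keys) * ratios[1] / total)
    n_test = ceil(len(keys) * ratios[2] / total)
    valid_keys = set(order[:n_valid])
    test_keys = set(order[n_valid : n_valid + n_test])
    train, valid, test = [], [], []
    for p in pairs:
        key = p.scaffold_key
        if key in valid_keys:
            valid.append(p)
        elif key in test_keys:
            test.append(p)
        else:
            train.append(p)
    return train, valid, test


def pairs_from_library(
    records: list[MoleculeRecord], rng_seed: int = 0, max_subset_size: int | None = None
) -> list[ScaffoldPair]:
    """Fragment every record and enumerate its scaffold-molecule pairs."""
    pairs = []
    for i, rec in enumerate(records):
        fs = brics_leaf_fragments(rec)
        for p in enumerate_pairs(fs, rng_seed + i):
            if max_subset_size is None or p.subset_size <= max_subset_size:
                pairs.append(p)
    return pairs
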