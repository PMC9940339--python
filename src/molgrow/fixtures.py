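"""Synthetic (generated) molecule libraries for desk-scale experiments.

The library is built by combinatorially decorating a fixed panel of
heteroaromatic cores common among adenosine-receptor ligands (furan,
triazine, aminotriazole, xanthine-like, azapurine-like, plus simple
carbo/heterocycles) with small substituents.  Each molecule carries a
deterministic pseudo-activity: a core-ring-system-dependent base value in
[4, 9] pChEMBL units plus seeded Gaussian noise (sigma = 0.3), giving a
learnable structure--activity signal for end-to-end tests of the scoring
and reinforcement-learning machinery.
"""
from __future__ import annotations

import hashlib
from itertools import product

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import InputError, MoleculeRecord, standardize

#: Decoration templates: numbered dummy atoms mark substitution sites.
CORES: dict[str, str] = {
    "furan": "[1*]c1ccc([2*])o1",
    "thiophene": "[1*]c1ccc([2*])s1",
    "benzene": "[1*]c1ccc([2*])cc1",
    "pyrimidine": "[1*]c1nccc([2*])n1",
    "triazine": "[1*]c1nc([2*])nc(N)n1",
    "aminotriazole": "Nc1nc([1*])n([2*])n1",
    "xanthine": "O=c1n([1*])c(=O)c2c(ncn2[2*])n1C",
    "azapurine": "Nc1nc([1*])nn2c([2*])nnc12",
}

#: Substituents; the first atom of each SMILES is the attachment atom.
#: The empty string means "cap with hydrogen".
SUBSTITUENTS: tuple[str, ...] = (
    "",
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "OC",
    "N",
    "NC",
    "F",
    "Cl",
    "C#N",
    "C(F)(F)F",
    "CO",
    "c1ccccc1",
)

NOISE_SIGMA = 0.3
PX_RANGE = (4.0, 9.0)


def _decorate(core_smiles: str, subs: tuple[str, ...]) -> str | None:
    """Replace the numbered dummy atoms of a core with substituents."""
    mol = Chem.RWMol(Chem.MolFromSmiles(core_smiles))
    # map-number -> substituent, applied one dummy at a time
    for site, sub in enumerate(subs, start=1):
        dummy = next(
            (
                a.GetIdx()
                for a in mol.GetAtoms()
                if a.GetAtomicNum() == 0 and a.GetIsotope() == site
            ),
            None,
        )
        if dummy is None:
            return None
        neighbor = mol.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
        if sub == "":
            mol.RemoveAtom(dummy)
        else:
            frag = Chem.MolFromSmiles(sub)
            offset = mol.GetNumAtoms()
            combined = Chem.RWMol(Chem.CombineMols(mol.GetMol(), frag))
            combined.AddBond(neighbor, offset, Chem.BondType.SINGLE)
            combined.RemoveAtom(dummy)
            mol = combined
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def _stable_unit_hash(text: str) -> float:
    """Map a string to a reproducible float in [0, 1)."""
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def pseudo_activity(smiles: str, seed: int, index: int) -> float:
    """Deterministic pX: ring-system base in [4, 9] plus seeded noise."""
    mol = Chem.MolFromSmiles(smiles)
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol) or smiles
    lo, hi = PX_RANGE
    base = lo + (hi - lo) * _stable_unit_hash(scaffold)
    noise = np.random.default_rng([seed % 2**31, index]).normal(0.0, NOISE_SIGMA)
    return float(base + noise)


_SPACE_CACHE: list[str] | None = None


def enumerate_fixture_space() -> list[str]:
    """All distinct decorated molecules, in a fixed deterministic order."""
    global _SPACE_CACHE
    if _SPACE_CACHE is not None:
        return _SPACE_CACHE
    seen, out = set(), []
    for core_name, core in CORES.items():
        n_sites = Chem.MolFromSmiles(core).GetNumAtoms() and sum(
            1 for a in Chem.MolFromSmiles(core).GetAtoms() if a.GetAtomicNum() == 0
        )
        for subs in product(SUBSTITUENTS, repeat=n_sites):
            smiles = _decorate(core, subs)
            if smiles is not None and smiles not in seen:
                seen.add(smiles)
                out.append(smiles)
    _SPACE_CACHE = out
    return out


def generate_fixture_library(seed: int, n: int) -> list[MoleculeRecord]:
    """Generate ``n`` distinct standardized molecules with pseudo-activities.

    Deterministic: the same seed yields a byte-identical library; different
    seeds select and order decorations differently.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    space = enumerate_fixture_space()
    if n > len(space):
        raise InputError(
            f"requested {n} molecules but the fixture space holds only {len(space)}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.permutation(len(space))[:n]
    records = []
    for i, idx in enumerate(picks):
        smiles = space[idx]
        rec = standardize(MoleculeRecord(smiles=smiles, id=f"FIX{i:05d}"))
        records.append(
            MoleculeRecord(
                smiles=rec.smiles,
                id=rec.id,
                pX=pseudo_activity(rec.smiles, seed, i),
            )
        )
    return records
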