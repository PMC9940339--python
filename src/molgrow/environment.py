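"""Objective scoring: drug-likeness, synthetic accessibility, affinity.

Descriptors are 2048-bit ECFP6 fingerprints (Morgan radius 3) followed by
19 physicochemical descriptors in a fixed order.  The affinity objective is
a random-forest regression over these descriptors, predicting pX; a
molecule is "desired" when its predicted pX reaches the activity threshold
(6.5, about 316 nM).  QED and a synthetic-accessibility score are computed
per molecule; SA is reported for inspection and never optimized.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import QED, Crippen, Descriptors, rdMolDescriptors
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .chem_io import MoleculeRecord

logger = logging.getLogger("molgrow")

ACTIVITY_THRESHOLD = 6.5
N_FP_BITS = 2048
FP_RADIUS = 3  # ECFP6

#: The 19 physicochemical descriptors, in fixed order.
PHYSCHEM = (
    ("mw", Descriptors.MolWt),
    ("logp", Crippen.MolLogP),
    ("hba", rdMolDescriptors.CalcNumHBA),
    ("hbd", rdMolDescriptors.CalcNumHBD),
    ("rotatable_bonds", rdMolDescriptors.CalcNumRotatableBonds),
    ("amide_bonds", rdMolDescriptors.CalcNumAmideBonds),
    ("bridgehead_atoms", rdMolDescriptors.CalcNumBridgeheadAtoms),
    ("heteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
    ("spiro_atoms", rdMolDescriptors.CalcNumSpiroAtoms),
    ("heavy_atoms", lambda m: m.GetNumHeavyAtoms()),
    ("fraction_csp3", rdMolDescriptors.CalcFractionCSP3),
    ("aliphatic_rings", rdMolDescriptors.CalcNumAliphaticRings),
    ("saturated_rings", rdMolDescriptors.CalcNumSaturatedRings),
    ("total_rings", rdMolDescriptors.CalcNumRings),
    ("aromatic_rings", rdMolDescriptors.CalcNumAromaticRings),
    ("heterocycles", rdMolDescriptors.CalcNumHeterocycles),
    ("valence_electrons", Descriptors.NumValenceElectrons),
    ("tpsa", rdMolDescriptors.CalcTPSA),
    ("molar_refractivity", Crippen.MolMR),
)

DESCRIPTOR_LENGTH = N_FP_BITS + len(PHYSCHEM)  # 2067


class DescriptorError(ValueError):
    pass


def ecfp6_fingerprint(mol: Chem.Mol) -> np.ndarray:
    from rdkit.Chem import AllChem

    fp = AllChem.GetMorganFingerprintAsBitVect(mol, FP_RADIUS, nBits=N_FP_BITS)
    arr = np.zeros(N_FP_BITS, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def ecfp6_bitset(smiles: str) -> frozenset:
    """ECFP6 on-bit set of a SMILES, for Tanimoto arithmetic."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DescriptorError(f"unparsable SMILES {smiles!r}")
    from rdkit.Chem import AllChem

    fp = AllChem.GetMorganFingerprintAsBitVect(mol, FP_RADIUS, nBits=N_FP_BITS)
    return frozenset(fp.GetOnBits())


def compute_descriptors(mol: MoleculeRecord | Chem.Mol) -> np.ndarray:
    """2048 ECFP6 bits + 19 PhysChem values as one length-2067 vector."""
    rdmol = mol if isinstance(mol, Chem.Mol) else mol.mol()
    vec = np.empty(DESCRIPTOR_LENGTH, dtype=np.float64)
    vec[:N_FP_BITS] = ecfp6_fingerprint(rdmol)
    for i, (name, fn) in enumerate(PHYSCHEM):
        try:
            vec[N_FP_BITS + i] = float(fn(rdmol))
        except Exception as exc:
            raise DescriptorError(f"descriptor {name!r} failed: {exc}") from exc
    if not np.isfinite(vec).all():
        bad = PHYSCHEM[int(np.flatnonzero(~np.isfinite(vec[N_FP_BITS:]))[0])][0]
        raise DescriptorError(f"descriptor {bad!r} is non-finite")
    return vec


def sa_score(mol: Chem.Mol) -> float:
    """Lightweight synthetic-accessibility heuristic in [1, 10] (lower = easier).

    Combines size, ring complexity (bridgeheads, spiro centres, fused and
    large rings), stereocentre count and heteroatom load.  It is a simple
    in-package heuristic in the spirit of published fragment-based SA
    scores, intended for relative comparison of generated sets, and is
    reported only -- never used as an optimization objective.
    """
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy == 0:
        return 10.0
    ring_info = mol.GetRingInfo()
    ring_sizes = [len(r) for r in ring_info.AtomRings()]
    n_macro = sum(1 for s in ring_sizes if s > 8)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_stereo = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    size_penalty = n_heavy**1.005 - n_heavy
    ring_penalty = math.log10(n_bridge + 1) + math.log10(n_spiro + 1) + 2.0 * n_macro
    stereo_penalty = math.log10(n_stereo + 1)
    # atoms in more than one ring ~ fused-system complexity
    fused = sum(1 for a in mol.GetAtoms() if ring_info.NumAtomRings(a.GetIdx()) > 1)
    complexity = (
        0.05 * n_heavy
        + size_penalty
        + 2.5 * ring_penalty
        + 1.5 * stereo_penalty
        + 0.15 * fused
    )
    return float(min(10.0, max(1.0, 1.0 + complexity)))


@dataclass
class ObjectiveScores:
    """Per-molecule objective values plus the desirability flag."""

    smiles: str
    valid: bool
    qed: float
    sa: float
    affinity: float
    desired: bool


class AffinityModel(RegressorMixin, BaseEstimator):
    """Random-forest pX regressor over ECFP6 + PhysChem descriptors.

    Parameters
    ----------
    n_estimators : trees in the forest (default 500).
    random_state : seed for reproducible fits and predictions.
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: Sequence[MoleculeRecord], y=None):
        records = [r for r in X if r.pX is not None and np.isfinite(r.pX)]
        if len(records) < 25:
            raise ValueError(f"need >= 25 records with finite pX, got {len(records)}")
        targets = np.array([r.pX for r in records])
        if np.allclose(targets, targets[0]):
            raise ValueError("degenerate training table: constant pX")
        feats = np.stack([compute_descriptors(r) for r in records])
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(feats, targets)
        self.n_features_in_ = DESCRIPTOR_LENGTH
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        feats = np.stack(
            [
                x if isinstance(x, np.ndarray) else compute_descriptors(x)
                for x in X
            ]
        )
        return self.model_.predict(feats)

    def predict_smiles(self, smiles_list) -> np.ndarray:
        return self.predict([MoleculeRecord(s) for s in smiles_list])


def train_affinity_model(
    records: Sequence[MoleculeRecord], n_estimators: int = 500, seed: int = 0
) -> AffinityModel:
    return AffinityModel(n_estimators=n_estimators, random_state=seed).fit(records)


@dataclass
class Environment:
    """Scoring environment for generated populations.

    ``objectives`` lists the active reward objectives ("affinity" and
    optionally "qed"); the desired flag always follows the affinity
    threshold, with an optional additional QED cutoff (off by default).
    """

    model: Optional[AffinityModel] = None
    objectives: tuple[str, ...] = ("affinity",)
    threshold: float = ACTIVITY_THRESHOLD
    qed_cutoff: Optional[float] = None

    def __post_init__(self):
        if "affinity" in self.objectives and self.model is None:
            raise ValueError("affinity objective requires a trained model")

    def score_population(self, smiles_list: Sequence[str]) -> pd.DataFrame:
        """Score every molecule; invalid SMILES get worst-case scores."""
        rows = []
        mols = []
        for s in smiles_list:
            mol = Chem.MolFromSmiles(s) if s else None
            mols.append(mol)
        valid_idx = [i for i, m in enumerate(mols) if m is not None]
        affinities = np.zeros(len(mols))
        if self.model is not None and valid_idx:
            affinities[valid_idx] = self.model.predict(
                [compute_descriptors(mols[i]) for i in valid_idx]
            )
        for i, (s, mol) in enumerate(zip(smiles_list, mols)):
            if mol is None:
                rows.append(
                    ObjectiveScores(
                        smiles=s, valid=False, qed=0.0, sa=10.0,
                        affinity=0.0, desired=False,
                    )
                )
                continue
            qed = float(QED.qed(mol))
            desired = bool(affinities[i] >= self.threshold)
            if self.qed_cutoff is not None:
                desired = desired and qed >= self.qed_cutoff
            rows.append(
                ObjectiveScores(
                    smiles=s, valid=True, qed=qed, sa=sa_score(mol),
                    affinity=float(affinities[i]), desired=desired,
                )
            )
        return pd.DataFrame([vars(r) for r in rows])

    def objective_matrix(self, scored: pd.DataFrame) -> np.ndarray:
        """N x n_objectives matrix (larger is better) for Pareto ranking."""
        cols = []
        for name in self.objectives:
            if name == "affinity":
                cols.append(scored["affinity"].to_numpy())
            elif name == "qed":
                cols.append(scored["qed"].to_numpy())
            else:
                raise ValueError(f"unknown objective {name!r}")
        return np.stack(cols, axis=1)


def score_population(
    mols: Sequence[str], objectives=("affinity",), model: AffinityModel | None = None,
    threshold: float = ACTIVITY_THRESHOLD, qed_cutoff: float | None = None,
) -> pd.DataFrame:
    env = Environment(
        model=model, objectives=tuple(objectives),
        threshold=threshold, qed_cutoff=qed_cutoff,
    )
    return env.score_population(mols)
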