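"""Molecule table I/O and structure standardization.

Tables are tab-separated text with a header row.  Standardization follows
the usual preprocessing for generative-model corpora: keep the largest
organic component of multi-component structures, reject molecules whose
largest component contains a metal (any element outside the organic subset),
neutralize charges where chemically possible, and emit canonical SMILES.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("molgrow")

#: Elements allowed in the largest kept component ("organic subset").
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


class InputError(ValueError):
    """Raised for unusable input data (e.g. a table with zero parsable rows)."""


class ConfigError(ValueError):
    """Raised for invalid configuration (e.g. a missing column name)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with an optional activity annotation.

    ``pX`` is a pChEMBL-style potency, -log10 of a molar Ki/Kd/IC50/EC50;
    6.5 corresponds to roughly 316 nM.
    """

    smiles: str
    id: str = ""
    pX: Optional[float] = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise InputError(f"unparsable SMILES: {self.smiles!r}")
        return m


class StandardizationError(ValueError):
    pass


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Return the standardized record, or raise :class:`StandardizationError`.

    Rules: split multi-component structures and keep the largest component
    by heavy-atom count; reject if that component contains a non-organic
    element; neutralize charges (quaternary centres that cannot be
    neutralized are kept charged and logged); canonicalize.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise StandardizationError(f"unparsable SMILES: {record.smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    largest = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    for atom in largest.GetAtoms():
        if atom.GetSymbol() not in ORGANIC_ELEMENTS:
            raise StandardizationError(
                f"metal or non-organic element {atom.GetSymbol()!r} "
                f"in largest component of {record.smiles!r}"
            )
    Chem.SanitizeMol(largest)
    neutral = _UNCHARGER.uncharge(largest)
    if Chem.GetFormalCharge(neutral) != 0:
        logger.debug("could not fully neutralize %s", record.smiles)
    smiles = Chem.MolToSmiles(neutral)
    return MoleculeRecord(smiles=smiles, id=record.id, pX=record.pX)


def read_smiles_table(
    path,
    smiles_col: str = "smiles",
    activity_col: Optional[str] = None,
    id_col: Optional[str] = None,
    sep: str = "\t",
) -> list[MoleculeRecord]:
    """Read a delimited molecule table into standardized records.

    Unparsable SMILES are skipped (counted in the log); duplicate structures
    carrying several activity values are collapsed to one record with the
    mean pX.
    """
    df = pd.read_csv(path, sep=sep)
    if smiles_col not in df.columns:
        raise ConfigError(f"column {smiles_col!r} not found in {path}")
    if activity_col is not None and activity_col not in df.columns:
        raise ConfigError(f"column {activity_col!r} not found in {path}")
    if id_col is not None and id_col not in df.columns:
        raise ConfigError(f"column {id_col!r} not found in {path}")

    records, skipped = [], 0
    for i, row in df.iterrows():
        raw = MoleculeRecord(
            smiles=str(row[smiles_col]),
            id=str(row[id_col]) if id_col else str(i),
            pX=float(row[activity_col])
            if activity_col is not None and pd.notna(row[activity_col])
            else None,
        )
        try:
            records.append(standardize(raw))
        except StandardizationError:
            skipped += 1
    if skipped:
        logger.info("read_smiles_table: skipped %d unparsable/rejected rows", skipped)
    if not records:
        raise InputError(f"no parsable molecules in {path}")

    # collapse duplicate structures; average their activities
    by_smiles: dict[str, list[MoleculeRecord]] = {}
    for r in records:
        by_smiles.setdefault(r.smiles, []).append(r)
    out = []
    for smiles, group in by_smiles.items():
        px_vals = [r.pX for r in group if r.pX is not None]
        out.append(
            MoleculeRecord(
                smiles=smiles,
                id=group[0].id,
                pX=sum(px_vals) / len(px_vals) if px_vals else None,
            )
        )
    return out


def write_smiles_table(records, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "id": [r.id for r in records],
            "pX": [r.pX for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)
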