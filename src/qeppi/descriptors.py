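"""Physicochemical descriptors underlying the QEPPI score and the rule-of-four.

Seven properties enter the desirability model — exact molecular weight (MW),
Wildman–Crippen logP (ALogP), hydrogen-bond donor and acceptor counts
(HBD, HBA), topological polar surface area (TPSA), rotatable-bond count
(ROTB) and aromatic-ring count (AROM). The total ring count (RING) is
computed alongside because the rule-of-four needs it; it never enters the
desirability model.

All values are delegated to RDKit's descriptor implementations so that a
canonical structure always maps to the same property vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

#: Canonical ordering of the modeled properties. Every weight vector,
#: desirability tuple and property matrix in this package follows it.
PROPERTY_NAMES: tuple[str, ...] = ("MW", "ALogP", "HBD", "HBA", "TPSA", "ROTB", "AROM")

#: Properties that take nonnegative integer values (unit-width histogram bins).
INTEGER_PROPERTIES: frozenset[str] = frozenset({"HBD", "HBA", "ROTB", "AROM"})


@dataclass(frozen=True)
class PropertyVector:
    """The seven modeled descriptors plus ring count for one molecule.

    ``mw`` is the exact (monoisotopic) molecular weight in Da; ``tpsa`` is in
    Å²; the remaining fields are dimensionless. ``ring`` counts SSSR rings and
    is used only by the rule-of-four.
    """

    mw: float
    alogp: float
    hbd: int
    hba: int
    tpsa: float
    rotb: int
    arom: int
    ring: int

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"molecular weight must be positive, got {self.mw}")
        if self.tpsa < 0:
            raise ValueError(f"TPSA must be nonnegative, got {self.tpsa}")
        for name in ("hbd", "hba", "rotb", "arom", "ring"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.arom > self.ring:
            raise ValueError("aromatic ring count cannot exceed total ring count")

    def as_array(self) -> np.ndarray:
        """The seven modeled properties in canonical order (RING excluded)."""
        return np.array(
            [self.mw, self.alogp, self.hbd, self.hba, self.tpsa, self.rotb, self.arom],
            dtype=float,
        )


def compute_properties(mol: Chem.Mol) -> PropertyVector:
    """Compute the descriptor vector for a sanitized RDKit molecule.

    Deterministic for a given canonical structure: every field comes from an
    RDKit descriptor call with default settings (exact molecular weight,
    Wildman–Crippen logP, default HBD/HBA definitions, non-strict rotatable
    bonds, SSSR ring count).

    Raises
    ------
    ValueError
        If ``mol`` is None or a descriptor cannot be computed.
    """
    if mol is None:
        raise ValueError("cannot compute properties of a null molecule")
    try:
        return PropertyVector(
            mw=rdMolDescriptors.CalcExactMolWt(mol),
            alogp=Crippen.MolLogP(mol),
            hbd=rdMolDescriptors.CalcNumHBD(mol),
            hba=rdMolDescriptors.CalcNumHBA(mol),
            tpsa=rdMolDescriptors.CalcTPSA(mol),
            rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
            arom=rdMolDescriptors.CalcNumAromaticRings(mol),
            ring=rdMolDescriptors.CalcNumRings(mol),
        )
    except Exception as exc:  # descriptor failure on exotic elements
        raise ValueError(f"descriptor computation failed: {exc}") from exc


def compute_properties_from_smiles(smiles: str) -> PropertyVector:
    """Parse a SMILES string and compute its descriptor vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return compute_properties(mol)


def property_matrix(vectors: Iterable[PropertyVector]) -> np.ndarray:
    """Stack property vectors into an (n, 7) matrix in canonical order."""
    rows = [pv.as_array() for pv in vectors]
    if not rows:
        return np.empty((0, len(PROPERTY_NAMES)))
    return np.vstack(rows)
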