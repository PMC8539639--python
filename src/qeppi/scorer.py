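"""QEPPI scoring, the rule-of-four classifier, and comparison QED scores.

The QEPPI score of a compound is the weighted geometric mean of seven
normalized desirability values,

    score = exp( sum_i w_i ln d_i(x_i) / sum_i w_i ),

evaluated in the log domain. The rule-of-four (RO4) is the rule-based
PPI-inhibitor filter it generalizes: MW > 400, ALogP > 4, HBA > 4 and ring
count > 4, judged by the number of violated criteria. QED — the analogous
index fitted to oral drugs — is consumed from RDKit's published
parameterization for comparison, never refit here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import QED

from .ads import ADSParams, DEFAULT_EPS, DesirabilityFunction, fit_desirability
from .descriptors import PROPERTY_NAMES, PropertyVector, compute_properties
from .weights import DEFAULT_TOP_K, select_weights

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: RO4 thresholds, all strict ("higher than"): boundary values violate.
RO4_THRESHOLDS = {"MW": 400.0, "ALogP": 4.0, "HBA": 4.0, "RING": 4.0}


def weighted_geometric_mean(desirabilities: Sequence[float], weights: Sequence[float]) -> float:
    """exp(sum w ln d / sum w) for d in (0, 1], weights nonnegative with
    positive sum. Invariant to rescaling all weights by a positive constant."""
    d = np.asarray(desirabilities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(d <= 0):
        raise ValueError("desirabilities must be strictly positive")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    return float(np.exp(np.dot(w, np.log(d)) / w.sum()))


@dataclass
class QEPPIModel:
    """The scoring artifact: seven desirability functions plus their weights.

    ``desirabilities`` follows the canonical property order (MW, ALogP, HBD,
    HBA, TPSA, ROTB, AROM). ``metadata`` records fit provenance (dataset
    name, bin widths, eps floor, compound count).
    """

    desirabilities: tuple[DesirabilityFunction, ...]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.desirabilities) != len(PROPERTY_NAMES):
            raise ValueError(f"expected {len(PROPERTY_NAMES)} desirability functions")
        for fn, name in zip(self.desirabilities, PROPERTY_NAMES):
            if fn.property != name:
                raise ValueError(f"desirability order mismatch: {fn.property} != {name}")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(PROPERTY_NAMES),):
            raise ValueError("need exactly seven weights")
        if self.weights.sum() <= 0:
            raise ValueError("weight sum must be positive")

    @property
    def peaks(self) -> np.ndarray:
        return np.array([fn.peak for fn in self.desirabilities])

    def desirability_values(self, pv: PropertyVector) -> np.ndarray:
        x = pv.as_array()
        return np.array([fn(xi) for fn, xi in zip(self.desirabilities, x)])

    def score(self, pv: PropertyVector) -> float:
        return weighted_geometric_mean(self.desirability_values(pv), self.weights)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "descriptor_convention": {
                "mw": "exact (monoisotopic) molecular weight",
                "alogp": "Wildman-Crippen",
                "toolkit": "rdkit-default-descriptors",
            },
            "properties": {
                fn.property: {
                    "a": fn.params.a, "b": fn.params.b, "c": fn.params.c,
                    "d": fn.params.d, "e": fn.params.e, "f": fn.params.f,
                    "q_max": fn.q_max, "peak": fn.peak,
                    "domain": list(fn.domain), "eps": fn.eps,
                }
                for fn in self.desirabilities
            },
            "weights": {name: w for name, w in zip(PROPERTY_NAMES, self.weights.tolist())},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "QEPPIModel":
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
        fns = []
        for name in PROPERTY_NAMES:
            block = doc["properties"][name]
            fns.append(
                DesirabilityFunction(
                    property=name,
                    params=ADSParams(
                        a=block["a"], b=block["b"], c=block["c"],
                        d=block["d"], e=block["e"], f=block["f"],
                    ),
                    q_max=block["q_max"],
                    peak=block["peak"],
                    domain=tuple(block["domain"]),
                    eps=block.get("eps", DEFAULT_EPS),
                )
            )
        weights = np.array([doc["weights"][name] for name in PROPERTY_NAMES])
        return cls(desirabilities=tuple(fns), weights=weights, metadata=doc.get("metadata", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "QEPPIModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def qeppi_score(model: QEPPIModel, pv: PropertyVector) -> float:
    """The QEPPI score of one compound; always in (0, 1]."""
    return model.score(pv)


def build_model(
    property_vectors: Sequence[PropertyVector],
    bin_widths: dict[str, float] | None = None,
    eps: float = DEFAULT_EPS,
    top_k: int = DEFAULT_TOP_K,
    seed: int = 0,
    metadata: dict | None = None,
) -> QEPPIModel:
    """Fit the full scoring model from a modeling set's property vectors.

    Pipeline: per-property histogram -> ADS fit -> normalization to a
    desirability function, then the exhaustive entropy-maximizing weight
    search over the resulting per-compound desirability matrix.
    """
    matrix = np.vstack([pv.as_array() for pv in property_vectors])
    fns = tuple(
        fit_desirability(matrix[:, i], name, bin_widths=bin_widths, eps=eps, seed=seed)
        for i, name in enumerate(PROPERTY_NAMES)
    )
    d_matrix = np.column_stack(
        [fns[i](matrix[:, i]) for i in range(len(PROPERTY_NAMES))]
    )
    result = select_weights(d_matrix, top_k=top_k)
    meta = {
        "n_compounds": len(property_vectors),
        "top_k": top_k,
        "eps": eps,
        "bin_widths": dict(bin_widths) if bin_widths else {},
        "seed": seed,
    }
    if metadata:
        meta.update(metadata)
    logger.info(
        "model fitted on %d compounds; peaks=%s weights=%s",
        len(property_vectors),
        np.round([fn.peak for fn in fns], 3).tolist(),
        np.round(result.final, 3).tolist(),
    )
    return QEPPIModel(desirabilities=fns, weights=result.final, metadata=meta)


# -- rule-of-four ----------------------------------------------------------


def ro4_violations(pv: PropertyVector) -> int:
    """Number of RO4 criteria (MW > 400, ALogP > 4, HBA > 4, RING > 4) the
    compound does NOT satisfy; strict inequalities, so boundary values count
    as violations."""
    checks = (
        pv.mw > RO4_THRESHOLDS["MW"],
        pv.alogp > RO4_THRESHOLDS["ALogP"],
        pv.hba > RO4_THRESHOLDS["HBA"],
        pv.ring > RO4_THRESHOLDS["RING"],
    )
    return sum(1 for ok in checks if not ok)


def ro4_pass(pv: PropertyVector, allowed_violations: int = 1) -> bool:
    """True iff the compound violates at most ``allowed_violations`` of the
    four criteria (the customary filter allows one)."""
    if allowed_violations not in range(5):
        raise ValueError("allowed_violations must be in 0..4")
    return ro4_violations(pv) <= allowed_violations


# -- QED comparison scores -------------------------------------------------


def qed_score(mol: Chem.Mol) -> float:
    """QED of a molecule from RDKit's published parameterization (includes
    the structural-alerts term); in (0, 1]."""
    if mol is None:
        raise ValueError("cannot score a null molecule")
    return float(QED.qed(mol))


def qed_inv(mol: Chem.Mol) -> float:
    """1 - QED: because oral-drug likeness and PPI-modulator likeness trend
    oppositely, the inverted QED is the natural QED-based baseline."""
    return 1.0 - qed_score(mol)


# -- batch reports ---------------------------------------------------------


@dataclass
class ScoreReport:
    """Full per-compound scoring output."""

    id: str
    qeppi: float
    per_property: tuple[tuple[float, float], ...]  # (x_i, d_i(x_i)) pairs
    ro4_violations: int
    qed: float | None = None

    @property
    def qed_inv(self) -> float | None:
        return None if self.qed is None else 1.0 - self.qed


def score_molecule(model: QEPPIModel, mol: Chem.Mol, mol_id: str = "") -> ScoreReport:
    """Score one sanitized molecule: QEPPI, per-property desirabilities,
    RO4 violations and QED."""
    pv = compute_properties(mol)
    d = model.desirability_values(pv)
    x = pv.as_array()
    try:
        qed = qed_score(mol)
    except Exception:
        logger.warning("QED failed for %s", mol_id)
        qed = None
    return ScoreReport(
        id=mol_id,
        qeppi=weighted_geometric_mean(d, model.weights),
        per_property=tuple(zip(x.tolist(), d.tolist())),
        ro4_violations=ro4_violations(pv),
        qed=qed,
    )


def score_many(
    model: QEPPIModel, mols: Iterable[tuple[str, Chem.Mol]]
) -> list[ScoreReport]:
    return [score_molecule(model, mol, mol_id) for mol_id, mol in mols]
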