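"""Synthetic inputs with the statistical structure the scoring method
assumes, so fitting, weight search, scoring and evaluation are testable
without any external compound download.

Three generators are provided:

* property vectors drawn from right-skewed unimodal distributions with
  chosen modes — a "PPI-modulator-like" population, and a shifted
  "oral-drug-like" population for separation experiments;
* histograms sampled around a known ADS curve (Poisson counts), the
  parameter-recovery harness for the fitting code;
* a small packaged SMILES collection covering salts, duplicate spellings
  and acyclic molecules for curation tests.

These fixtures validate mechanics, not chemistry: property vectors are
drawn independently per property, so cross-property correlations of real
compound collections are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ads import ADSParams, PropertyHistogram, ads_value
from .chem_io import CompoundRecord, CompoundSet
from .descriptors import INTEGER_PROPERTIES, PROPERTY_NAMES, PropertyVector

#: Default property modes of the positive population: the characteristic
#: values of PPI-modulator collections (large, lipophilic, acceptor-rich).
PPI_LIKE_PEAKS: tuple[float, ...] = (492.7, 4.78, 1.61, 4.79, 76.9, 6.37, 2.8)

#: Log-scale spreads (lognormal shape parameters) per property.
DEFAULT_SPREADS: tuple[float, ...] = (0.35, 0.35, 0.55, 0.35, 0.45, 0.45, 0.40)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the two-population property-vector generator.

    ``peaks`` are the target modes of the positive population; the negative
    ("oral-drug-like") population has its modes scaled down by the fraction
    ``shift`` (shift 0 makes the populations identical in distribution).
    """

    n_compounds: int = 1000
    peaks: tuple[float, ...] = PPI_LIKE_PEAKS
    spreads: tuple[float, ...] = DEFAULT_SPREADS
    shift: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 50:
            raise ValueError("n_compounds must be >= 50")
        if len(self.peaks) != len(PROPERTY_NAMES) or len(self.spreads) != len(PROPERTY_NAMES):
            raise ValueError(f"peaks and spreads must have length {len(PROPERTY_NAMES)}")
        if any(s <= 0 for s in self.spreads):
            raise ValueError("spreads must be positive")
        if any(p <= 0 for p in self.peaks):
            raise ValueError("peaks must be positive (lognormal sampler)")
        if not 0 <= self.shift < 1:
            raise ValueError("shift must be in [0, 1)")


def _sample_property(rng: np.random.Generator, mode: float, sigma: float, n: int) -> np.ndarray:
    # lognormal with the requested mode: mode = exp(mu - sigma^2)
    mu = np.log(mode) + sigma**2
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def generate_property_vectors(
    spec: FixtureSpec, population: str = "positive"
) -> list[PropertyVector]:
    """Draw ``n_compounds`` property vectors from right-skewed (lognormal)
    unimodal distributions with the spec's modes.

    ``population='negative'`` scales every mode by (1 - shift), emulating an
    oral-drug-like collection. Integer properties are rounded to the nearest
    nonnegative integer; the total ring count is the aromatic-ring count
    plus an independent Poisson-distributed number of aliphatic rings.
    Deterministic for a fixed spec.
    """
    if population not in ("positive", "negative"):
        raise ValueError("population must be 'positive' or 'negative'")
    offset = 0 if population == "positive" else 1
    rng = np.random.default_rng((spec.seed, offset))
    factor = 1.0 if population == "positive" else 1.0 - spec.shift
    cols = {}
    for name, mode, sigma in zip(PROPERTY_NAMES, spec.peaks, spec.spreads):
        vals = _sample_property(rng, mode * factor, sigma, spec.n_compounds)
        if name in INTEGER_PROPERTIES:
            vals = np.rint(vals).astype(int)
        cols[name] = vals
    extra_rings = rng.poisson(1.0, size=spec.n_compounds)
    out = []
    for k in range(spec.n_compounds):
        arom = int(cols["AROM"][k])
        out.append(
            PropertyVector(
                mw=float(cols["MW"][k]),
                alogp=float(cols["ALogP"][k]),
                hbd=int(cols["HBD"][k]),
                hba=int(cols["HBA"][k]),
                tpsa=float(cols["TPSA"][k]),
                rotb=int(cols["ROTB"][k]),
                arom=arom,
                ring=arom + int(extra_rings[k]),
            )
        )
    return out


def generate_ads_histogram(
    params: ADSParams,
    total_count: int,
    seed: int = 0,
    property: str = "MW",
    n_bins: int = 40,
    noise: str = "poisson",
) -> PropertyHistogram:
    """Sample a histogram around a known ADS curve — the parameter-recovery
    harness for the fitting code.

    Bin centers span the curve's support (center +/- separation plus eight
    slope scales on each side). Expected counts are the ADS curve clipped at
    zero and scaled to sum to ``total_count``; ``noise='poisson'`` draws
    Poisson counts around them, ``noise='none'`` returns the expectations.
    """
    if total_count < 500:
        raise ValueError("total_count must be >= 500 for a meaningful recovery test")
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    lo = params.c - abs(params.d) / 2 - 8 * params.e
    hi = params.c + abs(params.d) / 2 + 8 * params.f
    centers = np.linspace(lo, hi, n_bins)
    expected = np.clip(ads_value(params, centers), 0.0, None)
    if expected.sum() <= 0:
        raise ValueError("ADS curve has no positive mass on the sampling range")
    expected = expected * (total_count / expected.sum())
    if noise == "poisson":
        counts = np.random.default_rng(seed).poisson(expected).astype(float)
    else:
        counts = expected
    return PropertyHistogram(property=property, bin_centers=centers, counts=counts)


#: ~50 diverse, valid structures (id, SMILES, synthetic pActivity) for
#: end-to-end curation and descriptor tests: aromatics, heterocycles,
#: acyclic molecules, salt forms, and one duplicate-spelling pair
#: (ethanol / ethanol-alt). Activities are fabricated.
_FIXTURE_SMILES: tuple[tuple[str, str, float | None], ...] = (
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", 5.2),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 4.1),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 5.8),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", 4.9),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O", 6.0),
    ("benzene", "c1ccccc1", 3.0),
    ("toluene", "Cc1ccccc1", 3.1),
    ("ethylbenzene", "CCc1ccccc1", 3.2),
    ("cyclohexane", "C1CCCCC1", 2.5),
    ("naphthalene", "c1ccc2ccccc2c1", 3.6),
    ("anthracene", "c1ccc2cc3ccccc3cc2c1", 3.9),
    ("pyridine", "c1ccncc1", 3.3),
    ("quinoline", "c1ccc2ncccc2c1", 4.0),
    ("indole", "c1ccc2[nH]ccc2c1", 4.2),
    ("imidazole", "c1c[nH]cn1", 3.4),
    ("ethanol", "CCO", 1.5),
    ("ethanol-alt", "OCC", 1.6),  # duplicate spelling of ethanol
    ("hexane", "CCCCCC", 1.2),
    ("octanol", "CCCCCCCCO", 2.0),
    ("glycerol", "OCC(O)CO", 1.1),
    ("acetate-sodium", "[Na+].CC(=O)[O-]", 1.8),  # salt form
    ("amine-hcl", "Cl.NCCc1ccccc1", 4.4),  # hydrochloride salt
    ("choline-chloride", "[Cl-].C[N+](C)(C)CCO", 1.9),
    ("benzamidine", "NC(=N)c1ccccc1", 4.6),
    ("sulfanilamide", "Nc1ccc(cc1)S(N)(=O)=O", 4.3),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O", 6.3),
    ("diazepam", "CN1c2ccc(Cl)cc2C(=Nc3ccccc13)c1ccccc1", 7.1),
    ("haloperidol", "OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1", 7.4),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21", 7.0),
    ("imatinib", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1", 8.2),
    ("nutlin-like", "COc1ccc(cc1)C1=NC(c2ccc(Cl)cc2)C(N1C(=O)N1CCNC(=O)C1)c1ccc(Cl)cc1", 8.6),
    ("biphenyl", "c1ccc(cc1)-c2ccccc2", 3.7),
    ("terphenyl", "c1ccc(cc1)-c1ccc(cc1)-c1ccccc1", 4.5),
    ("stilbene", "C(=C/c1ccccc1)\\c1ccccc1", 4.8),
    ("benzophenone", "O=C(c1ccccc1)c1ccccc1", 4.0),
    ("dibenzofuran", "c1ccc2c(c1)oc1ccccc12", 4.1),
    ("carbazole", "c1ccc2c(c1)[nH]c1ccccc12", 4.7),
    ("fluorene", "C1c2ccccc2-c2ccccc21", 4.2),
    ("adamantane", "C1C2CC3CC1CC(C2)C3", 2.8),
    ("camphor", "CC1(C)C2CCC1(C)C(=O)C2", 2.9),
    ("menthol", "CC(C)C1CCC(C)CC1O", 2.6),
    ("citral", "CC(C)=CCCC(C)=CC=O", 2.2),
    ("urea", "NC(N)=O", 0.8),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O", 1.0),
    ("taurine", "NCCS(=O)(=O)O", 1.3),
    ("piperidine", "C1CCNCC1", 2.4),
    ("morpholine", "C1COCCN1", 2.1),
    ("proline", "OC(=O)C1CCCN1", 1.7),
    ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O", 2.3),
    ("no-activity", "c1ccc(cc1)C(=O)N", None),
)


def fixture_smiles_set() -> CompoundSet:
    """The packaged ~50-compound SMILES collection with fabricated ids and
    activities, spanning acyclic, aromatic, salt-containing and
    duplicate-spelling cases."""
    records = [
        CompoundRecord(id=cid, smiles=smi, activity=act, tags={"fixture"})
        for cid, smi, act in _FIXTURE_SMILES
    ]
    return CompoundSet(records=records, name="fixture")


#: Polar tail fragments for the combinatorial SMILES generator; linear
#: concatenation of any of these onto a carbon skeleton stays valid SMILES.
_TAIL_FRAGMENTS: tuple[str, ...] = (
    "", "O", "N", "CO", "OC", "C(=O)O", "C(=O)N", "N(C)C",
    "S(=O)(=O)N", "C(=O)OC", "OCCO", "NCCN", "C(=O)NCCO", "Oc1ccccc1",
)


def synthetic_modeling_smiles(n: int = 300, seed: int = 0) -> CompoundSet:
    """A combinatorial collection of valid structures broad enough to fit a
    full scoring model: alkyl chains x 0-6 linked phenyl rings x hydroxyl
    runs x a polar tail, sampled deterministically.

    Unlike :func:`fixture_smiles_set` (50 hand-picked molecules for curation
    tests), this set covers enough distinct values of every property — up to
    seven aromatic rings, donors/acceptors to ~6, molecular weights to
    ~700 Da — that each property histogram has the >= 6 populated bins the
    ADS fit requires. Chemistry here is unremarkable on purpose; the set
    exercises mechanics.
    """
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    while len(records) < n:
        alkyl = int(rng.integers(0, 11))
        phenyls = int(rng.integers(0, 7))
        hydroxyls = int(rng.integers(0, 4))
        tail = _TAIL_FRAGMENTS[int(rng.integers(0, len(_TAIL_FRAGMENTS)))]
        smiles = "C" * alkyl + "c1ccccc1" * phenyls + "C(O)" * hydroxyls + tail
        if not smiles or smiles in seen:
            continue
        seen.add(smiles)
        if Chem.MolFromSmiles(smiles) is None:  # defensive; fragments compose validly
            continue
        records.append(
            CompoundRecord(
                id=f"syn{len(records):04d}",
                smiles=smiles,
                activity=float(np.round(rng.normal(6.0, 1.0), 2)),
                tags={"synthetic"},
            )
        )
    return CompoundSet(records=records, name="synthetic-modeling")


def write_fixture_files(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write fixture artifacts for CLI use: a SMILES file of the packaged
    collection and positive/negative property CSVs drawn from ``spec``."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    smi_path = out_dir / "fixture_compounds.smi"
    lines = [f"{smi}\t{cid}" for cid, smi, _ in _FIXTURE_SMILES]
    smi_path.write_text("\n".join(lines) + "\n")
    paths["smiles"] = smi_path

    for population in ("positive", "negative"):
        pvs = generate_property_vectors(spec, population)
        df = pd.DataFrame(
            {
                "id": [f"{population}{k}" for k in range(len(pvs))],
                "MW": [pv.mw for pv in pvs],
                "ALogP": [pv.alogp for pv in pvs],
                "HBD": [pv.hbd for pv in pvs],
                "HBA": [pv.hba for pv in pvs],
                "TPSA": [pv.tpsa for pv in pvs],
                "ROTB": [pv.rotb for pv in pvs],
                "AROM": [pv.arom for pv in pvs],
                "RING": [pv.ring for pv in pvs],
            }
        )
        p = out_dir / f"{population}_properties.csv"
        df.to_csv(p, index=False)
        paths[population] = p
    return paths
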