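"""Screening-library preparation: parsing, physicochemical properties,
fragment-like filtering, fingerprints, novelty and leader clustering.

The library funnel mirrors a fragment-based virtual-screening campaign
against the melatonin receptors: keep small (MW <= 250 Da), moderately
lipophilic (logP 1-5), near-neutral (formal charge -1..+1) molecules and
discard reactive or pan-assay-interference (PAINS) chemotypes. Novelty of a
candidate is its Tanimoto distance (1 - similarity) to the nearest known
ligand; diversity picking uses greedy leader clustering on the same
distance with docking score as the ranking criterion.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
from rdkit.DataStructs import ExplicitBitVect

logger = logging.getLogger(__name__)

_FP_BITS = 2048  # per component; the combined fingerprint is 2 * _FP_BITS


@dataclass
class CompoundRecord:
    """One library molecule with computed properties and filter flags."""

    id: str
    smiles: str
    mol_weight: float | None = None       # Da, average mass
    logp_est: float | None = None         # Crippen atom-contribution estimate
    net_charge: int | None = None         # formal charge as written
    heavy_atoms: int | None = None
    pains_flag: bool | None = None
    reactive_flag: bool | None = None

    @property
    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"unparsable SMILES for {self.id}: {self.smiles!r}")
        return m


@dataclass
class FilterConfig:
    """Fragment-library bounds; all bounds are inclusive."""

    mw_max: float = 250.0
    logp_min: float = 1.0
    logp_max: float = 5.0
    charge_min: int = -1
    charge_max: int = 1
    pattern_set_id: str = "default"

    def __post_init__(self) -> None:
        if self.logp_min > self.logp_max or self.charge_min > self.charge_max:
            raise ValueError("filter mins must not exceed maxes")


@dataclass(frozen=True)
class NoveltyResult:
    compound_id: str
    nearest_reference: str
    tanimoto_distance: float


@dataclass(frozen=True)
class ClusterAssignment:
    compound_id: str
    cluster_id: int
    is_representative: bool


@dataclass
class ParsedLibrary:
    records: list[CompoundRecord]
    n_skipped: int
    skipped_lines: list[str] = field(default_factory=list)


def parse_smiles_library(path: str | Path) -> ParsedLibrary:
    """Read a .smi file (SMILES [whitespace id] per line).

    Unparsable lines are logged and skipped; the skip count is reported on
    the returned object. Raises on an empty file.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty SMILES file: {path}")
    records: list[CompoundRecord] = []
    skipped: list[str] = []
    for i, ln in enumerate(lines):
        parts = ln.split(None, 1)
        smi = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
        if Chem.MolFromSmiles(smi) is None:
            logger.warning("skipping unparsable SMILES at line %d: %s", i + 1, smi)
            skipped.append(ln)
            continue
        records.append(CompoundRecord(id=cid, smiles=smi))
    return ParsedLibrary(records=records, n_skipped=len(skipped), skipped_lines=skipped)


def _load_pains_catalog() -> FilterCatalog:
    params = FilterCatalogParams()
    for cat in (
        FilterCatalogParams.FilterCatalogs.PAINS_A,
        FilterCatalogParams.FilterCatalogs.PAINS_B,
        FilterCatalogParams.FilterCatalogs.PAINS_C,
    ):
        params.AddCatalog(cat)
    return FilterCatalog(params)


def load_reactive_patterns(path: str | Path | None = None) -> list[tuple[str, Chem.Mol]]:
    """Load the reactive-group SMARTS list (name, query) pairs."""
    if path is None:
        text = (resources.files("melapharm.data") / "reactive_patterns.smarts").read_text()
    else:
        text = Path(path).read_text()
    out = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        smarts, name = ln.split(None, 1)
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"bad SMARTS in reactive pattern list: {smarts}")
        out.append((name.strip(), q))
    return out


_PAINS = None
_REACTIVE = None


def _catalogs():
    global _PAINS, _REACTIVE
    if _PAINS is None:
        _PAINS = _load_pains_catalog()
        _REACTIVE = load_reactive_patterns()
    return _PAINS, _REACTIVE


def compute_properties(record: CompoundRecord) -> CompoundRecord:
    """Fill MW, logP, formal charge, heavy-atom count and both flags."""
    mol = record.mol
    pains, reactive = _catalogs()
    return replace(
        record,
        mol_weight=Descriptors.MolWt(mol),
        logp_est=Crippen.MolLogP(mol),
        net_charge=Chem.GetFormalCharge(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        pains_flag=pains.HasMatch(mol),
        reactive_flag=any(mol.HasSubstructMatch(q) for _, q in reactive),
    )


#: rule evaluation order; a rejection reports the FIRST failing rule
FILTER_RULE_ORDER = ("mw", "logp", "charge", "reactive", "pains")


def _first_failure(r: CompoundRecord, cfg: FilterConfig) -> str | None:
    if r.mol_weight > cfg.mw_max:
        return "mw"
    if not (cfg.logp_min <= r.logp_est <= cfg.logp_max):
        return "logp"
    if not (cfg.charge_min <= r.net_charge <= cfg.charge_max):
        return "charge"
    if r.reactive_flag:
        return "reactive"
    if r.pains_flag:
        return "pains"
    return None


def apply_filters(
    records: Iterable[CompoundRecord], cfg: FilterConfig | None = None
) -> tuple[list[CompoundRecord], list[tuple[CompoundRecord, str]]]:
    """Partition records into (kept, rejected-with-reason).

    All bounds are inclusive; a record is kept iff it satisfies every bound
    and both the PAINS and reactive flags are false. Rejections carry the
    first failing rule in :data:`FILTER_RULE_ORDER`.
    """
    cfg = cfg or FilterConfig()
    kept, rejected = [], []
    for r in records:
        if r.mol_weight is None:
            raise ValueError(f"properties not computed for {r.id}")
        reason = _first_failure(r, cfg)
        if reason is None:
            kept.append(r)
        else:
            rejected.append((r, reason))
    return kept, rejected


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_FP_BITS)
_LINEAR = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=_FP_BITS)


def fingerprint(record: CompoundRecord | Chem.Mol | str) -> ExplicitBitVect:
    """Combined circular + linear fingerprint (4096 bits).

    Concatenates a Morgan radius-2/2048 fingerprint with a 2048-bit RDKit
    path fingerprint, emulating screening tools that mix ECFP-like and
    linear fingerprints for similarity work. Canonicalization-stable.
    """
    if isinstance(record, CompoundRecord):
        mol = record.mol
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {record!r}")
    else:
        mol = record
    circ = _MORGAN.GetFingerprint(mol)
    lin = _LINEAR.GetFingerprint(mol)
    combined = ExplicitBitVect(2 * _FP_BITS)
    for b in circ.GetOnBits():
        combined.SetBit(b)
    for b in lin.GetOnBits():
        combined.SetBit(_FP_BITS + b)
    return combined


def tanimoto_distance(fp_a: ExplicitBitVect, fp_b: ExplicitBitVect) -> float:
    """1 - Tanimoto similarity; a bounded semimetric on [0, 1]."""
    return 1.0 - DataStructs.TanimotoSimilarity(fp_a, fp_b)


def nearest_reference_distance(
    record: CompoundRecord, reference_set: Sequence[CompoundRecord]
) -> NoveltyResult:
    """Novelty of ``record``: minimum Tanimoto distance to the references."""
    if not reference_set:
        raise ValueError("reference set is empty")
    fp = fingerprint(record)
    best_id, best_d = None, float("inf")
    for ref in reference_set:
        d = tanimoto_distance(fp, fingerprint(ref))
        if d < best_d:
            best_id, best_d = ref.id, d
    return NoveltyResult(record.id, best_id, best_d)


def cluster_leader(
    records: Sequence[CompoundRecord],
    distance_threshold: float,
    scores: dict[str, float] | None = None,
) -> list[ClusterAssignment]:
    """Greedy leader (Butina-style) clustering on Tanimoto distance.

    Compounds are processed in ascending docking-score order (best first;
    ties broken by lexical id). A compound joins the first existing leader
    within ``distance_threshold``, else founds a new cluster. Because the
    best-scoring member is always seen first, each leader is its cluster's
    representative.
    """
    if not (0.0 < distance_threshold < 1.0):
        raise ValueError("distance_threshold must be in (0, 1)")
    if scores is None or any(r.id not in scores for r in records):
        warnings.warn("missing docking scores; ranking clusters by input order")
        order = list(records)
    else:
        order = sorted(records, key=lambda r: (scores[r.id], r.id))
    fps = {r.id: fingerprint(r) for r in records}
    leaders: list[tuple[int, str]] = []  # (cluster_id, leader compound id)
    assignments: list[ClusterAssignment] = []
    for r in order:
        placed = False
        for cid, leader_id in leaders:
            if tanimoto_distance(fps[r.id], fps[leader_id]) <= distance_threshold:
                assignments.append(ClusterAssignment(r.id, cid, False))
                placed = True
                break
        if not placed:
            cid = len(leaders) + 1
            leaders.append((cid, r.id))
            assignments.append(ClusterAssignment(r.id, cid, True))
    return assignments
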