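"""Hit-summary metrics: ligand efficiency, subtype selectivity,
classification flags, hit counts, and assembly of summary tables.

Conventions follow the standard reporting of melatonin-receptor agonist
campaigns: ligand efficiency LE = 1.4 * pEC50 / heavy_atoms (kcal/mol per
non-hydrogen atom), subtype selectivity as the antilog of the difference of
log(Emax/EC50) between MT2 and MT1 (fold > 1 means MT2-preferring), and a
partial agonist is a compound whose Emax falls strictly below 70% of the
melatonin maximum.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ._util import Bound, parse_reported, round_half_away

REFERENCE_COMPOUND = "melatonin"


@dataclass
class MetricConfig:
    le_constant: float = 1.4          # kcal/mol per log10 unit (~2.303 RT at 310 K)
    partial_threshold: float = 70.0   # % of reference Emax, strict '<'
    submicromolar_threshold: float = 1000.0  # nM
    potent_threshold: float = 100.0   # nM
    ki_threshold: float = 10000.0     # nM (10 uM)

    def __post_init__(self) -> None:
        for name in ("le_constant", "partial_threshold",
                     "submicromolar_threshold", "potent_threshold", "ki_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ligand_efficiency(p_act: float, heavy_atoms: int,
                      le_constant: float = 1.4) -> float:
    """LE in kcal/mol per heavy atom from a p-scale potency or affinity.

    Unrounded; round only at reporting time.
    """
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    if p_act < 0:
        raise ValueError("p-scale activity must be non-negative")
    return le_constant * p_act / heavy_atoms


def selectivity_fold(ec50_mt1, emax_mt1, ec50_mt2, emax_mt2):
    """MT2-over-MT1 selectivity: antilog(log(Emax/EC50)_MT2 - log(Emax/EC50)_MT1).

    Equals (Emax2/EC502)/(Emax1/EC501). Censored inputs propagate as a
    :class:`Bound`: an EC50 lower bound at MT1 (weaker than X) caps the MT1
    potency ratio (Emax treated at its 100% ceiling when unreported) and
    yields a selectivity lower bound. Returns an unrounded float (or Bound);
    report at one decimal with halves away from zero.
    """
    def _clean(v):
        return None if (isinstance(v, float) and math.isnan(v)) else v

    ec50_mt1, emax_mt1 = _clean(ec50_mt1), _clean(emax_mt1)
    ec50_mt2, emax_mt2 = _clean(ec50_mt2), _clean(emax_mt2)
    censored_mt1 = isinstance(ec50_mt1, Bound) or emax_mt1 is None
    if censored_mt1:
        if not isinstance(ec50_mt1, Bound) or ec50_mt1.op != ">":
            raise ValueError("unsupported censoring pattern for MT1 block")
        emax1 = 100.0 if emax_mt1 is None else emax_mt1
        mt1_ratio_ub = emax1 / ec50_mt1.value
        return Bound(">", (emax_mt2 / ec50_mt2) / mt1_ratio_ub)
    for v in (ec50_mt1, emax_mt1, ec50_mt2, emax_mt2):
        if v is None or v <= 0:
            raise ValueError("EC50/Emax inputs must be positive")
    return (emax_mt2 / ec50_mt2) / (emax_mt1 / ec50_mt1)


def report_fold(fold, ndigits: int = 1):
    """Reporting-grade rounding of a selectivity fold (half away from zero)."""
    if isinstance(fold, Bound):
        return Bound(fold.op, round_half_away(fold.value, ndigits))
    return round_half_away(fold, ndigits)


def hit_rate(n_hits: int, n_tested: int) -> int:
    """Hit rate as a whole-number percent."""
    if n_tested <= 0:
        raise ZeroDivisionError("n_tested must be positive")
    if not (0 <= n_hits <= n_tested):
        raise ValueError("need 0 <= n_hits <= n_tested")
    return int(round_half_away(100.0 * n_hits / n_tested, 0))


def _lt(value, threshold: float) -> bool:
    """Strict '<' respecting censoring; a '>X' bound with X >= t is False."""
    if value is None:
        return False
    if isinstance(value, Bound):
        # '>X': true value exceeds X -> cannot assert < t unless impossible
        return False if value.op == ">" else value.value <= threshold
    return value < threshold


def _gt(value, threshold: float) -> bool:
    if value is None:
        return False
    if isinstance(value, Bound):
        return value.op == ">" and value.value >= threshold
    return value > threshold


def classify_hit(row: dict, cfg: MetricConfig | None = None) -> dict:
    """Per-receptor classification and any-receptor aggregate flags.

    ``row`` carries (possibly censored) ``mt1_EC50_nM``, ``mt1_Emax``,
    ``mt1_pKi`` and the MT2 equivalents. Flags: ``submicromolar`` /
    ``potent_lt_100nM`` (EC50 below threshold at >= 1 receptor),
    ``ki_lt_10uM`` (pKi above the 10 uM-equivalent at >= 1 receptor),
    ``partial_mt1`` / ``partial_mt2`` (Emax strictly below threshold).
    """
    cfg = cfg or MetricConfig()
    pki_floor = 9.0 - math.log10(cfg.ki_threshold)
    flags = {}
    for rec in ("mt1", "mt2"):
        ec50 = row.get(f"{rec}_EC50_nM")
        emax = row.get(f"{rec}_Emax")
        flags[f"submicromolar_{rec}"] = _lt(ec50, cfg.submicromolar_threshold)
        flags[f"potent_{rec}"] = _lt(ec50, cfg.potent_threshold)
        flags[f"partial_{rec}"] = emax is not None and not isinstance(emax, Bound) \
            and emax < cfg.partial_threshold
        flags[f"ki_ok_{rec}"] = _gt(row.get(f"{rec}_pKi"), pki_floor)
        if ec50 is None:
            cls = "inactive"
        elif flags[f"partial_{rec}"]:
            cls = "partial"
        else:
            cls = "full"
        flags[f"classification_{rec}"] = cls
    flags["submicromolar"] = flags["submicromolar_mt1"] or flags["submicromolar_mt2"]
    flags["potent_lt_100nM"] = flags["potent_mt1"] or flags["potent_mt2"]
    flags["ki_lt_10uM"] = flags["ki_ok_mt1"] or flags["ki_ok_mt2"]
    flags["partial"] = flags["partial_mt1"] or flags["partial_mt2"]
    return flags


def load_reference_table() -> pd.DataFrame:
    """Packaged literature pharmacology table, censored cells parsed.

    Columns with possible censoring (EC50, Emax, pKi, pEC50, LE,
    selectivity) hold floats, ``None`` for not-determined, or
    :class:`Bound` for one-sided values.
    """
    path = resources.files("melapharm.data") / "reference_pharmacology.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype=str)
    parsed = df.copy()
    for col in df.columns:
        if col == "compound":
            continue
        # object dtype keeps None as None (float coercion would turn it NaN)
        parsed[col] = pd.Series([parse_reported(v) for v in df[col]],
                                index=df.index, dtype=object)
    return parsed


def recompute_selectivity(table: pd.DataFrame, ndigits: int = 1) -> pd.Series:
    """Re-derive the selectivity column from printed EC50/Emax per row."""
    out = {}
    for _, row in table.iterrows():
        out[row["compound"]] = report_fold(
            selectivity_fold(row["mt1_EC50_nM"], row["mt1_Emax"],
                             row["mt2_EC50_nM"], row["mt2_Emax"]),
            ndigits)
    return pd.Series(out, name="selectivity_recomputed")


def build_summary_table(
    agonist_fits: list | None = None,
    binding_fits: list | None = None,
    novelty: dict[str, float] | None = None,
    heavy_atoms: dict[str, int] | None = None,
    cfg: MetricConfig | None = None,
) -> pd.DataFrame:
    """Assemble a per-compound pharmacology summary from fit objects.

    One row per compound; a receptor block with no assay renders as None
    ("ND"). Selectivity, LE and classification flags are computed from the
    fitted values; formatting rules (EC50 < 100 nM, Emax < 70%) are exported
    as boolean columns rather than typography.
    """
    cfg = cfg or MetricConfig()
    agonist_fits = agonist_fits or []
    binding_fits = binding_fits or []
    novelty = novelty or {}
    heavy_atoms = heavy_atoms or {}
    compounds: dict[str, dict] = {}

    def blank(cid: str) -> dict:
        return compounds.setdefault(cid, {"compound": cid})

    for f in agonist_fits:
        rec = f.receptor.lower()
        d = blank(f.compound_id)
        d[f"{rec}_pEC50"] = f.pec50
        d[f"{rec}_pEC50_sem"] = f.se.get("pec50")
        d[f"{rec}_EC50_nM"] = f.ec50_nM
        d[f"{rec}_Emax"] = f.emax
        d[f"{rec}_Emax_sem"] = f.se.get("emax")
        if f.compound_id in heavy_atoms:
            d[f"{rec}_LE"] = ligand_efficiency(
                f.pec50, heavy_atoms[f.compound_id], cfg.le_constant)
    for f in binding_fits:
        rec = f.receptor.lower()
        d = blank(f.compound_id)
        d[f"{rec}_pKi"] = f.pki
        d[f"{rec}_Ki_nM"] = f.ki_nM
    rows = []
    for cid, d in compounds.items():
        try:
            d["selectivity_fold"] = report_fold(selectivity_fold(
                d.get("mt1_EC50_nM"), d.get("mt1_Emax"),
                d.get("mt2_EC50_nM"), d.get("mt2_Emax")))
        except (ValueError, TypeError):
            d["selectivity_fold"] = None  # censored block: fold not computable
        if cid in novelty:
            d["tanimoto_distance"] = novelty[cid]
        d.update(classify_hit(d, cfg))
        d["bold_ec50_lt_100nM"] = d["potent_lt_100nM"]
        d["italic_emax_lt_70"] = d["partial"]
        rows.append(d)
    if not rows:
        return pd.DataFrame(columns=["compound"])
    return pd.DataFrame(rows).set_index("compound", drop=False)


def count_hits(table: pd.DataFrame, cfg: MetricConfig | None = None,
               reference: str = REFERENCE_COMPOUND) -> dict:
    """Funnel statistics over a summary/reference table (reference excluded)."""
    cfg = cfg or MetricConfig()
    hits = table[table["compound"] != reference]
    flags = [classify_hit(row.to_dict(), cfg) for _, row in hits.iterrows()]
    n = len(flags)
    n_sub = sum(f["submicromolar"] for f in flags)
    return {
        "n_compounds": n,
        "n_submicromolar": n_sub,
        "n_potent_lt_100nM": sum(f["potent_lt_100nM"] for f in flags),
        "n_ki_lt_10uM": sum(f["ki_lt_10uM"] for f in flags),
        "n_partial_mt2": sum(f["partial_mt2"] for f in flags),
    }
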