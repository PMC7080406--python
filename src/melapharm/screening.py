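"""Docking-model enrichment benchmarking and candidate triage.

Docking scores are energies in kJ/mol, lower (more negative) = better. A
labeled score table (known actives vs. property-matched decoys) yields a
ROC curve and its AUC (reported on a 0-100 scale), used to select among
receptor models. Triage then applies the screening funnel: an energy
cutoff, top-N selection per model, rank intersection across receptors, and
a diversity pick over chemical clusters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .library import ClusterAssignment

LABELS = ("active", "decoy", "unknown")

#: standard virtual-screening energy cutoff, kJ/mol
DEFAULT_SCORE_CUTOFF = -32.0


@dataclass
class TriageConfig:
    score_cutoff: float = DEFAULT_SCORE_CUTOFF
    top_n_initial: int = 5000
    top_n_final: int = 500
    cluster_distance_threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.top_n_final > self.top_n_initial:
            raise ValueError("top_n_final must not exceed top_n_initial")


@dataclass
class ROCResult:
    """ROC points and trapezoidal AUC for one model's labeled scores."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc_percent: float
    n_active: int
    n_decoy: int

    @property
    def auc_fraction(self) -> float:
        return self.auc_percent / 100.0


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"compound_id", "score", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    if not np.isfinite(table["score"].to_numpy(float)).all():
        raise ValueError("non-finite docking scores")
    bad = set(table["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return table


def _labeled_scores(table: pd.DataFrame, model_id: str | None) -> pd.DataFrame:
    _validate_table(table)
    if model_id is not None and "model_id" in table.columns:
        table = table[table["model_id"] == model_id]
    labeled = table[table["label"].isin(("active", "decoy"))]
    n_act = int((labeled["label"] == "active").sum())
    n_dec = int((labeled["label"] == "decoy").sum())
    if n_act == 0 or n_dec == 0:
        raise ValueError("need at least one active and one decoy")
    return labeled


def roc_curve(table: pd.DataFrame, model_id: str | None = None) -> ROCResult:
    """ROC of a labeled score table; lower scores rank better.

    Tied scores follow the average-rank convention (a tied group contributes
    a diagonal segment), so an all-tied table gives AUC 50. AUC is the
    trapezoidal area, reported in percent.
    """
    labeled = _labeled_scores(table, model_id)
    y = (labeled["label"] == "active").to_numpy(int)
    # negate: sklearn ranks high scores first, docking energies rank low first
    fpr, tpr, _ = _sk_roc_curve(y, -labeled["score"].to_numpy(float),
                                drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc_percent=100.0 * auc,
                     n_active=int(y.sum()), n_decoy=int(len(y) - y.sum()))


def auc_rank_equivalence(table: pd.DataFrame, model_id: str | None = None) -> float:
    """AUC (percent) via the Mann-Whitney rank statistic.

    Independent of the ROC-integration path: AUC is the fraction of
    (active, decoy) pairs where the active scores better, counting ties as
    half. Agrees with :func:`roc_curve` to floating-point precision.
    """
    labeled = _labeled_scores(table, model_id)
    scores = labeled["score"].to_numpy(float)
    is_active = (labeled["label"] == "active").to_numpy(bool)
    ranks = rankdata(scores)  # ascending: best energy gets rank 1
    n_a, n_d = int(is_active.sum()), int((~is_active).sum())
    # pairs in which a decoy outranks an active (plus half the ties)
    u_against = ranks[is_active].sum() - n_a * (n_a + 1) / 2.0
    return 100.0 * (1.0 - u_against / (n_a * n_d))


def tpr_at_fpr(roc: ROCResult, fpr_level: float) -> float:
    """Interpolated TPR of a ROC curve at a given FPR (early-enrichment)."""
    return float(np.interp(fpr_level, roc.fpr, roc.tpr))


def select_model(tables: dict[str, pd.DataFrame]) -> str:
    """Pick the receptor model with the best enrichment (arg-max AUC).

    All models must score the same labeled compound set. Exact AUC ties are
    broken toward the model with higher TPR at FPR = 0.1, then lexically.
    """
    if not tables:
        raise ValueError("no models given")
    ids = {m: frozenset(_labeled_scores(t, None)["compound_id"]) for m, t in tables.items()}
    ref_model = next(iter(ids))
    for m, s in ids.items():
        if s != ids[ref_model]:
            diff = sorted(s.symmetric_difference(ids[ref_model]))
            raise ValueError(
                f"models {ref_model!r} and {m!r} score different compound sets: {diff}")
    rocs = {m: roc_curve(t) for m, t in tables.items()}
    best = sorted(
        rocs,
        key=lambda m: (-rocs[m].auc_percent, -tpr_at_fpr(rocs[m], 0.1), m),
    )
    return best[0]


def score_cutoff_filter(table: pd.DataFrame, cutoff: float = DEFAULT_SCORE_CUTOFF) -> pd.DataFrame:
    """Rows scoring better than (<=, more negative than) the energy cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    _validate_table(table)
    return table[table["score"] <= cutoff]


def _top_n_ids(table: pd.DataFrame, top_n: int) -> list[str]:
    if top_n > len(table):
        warnings.warn(f"top_n={top_n} exceeds table size {len(table)}; using all rows")
        top_n = len(table)
    ordered = table.sort_values(["score", "compound_id"], kind="mergesort")
    return ordered["compound_id"].head(top_n).tolist()


def rank_intersect(table_a: pd.DataFrame, table_b: pd.DataFrame, top_n: int) -> list[str]:
    """Compound ids in the top-N (ascending score) of both tables.

    The cross-receptor intersection step of the screening funnel; order of
    the result follows table A's ranking.
    """
    _validate_table(table_a), _validate_table(table_b)
    top_b = set(_top_n_ids(table_b, top_n))
    return [cid for cid in _top_n_ids(table_a, top_n) if cid in top_b]


def diversity_pick(
    table: pd.DataFrame,
    clusters: list[ClusterAssignment],
    top_n_final: int,
) -> list[str]:
    """Final diversity selection: cluster representatives by best score.

    Takes the representative of each chemical cluster, ranks them by
    ascending docking score, and returns the first ``top_n_final``.
    """
    _validate_table(table)
    reps = {a.compound_id for a in clusters if a.is_representative}
    sub = table[table["compound_id"].isin(reps)]
    if len(reps) < top_n_final:
        warnings.warn(
            f"only {len(reps)} cluster representatives for top_n_final={top_n_final}")
        top_n_final = len(reps)
    return _top_n_ids(sub, top_n_final)


def read_score_table(path) -> pd.DataFrame:
    """Read a delimited score table (compound_id, model_id, score, label)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        df["label"] = "unknown"
    df["label"] = df["label"].fillna("unknown")
    return _validate_table(df)
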