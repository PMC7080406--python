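"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the study conditions of a melatonin-receptor
virtual-screening campaign without any external data: two-component normal
score distributions for 20 known ligands vs. 780 decoys, Hill and
operational-model agonist curves with additive Gaussian noise on the
percent scale (N = 3 replicates), one-site competition-binding curves over
a 100 fM - 10 uM span, and small SMILES libraries drawn from packaged
template molecules with known filter outcomes. Every generator is
deterministic for a fixed seed, and every generated observation traces to
a ground-truth record, enabling parameter-recovery testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bias import operational_response
from .doseresponse import (AgonistDataset, BindingDataset, competition_response,
                           hill_response, DEFAULT_RADIOLIGAND_KD_NM)

#: default agonist grid: 10 half-log steps ending at 10 uM (log10 molar)
DEFAULT_AGONIST_GRID = tuple(float(x) for x in np.arange(-9.5, -4.9, 0.5).round(2))
#: default binding grid: 9 log-spaced points spanning 100 fM to 10 uM
DEFAULT_BINDING_GRID = tuple(float(x) for x in np.linspace(-13.0, -5.0, 9))


@dataclass
class SimConfig:
    """Study-condition parameters for all generators."""

    seed: int = 0
    n_actives: int = 20
    n_decoys: int = 780
    active_score_mean: float = -35.0   # kJ/mol
    active_score_sd: float = 3.0
    decoy_score_mean: float = -25.0
    decoy_score_sd: float = 3.0
    conc_grid: tuple = DEFAULT_AGONIST_GRID   # log10 molar
    noise_sd: float = 5.0              # response units (% scale)
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("active and decoy counts must be positive")
        if self.active_score_sd <= 0 or self.decoy_score_sd <= 0:
            raise ValueError("score SDs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        grid = np.asarray(self.conc_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("empty concentration grid")
        if not (np.diff(grid) > 0).all():
            raise ValueError("conc_grid must be strictly increasing")


# ------------------------------------------------------------ ground truth

@dataclass(frozen=True)
class HillTruth:
    compound_id: str
    receptor: str = "MT2"
    pathway: str = "Gprotein_cAMP"
    pec50: float = 9.0
    emax: float = 100.0
    basal: float = 0.0
    hill_slope: float = 1.0


@dataclass(frozen=True)
class OperationalTruth:
    compound_id: str
    pathway: str = "Gprotein_cAMP"
    receptor: str = "MT2"
    log_ka: float = -7.0
    log_r: float = 8.0
    n: float = 1.0
    em: float = 100.0
    basal: float = 0.0


@dataclass(frozen=True)
class BindingTruth:
    compound_id: str
    receptor: str = "MT2"
    ic50_nM: float = 10.0
    top: float = 100.0
    bottom: float = 0.0


@dataclass
class ScoreGroundTruth:
    """Population membership for every generated score row."""

    labels: dict[str, str] = field(default_factory=dict)


# -------------------------------------------------------------- generators

def gen_screen_scores(cfg: SimConfig, model_id: str = "model"
                      ) -> tuple[pd.DataFrame, ScoreGroundTruth]:
    """Docking-score table from two normal components (actives vs. decoys).

    The closed-form expected AUC of this construction is
    Phi((mu_d - mu_a) / sqrt(sd_a^2 + sd_d^2)), which anchors the
    enrichment oracles.
    """
    rng = np.random.default_rng(cfg.seed)
    act = rng.normal(cfg.active_score_mean, cfg.active_score_sd, cfg.n_actives)
    dec = rng.normal(cfg.decoy_score_mean, cfg.decoy_score_sd, cfg.n_decoys)
    ids = ([f"ACT{i + 1:05d}" for i in range(cfg.n_actives)]
           + [f"DEC{i + 1:05d}" for i in range(cfg.n_decoys)])
    labels = ["active"] * cfg.n_actives + ["decoy"] * cfg.n_decoys
    table = pd.DataFrame({
        "compound_id": ids,
        "model_id": model_id,
        "score": np.concatenate([act, dec]),
        "label": labels,
    })
    return table, ScoreGroundTruth(labels=dict(zip(ids, labels)))


def expected_auc_percent(cfg: SimConfig) -> float:
    """Closed-form AUC (percent) of the two-normal score model."""
    from scipy.stats import norm

    delta = cfg.decoy_score_mean - cfg.active_score_mean
    spread = np.hypot(cfg.active_score_sd, cfg.decoy_score_sd)
    return 100.0 * float(norm.cdf(delta / spread))


def gen_agonist_dataset(truth, cfg: SimConfig) -> AgonistDataset:
    """Noisy concentration-response observations from a Hill or
    operational-model ground truth, replicated over the grid."""
    grid = np.asarray(cfg.conc_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    if isinstance(truth, HillTruth):
        clean = hill_response(grid, truth.pec50, truth.emax, truth.basal,
                              truth.hill_slope)
    elif isinstance(truth, OperationalTruth):
        clean = operational_response(grid, truth.log_ka, truth.log_r,
                                     truth.n, truth.em, truth.basal)
    else:
        raise TypeError(f"unsupported truth type: {type(truth).__name__}")
    if not np.isfinite(clean).all():
        raise ValueError("truth parameters produce non-finite responses")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(1, cfg.replicates + 1):
        noise = rng.normal(0.0, cfg.noise_sd, grid.size) if cfg.noise_sd > 0 else 0.0
        rows.append(pd.DataFrame({
            "log_conc_M": grid,
            "response": clean + noise,
            "replicate": rep,
        }))
    return AgonistDataset(truth.compound_id, truth.receptor, truth.pathway,
                          pd.concat(rows, ignore_index=True))


def gen_binding_dataset(truth: BindingTruth, cfg: SimConfig,
                        radioligand_conc_nM: float = 1.0,
                        radioligand_kd_nM: float = DEFAULT_RADIOLIGAND_KD_NM,
                        conc_grid=DEFAULT_BINDING_GRID) -> BindingDataset:
    """Noisy one-site competition-binding observations."""
    grid = np.asarray(conc_grid, dtype=float)
    log_ic50_M = np.log10(truth.ic50_nM) - 9.0
    clean = competition_response(grid, log_ic50_M, truth.top, truth.bottom)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(1, cfg.replicates + 1):
        noise = rng.normal(0.0, cfg.noise_sd, grid.size) if cfg.noise_sd > 0 else 0.0
        rows.append(pd.DataFrame({
            "log_conc_M": grid,
            "response": clean + noise,
            "replicate": rep,
        }))
    return BindingDataset(truth.compound_id, truth.receptor,
                          pd.concat(rows, ignore_index=True),
                          radioligand_conc_nM=radioligand_conc_nM,
                          radioligand_kd_nM=radioligand_kd_nM)


# ------------------------------------------------------------- library gen

def load_templates() -> pd.DataFrame:
    """Packaged template molecules with annotated filter outcomes."""
    path = resources.files("melapharm.data") / "library_templates.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    df["expect_pass"] = df["expect_pass"].astype(bool)
    return df


def gen_library(n_pass: int, n_fail: int, seed: int = 0) -> pd.DataFrame:
    """Sample a SMILES library from the annotated templates.

    Returns rows (compound_id, smiles, template_id, expect_pass,
    fail_reason): ``n_pass`` draws from filter-passing templates and
    ``n_fail`` from failing ones, with replacement, deterministically.
    """
    if n_pass < 0 or n_fail < 0 or n_pass + n_fail < 1:
        raise ValueError("need at least one molecule")
    t = load_templates()
    rng = np.random.default_rng(seed)
    parts = []
    for want, pool in ((n_pass, t[t["expect_pass"]]), (n_fail, t[~t["expect_pass"]])):
        if want == 0:
            continue
        idx = rng.integers(0, len(pool), size=want)
        parts.append(pool.iloc[idx].reset_index(drop=True))
    lib = pd.concat(parts, ignore_index=True)
    lib.insert(0, "compound_id",
               [f"LIB{i + 1:05d}_{tid}" for i, tid in enumerate(lib["template_id"])])
    return lib[["compound_id", "smiles", "template_id", "expect_pass", "fail_reason"]]


def write_smiles(lib: pd.DataFrame, path: str | Path) -> Path:
    """Write a library as a .smi file (SMILES whitespace id per line)."""
    path = Path(path)
    lines = [f"{row.smiles}\t{row.compound_id}" for row in lib.itertuples()]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_manifest(path: str | Path, cfg: SimConfig, **extra) -> Path:
    """Record the generator configuration (seed included) as YAML."""
    path = Path(path)
    payload = {"sim_config": {
        k: ([float(x) for x in v] if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()}}
    payload.update(extra)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path
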