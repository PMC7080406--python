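"""End-to-end orchestration: prep -> bench -> triage -> fit -> table -> bias.

The pipeline runs either on user-supplied delimited files or fully on
synthetic inputs. Every stage writes new files into the output directory
(no stage mutates another stage's inputs) and the run manifest records the
seed, the configuration and a content hash, so a rerun with the same seed
is byte-identical in its numeric outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import bias as bias_mod
from . import doseresponse as dr
from . import library as lib_mod
from . import metrics as metrics_mod
from . import screening as screen_mod
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "melapharm_out"
    stages: tuple = ("prep", "bench", "triage", "fit", "table", "bias")
    filter_config: lib_mod.FilterConfig = field(default_factory=lib_mod.FilterConfig)
    triage_config: screen_mod.TriageConfig = field(
        default_factory=lambda: screen_mod.TriageConfig(top_n_initial=200, top_n_final=20))
    metric_config: metrics_mod.MetricConfig = field(default_factory=metrics_mod.MetricConfig)
    sim_config: syn.SimConfig = field(default_factory=syn.SimConfig)
    n_library_pass: int = 30
    n_library_fail: int = 10
    reference_compound: str = "melatonin"


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema diagnostics for delimited inputs; empty list means clean.

    ``paths`` maps a kind ('scores' or 'assay') to a file path. Messages
    carry 1-based line numbers where applicable.
    """
    required = {
        "scores": ["compound_id", "score"],
        "assay": ["compound_id", "receptor", "pathway", "log_conc_M", "response"],
    }
    numeric = {"scores": ["score"], "assay": ["log_conc_M", "response"]}
    diags: list[str] = []
    for kind, path in paths.items():
        path = Path(path)
        if kind not in required:
            diags.append(f"{path}: unknown input kind {kind!r}")
            continue
        if not path.exists():
            diags.append(f"{path}: file not found")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            diags.append(f"{path}: unreadable ({exc})")
            continue
        for col in required[kind]:
            if col not in df.columns:
                diags.append(f"{path}: missing required column {col!r}")
        for col in numeric[kind]:
            if col not in df.columns:
                continue
            coerced = pd.to_numeric(df[col], errors="coerce")
            for idx in df.index[coerced.isna() & df[col].notna()]:
                # +2: header line plus 1-based indexing
                diags.append(f"{path}: line {idx + 2}: non-numeric value "
                             f"{df.loc[idx, col]!r} in column {col!r}")
    return diags


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Run the demo pipeline on synthetic inputs; returns a report bundle.

    The bundle maps stage names to their primary tables and file paths.
    Failure of any stage raises :class:`StageError` naming the stage;
    outputs of completed stages remain on disk.
    """
    cfg = cfg or PipelineConfig()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(out), "config_hash": _config_hash(cfg)}
    seed = cfg.sim_config.seed if cfg.sim_config.seed else cfg.seed

    stage = "prep"
    try:
        lib = syn.gen_library(cfg.n_library_pass, cfg.n_library_fail, seed=seed)
        smi = syn.write_smiles(lib, out / "library.smi")
        parsed = lib_mod.parse_smiles_library(smi)
        records = [lib_mod.compute_properties(r) for r in parsed.records]
        kept, rejected = lib_mod.apply_filters(records, cfg.filter_config)
        kept_df = pd.DataFrame([vars(r) for r in kept])
        rej_df = pd.DataFrame([{**vars(r), "reason": why} for r, why in rejected])
        kept_df.to_csv(out / "library_kept.csv", index=False)
        rej_df.to_csv(out / "library_rejected.csv", index=False)
        logger.info("prep: %d in, %d kept, %d rejected",
                    len(records), len(kept), len(rejected))
        bundle["prep"] = {"n_in": len(records), "n_kept": len(kept),
                          "n_rejected": len(rejected)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "bench"
    try:
        sim = cfg.sim_config
        opt_cfg = syn.SimConfig(**{**vars(sim), "seed": seed})
        xtal_cfg = syn.SimConfig(**{**vars(sim), "seed": seed + 1,
                                    "active_score_mean": sim.active_score_mean + 5.0})
        t_opt, _ = syn.gen_screen_scores(opt_cfg, model_id="optimized")
        t_x, _ = syn.gen_screen_scores(xtal_cfg, model_id="crystal")
        t_x["compound_id"] = t_opt["compound_id"].to_numpy()  # same compound set
        best = screen_mod.select_model({"optimized": t_opt, "crystal": t_x})
        aucs = {m: screen_mod.roc_curve(t).auc_percent
                for m, t in (("optimized", t_opt), ("crystal", t_x))}
        pd.concat([t_opt, t_x]).to_csv(out / "bench_scores.csv", index=False)
        logger.info("bench: AUCs %s; selected %s", aucs, best)
        bundle["bench"] = {"auc_percent": aucs, "selected_model": best,
                           "scores": t_opt}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "triage"
    try:
        table = bundle["bench"]["scores"]
        tri = cfg.triage_config
        passed = screen_mod.score_cutoff_filter(table, tri.score_cutoff)
        both = screen_mod.rank_intersect(table, table, tri.top_n_initial)
        passed.to_csv(out / "triage_cutoff.csv", index=False)
        logger.info("triage: %d pass cutoff %.1f; %d in rank intersection",
                    len(passed), tri.score_cutoff, len(both))
        bundle["triage"] = {"n_pass_cutoff": len(passed),
                            "n_intersect": len(both)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "fit"
    try:
        truths = {
            "melatonin": {"MT1": 11.38, "MT2": 10.30},
            "cpd21": {"MT1": 7.91, "MT2": 9.44},
            "cpd28": {"MT1": 10.39, "MT2": 10.35},
        }
        emax = {"melatonin": 100.0, "cpd21": 86.1, "cpd28": 69.4}
        fits = []
        k = 0
        # picomolar agonists need a wider span than the default assay grid
        wide_grid = tuple(float(x) for x in range(-13, -4, 1))
        for cid, per_rec in truths.items():
            for rec, pec50 in per_rec.items():
                truth = syn.HillTruth(cid, receptor=rec, pec50=pec50,
                                      emax=emax[cid])
                dcfg = syn.SimConfig(**{**vars(cfg.sim_config),
                                        "seed": seed + 100 + k,
                                        "conc_grid": wide_grid})
                fits.append(dr.fit_hill(syn.gen_agonist_dataset(truth, dcfg)))
                k += 1
        fit_df = pd.DataFrame([{
            "compound_id": f.compound_id, "receptor": f.receptor,
            "pEC50": f.pec50, "pEC50_sem": f.se.get("pec50"),
            "EC50_nM": f.ec50_nM, "Emax": f.emax,
            "converged": f.converged} for f in fits])
        fit_df.to_csv(out / "agonist_fits.csv", index=False)
        bundle["fit"] = {"fits": fits, "table": fit_df}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "table"
    try:
        heavy = {"melatonin": 17, "cpd28": 17, "cpd21": 16}
        summary = metrics_mod.build_summary_table(
            agonist_fits=bundle["fit"]["fits"], heavy_atoms=heavy,
            cfg=cfg.metric_config)
        summary.to_csv(out / "summary_table.csv", index=False)
        bundle["table"] = {"summary": summary}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "bias"
    try:
        op_truths = {
            "melatonin": {"Gprotein_cAMP": (-9.0, 10.5), "arrestin_Tango": (-9.0, 10.0)},
            "cpd21": {"Gprotein_cAMP": (-8.0, 10.2), "arrestin_Tango": (-8.0, 8.5)},
        }
        fits_by_pathway = {}
        for j, pathway in enumerate(dr.PATHWAYS):
            dsets = []
            for i, (cid, per_pw) in enumerate(op_truths.items()):
                log_ka, log_r = per_pw[pathway]
                truth = syn.OperationalTruth(cid, pathway=pathway,
                                             log_ka=log_ka, log_r=log_r)
                dcfg = syn.SimConfig(**{**vars(cfg.sim_config),
                                        "seed": seed + 200 + 10 * j + i,
                                        "conc_grid": wide_grid})
                dsets.append(syn.gen_agonist_dataset(truth, dcfg))
            fits_by_pathway[pathway] = bias_mod.fit_operational(dsets)
        bt = bias_mod.bias_table(fits_by_pathway["Gprotein_cAMP"],
                                 fits_by_pathway["arrestin_Tango"],
                                 reference_id=cfg.reference_compound)
        bt.to_csv(out / "bias_table.csv", index=False)
        bundle["bias"] = {"table": bt}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "seed": seed,
        "config_hash": bundle["config_hash"],
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "stages_run": list(cfg.stages),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return bundle
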