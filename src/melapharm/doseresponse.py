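"""Concentration-response fitting and potency/affinity scale conversions.

Agonist curves are fit with the Hill (log-logistic) equation on the
log10-molar concentration scale:

    response(x) = basal + (emax - basal) / (1 + 10^(slope * (-pEC50 - x)))

so the fitted midpoint parameter is pEC50 directly and its asymptotic
standard error matches the "pEC50 +/- SEM" convention of pharmacology
tables. Competition binding uses the one-site model with a Cheng-Prusoff
conversion of IC50 to Ki given the radioligand concentration and Kd.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

RECEPTORS = ("MT1", "MT2", "other")
PATHWAYS = ("Gprotein_cAMP", "arrestin_Tango")

#: synthetic-fixture radioligand Kd in nM; a stand-in configuration value
#: for simulated assays, not a measured constant.
DEFAULT_RADIOLIGAND_KD_NM = 0.1


class NoResponseError(ValueError):
    """Raised when a dataset is flat (no concentration-dependent signal)."""


# ---------------------------------------------------------------- datasets

@dataclass
class AgonistDataset:
    """Concentration-response observations for one compound/receptor/pathway.

    ``data`` columns: log_conc_M (log10 molar), response (% of reference
    Emax), replicate.
    """

    compound_id: str
    receptor: str
    pathway: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"log_conc_M", "response"} - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if "replicate" not in self.data.columns:
            self.data = self.data.assign(replicate=1)
        if not np.isfinite(self.data["response"].to_numpy(float)).all():
            raise ValueError("non-finite responses")

    @property
    def n_concentrations(self) -> int:
        return self.data["log_conc_M"].nunique()


@dataclass
class BindingDataset:
    """Competition-binding observations (% specific binding vs. log conc)."""

    compound_id: str
    receptor: str
    data: pd.DataFrame
    radioligand_conc_nM: float = 1.0
    radioligand_kd_nM: float = DEFAULT_RADIOLIGAND_KD_NM


# ---------------------------------------------------------------- results

@dataclass
class HillFit:
    compound_id: str
    receptor: str
    pathway: str
    pec50: float
    emax: float
    basal: float
    hill_slope: float
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    @property
    def ec50_nM(self) -> float:
        return pec50_to_ec50_nM(self.pec50)


@dataclass
class CompetitionFit:
    compound_id: str
    receptor: str
    ic50_nM: float
    ki_nM: float
    top: float
    bottom: float
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    @property
    def pic50(self) -> float:
        return 9.0 - math.log10(self.ic50_nM)

    @property
    def pki(self) -> float:
        return 9.0 - math.log10(self.ki_nM)


# ------------------------------------------------------------- conversions

def pec50_to_ec50_nM(pec50: float) -> float:
    """EC50 in nM from pEC50 (= -log10 EC50 in molar): 10^(9 - pEC50)."""
    return 10.0 ** (9.0 - pec50)


def ec50_nM_to_pec50(ec50_nM: float) -> float:
    if ec50_nM <= 0:
        raise ValueError("EC50 must be positive")
    return 9.0 - math.log10(ec50_nM)


# affinity scale uses the identical antilog relation
pki_to_ki_nM = pec50_to_ec50_nM
ki_nM_to_pki = ec50_nM_to_pec50


def cheng_prusoff_ki_nM(ic50_nM: float, radioligand_conc_nM: float,
                        radioligand_kd_nM: float) -> float:
    """Ki = IC50 / (1 + [L]/Kd); monotone decreasing in [L]."""
    if ic50_nM <= 0 or radioligand_kd_nM <= 0 or radioligand_conc_nM < 0:
        raise ValueError("concentrations and Kd must be positive")
    return ic50_nM / (1.0 + radioligand_conc_nM / radioligand_kd_nM)


# ------------------------------------------------------------------ models

def hill_response(log_conc_M, pec50, emax, basal=0.0, hill_slope=1.0):
    """Hill curve on the log10-molar concentration axis."""
    x = np.asarray(log_conc_M, dtype=float)
    return basal + (emax - basal) / (1.0 + 10.0 ** (hill_slope * (-pec50 - x)))


def competition_response(log_conc_M, log_ic50_M, top=100.0, bottom=0.0):
    """One-site competition: % specific binding falls with competitor."""
    x = np.asarray(log_conc_M, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (x - log_ic50_M))


# -------------------------------------------------------------------- fits

def _noise_estimate(data: pd.DataFrame) -> float:
    """Pooled replicate SD; 0 when unreplicated or noiseless."""
    g = data.groupby("log_conc_M")["response"]
    counts = g.count()
    if (counts < 2).all():
        return 0.0
    resid = data["response"] - g.transform("mean")
    dof = (counts - 1).sum()
    return float(np.sqrt((resid ** 2).sum() / dof)) if dof > 0 else 0.0


def _check_signal(data: pd.DataFrame) -> None:
    means = data.groupby("log_conc_M")["response"].mean()
    span = float(means.max() - means.min())
    noise = _noise_estimate(data)
    if span < max(5.0 * noise, 1e-6):
        raise NoResponseError(
            f"no concentration-dependent response (span {span:.3g}, "
            f"noise estimate {noise:.3g})")


def fit_hill(dataset: AgonistDataset, slope_mode: str = "fixed1") -> HillFit:
    """Least-squares Hill fit; ``slope_mode`` 'fixed1' (three-parameter,
    the default workflow for these assays) or 'free' (four-parameter).

    Returns asymptotic standard errors; ``converged`` is False (never an
    exception) when the optimizer fails.
    """
    if dataset.n_concentrations < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if slope_mode not in ("fixed1", "free"):
        raise ValueError("slope_mode must be 'fixed1' or 'free'")
    _check_signal(dataset.data)
    x = dataset.data["log_conc_M"].to_numpy(float)
    y = dataset.data["response"].to_numpy(float)
    means = dataset.data.groupby("log_conc_M")["response"].mean()
    basal0, emax0 = float(means.iloc[0]), float(means.max())
    half = (basal0 + emax0) / 2.0
    pec50_0 = -float(np.interp(half, means.to_numpy(), means.index.to_numpy()))
    names = ["pec50", "emax", "basal"]
    if slope_mode == "fixed1":
        model = lambda xx, p, e, b: hill_response(xx, p, e, b, 1.0)
        p0 = [pec50_0, emax0, basal0]
    else:
        model = hill_response
        p0 = [pec50_0, emax0, basal0, 1.0]
        names = names + ["hill_slope"]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        ok = bool(np.isfinite(popt).all())
        msg = "" if ok else "non-finite parameter estimates"
    except RuntimeError as exc:  # optimizer failure stays a flag, not a crash
        popt, perr, ok, msg = p0, [np.nan] * len(p0), False, str(exc)
    params = dict(zip(names, map(float, popt)))
    return HillFit(
        compound_id=dataset.compound_id, receptor=dataset.receptor,
        pathway=dataset.pathway,
        pec50=params["pec50"], emax=params["emax"], basal=params["basal"],
        hill_slope=params.get("hill_slope", 1.0),
        se=dict(zip(names, map(float, perr))), converged=ok, message=msg)


def normalize_to_reference(dataset: AgonistDataset, reference_fit: HillFit) -> AgonistDataset:
    """Rescale responses so the reference agonist's fitted Emax reads 100%."""
    if reference_fit is None:
        raise ValueError("missing reference fit")
    if reference_fit.emax <= 0:
        raise ValueError("reference emax must be positive")
    scaled = dataset.data.assign(
        response=dataset.data["response"] * (100.0 / reference_fit.emax))
    return AgonistDataset(dataset.compound_id, dataset.receptor,
                          dataset.pathway, scaled)


def fit_competition(dataset: BindingDataset) -> CompetitionFit:
    """One-site competition fit (top, bottom, logIC50) + Cheng-Prusoff Ki."""
    data = dataset.data
    _check_signal(data)
    x = data["log_conc_M"].to_numpy(float)
    y = data["response"].to_numpy(float)
    p0 = [float(np.median(x)), float(np.max(y)), float(np.min(y))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                lambda xx, l, t, b: competition_response(xx, l, t, b),
                x, y, p0=p0, maxfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        ok, msg = True, ""
    except RuntimeError as exc:
        popt, perr, ok, msg = p0, [np.nan] * 3, False, str(exc)
    log_ic50, top, bottom = map(float, popt)
    ic50_nM = 10.0 ** (log_ic50 + 9.0)
    ki_nM = cheng_prusoff_ki_nM(ic50_nM, dataset.radioligand_conc_nM,
                                dataset.radioligand_kd_nM)
    return CompetitionFit(
        compound_id=dataset.compound_id, receptor=dataset.receptor,
        ic50_nM=ic50_nM, ki_nM=ki_nM, top=top, bottom=bottom,
        se=dict(zip(["log_ic50", "top", "bottom"], map(float, perr))),
        converged=ok, message=msg)


def read_assay_table(path) -> list[AgonistDataset]:
    """Read delimited assay data (compound_id, receptor, pathway,
    log_conc_M, response, replicate) into per-curve datasets."""
    df = pd.read_csv(path)
    required = {"compound_id", "receptor", "pathway", "log_conc_M", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    out = []
    for (cid, rec, pw), sub in df.groupby(["compound_id", "receptor", "pathway"]):
        out.append(AgonistDataset(str(cid), rec, pw, sub.reset_index(drop=True)))
    return out
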