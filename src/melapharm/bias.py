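"""Signaling-bias quantification with the Black-Leff operational model.

Each agonist curve on a pathway is described by the operational model

    response(A) = basal + (Em - basal) / (1 + ((1 + A/KA) / (R * A))^n)

with A the agonist concentration (molar), KA = 10^logKA the functional
affinity, R = 10^logR the transduction coefficient tau/KA, and n the
transducer slope. Within one pathway Em, basal and n are shared across
compounds (per-compound Em is not identifiable for partial batches) while
logKA and logR are per-compound.

Bias analysis follows the transduction-coefficient procedure:
DeltaLog(tau/KA) of a test compound against the reference agonist
(melatonin) within each pathway, DeltaDeltaLog(tau/KA) between pathways,
and bias factor = 10^DeltaDeltaLog. Orientation: the G-protein pathway
minus the arrestin pathway, so a factor > 1 means G-protein-biased.
Standard errors combine in quadrature.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .doseresponse import AgonistDataset


@dataclass
class OperationalFit:
    compound_id: str
    pathway: str
    log_ka: float              # log10 molar
    log_r: float               # Log(tau/KA), the transduction coefficient
    n: float                   # transducer slope (shared within pathway)
    em: float                  # system maximal response, % (shared)
    basal: float               # shared
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    @property
    def log_tau(self) -> float:
        return self.log_r + self.log_ka


@dataclass
class BiasResult:
    compound_id: str
    reference_id: str
    dlog_r_gprotein: float
    dlog_r_gprotein_se: float
    dlog_r_arrestin: float
    dlog_r_arrestin_se: float

    @property
    def ddlog_r(self) -> float:
        return self.dlog_r_gprotein - self.dlog_r_arrestin

    @property
    def ddlog_r_se(self) -> float:
        return math.hypot(self.dlog_r_gprotein_se, self.dlog_r_arrestin_se)

    @property
    def bias_factor(self) -> float:
        return 10.0 ** self.ddlog_r


def operational_response(log_conc_M, log_ka, log_r, n=1.0, em=100.0, basal=0.0):
    """Operational-model response at log10-molar concentrations."""
    a = 10.0 ** np.asarray(log_conc_M, dtype=float)
    ka = 10.0 ** log_ka
    r = 10.0 ** log_r
    occ = (1.0 + a / ka) / (r * a)
    return basal + (em - basal) / (1.0 + occ ** n)


def operational_ec50_M(log_ka: float, log_r: float, n: float = 1.0) -> float:
    """Closed-form EC50 (molar) of the operational curve:
    EC50 = KA / ((2 + tau^n)^(1/n) - 1)."""
    ka = 10.0 ** log_ka
    tau = 10.0 ** (log_r + log_ka)
    return ka / ((2.0 + tau ** n) ** (1.0 / n) - 1.0)


def _initial_guesses(datasets: list[AgonistDataset]):
    """Heuristic starting values from per-curve span and midpoint."""
    em0 = max(float(d.data["response"].max()) for d in datasets)
    basal0 = min(float(d.data["response"].min()) for d in datasets)
    per = []
    for d in datasets:
        means = d.data.groupby("log_conc_M")["response"].mean()
        top = float(means.max())
        frac = min(max((top - basal0) / max(em0 - basal0, 1e-9), 0.05), 0.95)
        tau0 = frac / (1.0 - frac)
        half = (basal0 + top) / 2.0
        x_half = float(np.interp(half, means.to_numpy(), means.index.to_numpy()))
        ec50 = 10.0 ** x_half
        log_ka0 = math.log10(ec50 * (1.0 + tau0))
        log_r0 = math.log10(tau0) - log_ka0
        per.append((log_ka0, log_r0))
    return em0, basal0, per


def fit_operational(
    datasets: list[AgonistDataset],
    fix_n: float | None = 1.0,
    fix_em: float | None = 100.0,
    fix_basal: float | None = 0.0,
) -> list[OperationalFit]:
    """Global operational-model fit for all compounds on one pathway.

    Shared parameters (Em, basal, transducer slope n) may each be fixed or
    fitted; per-compound parameters are logKA and logR. Defaults pin
    n = 1, Em = 100 and basal = 0: with n = 1 each curve is an exact
    slope-1 Hill curve, so Em is structurally unidentifiable (logR shifts
    by -log Em uniformly across compounds, which cancels in DeltaLog but
    not in logR itself); responses normalized to the reference agonist's
    maximum make Em = 100% and a zero baseline the natural system
    constraints, and with no shared free parameters the per-compound
    uncertainties are independent, so quadrature SE combination is exact.
    Pass ``fix_em=None``/``fix_basal=None`` to fit them (sensible only
    with partial agonists in the batch).

    Per-compound convergence problems are reported through the
    ``converged``/``message`` fields, never by aborting the batch; poorly
    identified parameters (a full agonist's KA) surface as inflated SEs.
    """
    if not datasets:
        raise ValueError("no datasets to fit")
    pathways = {d.pathway for d in datasets}
    if len(pathways) != 1:
        raise ValueError(f"datasets span multiple pathways: {sorted(pathways)}")
    pathway = pathways.pop()
    em0, basal0, per0 = _initial_guesses(datasets)

    # assemble the shared-parameter block: (name, initial, lo, hi) if free
    shared_spec = []
    if fix_em is None:
        shared_spec.append(("em", max(em0, 1.0), 0.0, 500.0))
    if fix_basal is None:
        shared_spec.append(("basal", basal0, -50.0, 50.0))
    if fix_n is None:
        shared_spec.append(("n", 1.0, 0.2, 5.0))
    n_shared = len(shared_spec)
    p0 = [s[1] for s in shared_spec]
    lo = [s[2] for s in shared_spec]
    hi = [s[3] for s in shared_spec]
    for log_ka0, log_r0 in per0:
        p0 += [log_ka0, log_r0]
        lo += [-15.0, -5.0]
        hi += [5.0, 25.0]
    xs = [d.data["log_conc_M"].to_numpy(float) for d in datasets]
    ys = [d.data["response"].to_numpy(float) for d in datasets]
    shared_names = [s[0] for s in shared_spec]

    def unpack(p):
        sh = dict(zip(shared_names, p[:n_shared]))
        return (sh.get("em", fix_em), sh.get("basal", fix_basal),
                sh.get("n", fix_n))

    def residuals(p):
        em, basal, n = unpack(p)
        res = []
        for k in range(len(datasets)):
            log_ka, log_r = p[n_shared + 2 * k], p[n_shared + 2 * k + 1]
            res.append(operational_response(xs[k], log_ka, log_r, n, em, basal) - ys[k])
        return np.concatenate(res)

    p0 = np.clip(p0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
    sol = least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=50000)
    m = sum(len(y) for y in ys)
    dof = max(m - len(p0), 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    perr = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    em, basal, n_fit = unpack(sol.x)
    shared_se = dict(zip(shared_names, map(float, perr[:n_shared])))
    fits = []
    for k, d in enumerate(datasets):
        i_ka, i_r = n_shared + 2 * k, n_shared + 2 * k + 1
        ok = bool(sol.success and np.isfinite(sol.x[[i_ka, i_r]]).all())
        fits.append(OperationalFit(
            compound_id=d.compound_id, pathway=pathway,
            log_ka=float(sol.x[i_ka]), log_r=float(sol.x[i_r]),
            n=float(n_fit), em=float(em), basal=float(basal if basal is not None else 0.0),
            se={"log_ka": float(perr[i_ka]), "log_r": float(perr[i_r]),
                **shared_se},
            converged=ok, message="" if ok else str(sol.message)))
    return fits


def delta_logR(test: OperationalFit, reference: OperationalFit) -> tuple[float, float]:
    """DeltaLog(tau/KA) of test vs. reference on one pathway, with SE
    combined in quadrature. The reference against itself is exactly 0."""
    if test.pathway != reference.pathway:
        raise ValueError(
            f"pathway mismatch: {test.pathway} vs {reference.pathway}")
    if test.compound_id == reference.compound_id:
        return 0.0, math.hypot(test.se.get("log_r", 0.0), reference.se.get("log_r", 0.0))
    d = test.log_r - reference.log_r
    se = math.hypot(test.se.get("log_r", 0.0), reference.se.get("log_r", 0.0))
    return d, se


def bias_factor(
    dlog_r_gprotein: tuple[float, float],
    dlog_r_arrestin: tuple[float, float],
    compound_id: str = "",
    reference_id: str = "",
) -> BiasResult:
    """Combine per-pathway DeltaLog(tau/KA) into a bias factor.

    DeltaDeltaLog = G-protein minus arrestin; factor = 10^DeltaDeltaLog, so
    a compound with weakened arrestin recruitment scores above 1.
    """
    return BiasResult(
        compound_id=compound_id, reference_id=reference_id,
        dlog_r_gprotein=dlog_r_gprotein[0], dlog_r_gprotein_se=dlog_r_gprotein[1],
        dlog_r_arrestin=dlog_r_arrestin[0], dlog_r_arrestin_se=dlog_r_arrestin[1])


def bias_table(
    fits_gprotein: list[OperationalFit],
    fits_arrestin: list[OperationalFit],
    reference_id: str,
):
    """Per-compound bias results against a shared reference agonist."""
    import pandas as pd

    by_g = {f.compound_id: f for f in fits_gprotein}
    by_a = {f.compound_id: f for f in fits_arrestin}
    if reference_id not in by_g or reference_id not in by_a:
        raise ValueError(f"reference {reference_id!r} missing from a pathway")
    rows = []
    for cid in by_g:
        if cid not in by_a:
            continue
        dg = delta_logR(by_g[cid], by_g[reference_id])
        da = delta_logR(by_a[cid], by_a[reference_id])
        res = bias_factor(dg, da, cid, reference_id)
        rows.append({
            "compound_id": cid, "reference_id": reference_id,
            "dlogR_G": res.dlog_r_gprotein, "dlogR_G_se": res.dlog_r_gprotein_se,
            "dlogR_arr": res.dlog_r_arrestin, "dlogR_arr_se": res.dlog_r_arrestin_se,
            "ddlogR": res.ddlog_r, "ddlogR_se": res.ddlog_r_se,
            "bias_factor": res.bias_factor,
        })
    return pd.DataFrame(rows)
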