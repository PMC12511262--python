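"""External-validation statistics: prediction-error metrics, acceptability
gates, NPDE, prediction-corrected VPC and trapezoidal AUC.

Metric definitions
------------------
For each observation with predicted concentration Cpred and observed Cobs:

* MPE (ng/mL)  = mean(Cpred - Cobs), with SD and a one-sample test p-value
* PE (%)       = (Cpred - Cobs) / Cobs * 100
* APE (%)      = |PE|
* MdPE (%)     = median(PE)           -- bias
* MdAPE (%)    = median(APE)          -- imprecision
* F20 / F30    = % of observations with |PE| <= 20 / 30

Stratified MdPE is reported over the concentration bands low < 100,
medium 100-150 and high > 150 ng/mL (half-open [0,100), closed [100,150],
open (150, inf), so "100-150" is inclusive).  R^2 is the squared Pearson
correlation of observed vs predicted, reported both as a fraction and as a
percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ThresholdConfig

logger = logging.getLogger("quizpk")

BAND_LABELS = ("low", "medium", "high")


class MetricError(ValueError):
    """Invalid input to a validation metric."""


@dataclass(frozen=True)
class PredictionRecord:
    """Per-observation alignment of DV with its model predictions."""

    subject_id: int
    time: float
    dv: float
    pred: float
    ipred: float | None = None
    npde: float | None = None


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "time": r.time,
                "dv": r.dv,
                "pred": r.pred,
                "ipred": r.ipred,
                "npde": r.npde,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# prediction-error metric suite
# ---------------------------------------------------------------------------


def prediction_error(cpred, cobs):
    """Relative prediction error PE (%) = (Cpred - Cobs) / Cobs * 100."""
    cpred = np.asarray(cpred, dtype=float)
    cobs = np.asarray(cobs, dtype=float)
    if np.any(cobs <= 0):
        raise MetricError("PE undefined for Cobs <= 0")
    return (cpred - cobs) / cobs * 100.0


@dataclass
class ValidationReport:
    """Full metric suite for one prediction level (population or individual)."""

    n_obs: int
    prediction_level: str
    mpe: float
    mpe_sd: float
    mpe_p: float
    mdpe: float
    mdape: float
    f20: float
    f30: float
    r2: float
    stratified_mdpe: dict = field(default_factory=dict)
    stratified_n: dict = field(default_factory=dict)
    n_excluded: int = 0
    test: str = "t"
    gates: dict | None = None

    @property
    def r2_percent(self) -> float:
        return self.r2 * 100.0

    def to_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "prediction_level": self.prediction_level,
            "mpe": self.mpe,
            "mpe_sd": self.mpe_sd,
            "mpe_p": self.mpe_p,
            "mdpe": self.mdpe,
            "mdape": self.mdape,
            "f20": self.f20,
            "f30": self.f30,
            "r2": self.r2,
            "r2_percent": self.r2_percent,
            "stratified_mdpe": dict(self.stratified_mdpe),
            "stratified_n": dict(self.stratified_n),
            "n_excluded": self.n_excluded,
            "test": self.test,
            "gates": dict(self.gates) if self.gates else None,
        }


def _band_of(dv: np.ndarray, edges: tuple[float, float]) -> np.ndarray:
    lo, hi = edges
    out = np.full(dv.shape, "medium", dtype=object)
    out[dv < lo] = "low"
    out[dv > hi] = "high"
    return out


def metric_suite(
    records,
    level: str = "population",
    thresholds: ThresholdConfig | None = None,
    test: str = "t",
) -> ValidationReport:
    """Compute the full external-validation metric suite.

    ``level`` selects the prediction column: ``"population"`` uses PRED,
    ``"individual"`` uses IPRED.  Observations with Cobs <= 0 are excluded
    with a logged reason.  ``test`` chooses the MPE significance test:
    one-sample t-test (default) or Wilcoxon signed-rank (``"wilcoxon"``).
    """
    df = records_to_frame(records)
    if df.empty:
        raise MetricError("metric suite requires at least one record")
    if level not in ("population", "individual"):
        raise MetricError(f"unknown prediction level: {level!r}")
    col = "pred" if level == "population" else "ipred"
    if col not in df or df[col].isna().all():
        raise MetricError(f"records carry no {col} values for level={level!r}")
    keep = df["dv"] > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluding %d record(s) with Cobs <= 0 from PE metrics", n_excluded)
    df = df[keep]
    if df.empty:
        raise MetricError("no records with Cobs > 0")
    dv = df["dv"].to_numpy(float)
    cpred = df[col].to_numpy(float)

    err = cpred - dv
    pe = prediction_error(cpred, dv)
    ape = np.abs(pe)
    n = dv.size
    if test == "t":
        p = float(stats.ttest_1samp(err, 0.0).pvalue) if n > 1 else np.nan
    elif test == "wilcoxon":
        p = (
            float(stats.wilcoxon(err).pvalue)
            if n > 1 and np.any(err != 0)
            else (1.0 if n > 1 else np.nan)
        )
    else:
        raise MetricError(f"unknown MPE test: {test!r}")

    edges = (thresholds or ThresholdConfig()).band_edges
    bands = _band_of(dv, edges)
    strat, strat_n = {}, {}
    for label in BAND_LABELS:
        m = bands == label
        strat[label] = float(np.median(pe[m])) if np.any(m) else None
        strat_n[label] = int(m.sum())

    if n > 1 and np.std(dv) > 0 and np.std(cpred) > 0:
        r2 = float(np.corrcoef(dv, cpred)[0, 1] ** 2)
    else:
        r2 = 1.0 if np.allclose(cpred, dv) else np.nan

    return ValidationReport(
        n_obs=n,
        prediction_level=level,
        mpe=float(np.mean(err)),
        mpe_sd=float(np.std(err, ddof=1)) if n > 1 else 0.0,
        mpe_p=p,
        mdpe=float(np.median(pe)),
        mdape=float(np.median(ape)),
        f20=float(np.mean(ape <= 20.0) * 100.0),
        f30=float(np.mean(ape <= 30.0) * 100.0),
        r2=r2,
        stratified_mdpe=strat,
        stratified_n=strat_n,
        n_excluded=n_excluded,
        test=test,
    )


def acceptability_gate(
    report: ValidationReport, thresholds: ThresholdConfig | None = None
) -> dict:
    """Judge a report against the predefined acceptability criteria.

    Returns verdicts for bias (MdPE within bounds), precision (MdAPE below
    max), F20 and F30 minimums, plus ``overall`` = all four.
    """
    th = thresholds or ThresholdConfig()
    verdicts = {
        "bias": bool(th.mdpe_low <= report.mdpe <= th.mdpe_high),
        "precision": bool(report.mdape <= th.mdape_max),
        "f20": bool(report.f20 >= th.f20_min),
        "f30": bool(report.f30 >= th.f30_min),
    }
    verdicts["overall"] = all(verdicts.values())
    report.gates = verdicts
    return verdicts


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


def npde_from_simulations(
    observed: list[np.ndarray],
    simulated: list[np.ndarray],
    seed: int = 0,
    min_k: int = 100,
) -> list[np.ndarray]:
    """Normalized prediction distribution errors, one array per subject.

    ``observed[i]`` is subject i's DV vector (length n_i); ``simulated[i]``
    is a (K, n_i) matrix of replicate simulations under the fixed model.
    Per subject: center on the simulated mean, decorrelate observed and
    simulated vectors with the Cholesky factor of the simulated covariance,
    rank each decorrelated observation among its decorrelated simulations,
    and apply the inverse-normal transform.  Ties are broken by seeded
    uniform jitter; boundary ranks are clamped to [0.5/K, (K-0.5)/K].
    A singular simulated covariance falls back to variance-only
    decorrelation with a logged warning.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i, (y, sims) in enumerate(zip(observed, simulated)):
        y = np.asarray(y, dtype=float)
        sims = np.asarray(sims, dtype=float)
        K, n = sims.shape
        if K < min_k:
            raise MetricError(
                f"subject {i}: K={K} replicates < minimum {min_k} for NPDE"
            )
        if y.shape != (n,):
            raise MetricError(f"subject {i}: observation/simulation shape mismatch")
        mu = sims.mean(axis=0)
        if n == 1:
            sd = sims.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            y_dec = (y - mu) / sd
            s_dec = (sims - mu) / sd
        else:
            cov = np.cov(sims, rowvar=False, ddof=1)
            try:
                L = np.linalg.cholesky(cov)
                y_dec = np.linalg.solve(L, y - mu)
                s_dec = np.linalg.solve(L, (sims - mu).T).T
            except np.linalg.LinAlgError:
                logger.warning(
                    "subject %d: singular simulated covariance; "
                    "falling back to variance-only decorrelation",
                    i,
                )
                sd = sims.std(axis=0, ddof=1)
                sd = np.where(sd > 0, sd, 1.0)
                y_dec = (y - mu) / sd
                s_dec = (sims - mu) / sd
        # rank with seeded tie-break jitter
        jitter = rng.uniform(-1e-9, 1e-9, size=s_dec.shape)
        pd_frac = np.mean(s_dec + jitter < y_dec, axis=0)
        pd_frac = np.clip(pd_frac, 0.5 / K, (K - 0.5) / K)
        out.append(stats.norm.ppf(pd_frac))
    return out


def npde_compute(dataset, params, model, k: int = 1000, seed: int = 0) -> pd.DataFrame:
    """NPDE for every observation of a cohort under the fixed model.

    Simulates ``k`` replicate datasets with the cohort's own dose histories
    and actual sampling times (new random effects and residual errors per
    replicate), then applies :func:`npde_from_simulations`.  Returns the
    observation rows with an ``npde`` column appended.
    """
    from .pk import _subject_arrays, concentration_from_doses_batch, add_residual_error

    rng = np.random.default_rng(seed)
    observed, simulated, index = [], [], []
    for sid, dt, da, ot, dv, idx in _subject_arrays(dataset):
        etas = model.sample_eta(rng, k)
        conc = concentration_from_doses_batch(params, etas, dt, da, ot)
        sims = add_residual_error(conc, model, rng)
        observed.append(dv)
        simulated.append(sims)
        index.extend(idx)
    npdes = npde_from_simulations(
        observed, simulated, seed=int(rng.integers(2**31)), min_k=min(100, k)
    )
    obs = dataset.observations.copy()
    obs["NPDE"] = np.concatenate(npdes)
    return obs


def simulate_replicates(dataset, params, model, k: int, seed: int = 0) -> np.ndarray:
    """K replicate DV matrices over a cohort's observation design.

    Returns a (K, n_obs) array aligned with the dataset's observation rows:
    each replicate redraws every subject's random effects and residual
    errors while keeping dose histories and sampling times fixed.
    """
    from .pk import _subject_arrays, concentration_from_doses_batch, add_residual_error

    rng = np.random.default_rng(seed)
    blocks = []
    for _sid, dt, da, ot, _dv, _idx in _subject_arrays(dataset):
        etas = model.sample_eta(rng, k)
        conc = concentration_from_doses_batch(params, etas, dt, da, ot)
        blocks.append(add_residual_error(conc, model, rng))
    return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# prediction-corrected VPC
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    """pcVPC summary: per-bin observed percentiles with simulated CIs."""

    table: pd.DataFrame  # bin, percentile, observed, ci_lo, ci_hi, n_obs
    coverage: float  # fraction of observed percentile points inside their CI
    percentiles: tuple[float, ...]
    n_replicates: int

    def plot(self, ax=None):
        """Draw the pcVPC panel (observed percentiles over simulated CIs)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        for q, color in zip(self.percentiles, ("tab:blue", "tab:red", "tab:blue")):
            sub = t[t["percentile"] == q]
            ax.fill_between(
                sub["bin"], sub["ci_lo"], sub["ci_hi"], alpha=0.25, color=color
            )
            ax.plot(sub["bin"], sub["observed"], "o-", color=color, label=f"p{q:g}")
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("prediction-corrected concentration (ng/mL)")
        ax.legend()
        return ax


def _assign_bins(values: np.ndarray, strategy, n_quantile_bins: int = 4):
    """Return integer bin ids and representative bin locations."""
    values = np.asarray(values, dtype=float)
    if strategy == "nominal":
        centers = np.unique(values)
        ids = np.searchsorted(centers, values)
        return ids, centers
    if strategy == "quantile":
        qs = np.quantile(values, np.linspace(0, 1, n_quantile_bins + 1))
        qs[-1] += 1e-9
        ids = np.clip(np.searchsorted(qs, values, side="right") - 1, 0, n_quantile_bins - 1)
        centers = np.array(
            [values[ids == b].mean() if np.any(ids == b) else np.nan
             for b in range(n_quantile_bins)]
        )
        keep = ~np.isnan(centers)
        remap = {old: new for new, old in enumerate(np.flatnonzero(keep))}
        ids = np.array([remap[i] for i in ids])
        return ids, centers[keep]
    raise MetricError(f"unknown binning strategy: {strategy!r}")


def pcvpc(
    obs_frame: pd.DataFrame,
    simulated_dv: np.ndarray,
    bins: str = "nominal",
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
    ci_level: float = 95.0,
    min_bin_obs: int = 3,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    ``obs_frame`` must carry columns ``time`` (binning variable; use nominal
    sampling offsets for the sparse steady-state design), ``dv`` and ``pred``.
    ``simulated_dv`` is a (K, n_obs) matrix of replicate simulated DVs at the
    same design points.  Both observed and simulated values are corrected by
    ``pcY_ij = Y_ij * median(PRED_bin) / PRED_ij``; per bin the observed
    5th/50th/95th percentiles are compared with nonparametric 95% CIs formed
    from the per-replicate percentile estimates.  Records with PRED = 0 are
    excluded with a logged reason; bins with fewer than ``min_bin_obs``
    observations are merged into their nearest neighbour.
    """
    df = obs_frame.copy().reset_index(drop=True)
    sims = np.asarray(simulated_dv, dtype=float)
    if sims.ndim != 2 or sims.shape[1] != len(df):
        raise MetricError("simulated_dv must be (K, n_obs) aligned with obs_frame")
    keep = df["pred"].to_numpy(float) > 0
    if not keep.all():
        logger.info("pcvpc: excluding %d record(s) with PRED = 0", int((~keep).sum()))
        df = df[keep].reset_index(drop=True)
        sims = sims[:, keep]
    ids, centers = _assign_bins(df["time"].to_numpy(float), bins)
    # merge sparse bins into nearest neighbour
    while True:
        counts = np.bincount(ids, minlength=len(centers))
        small = np.flatnonzero((counts > 0) & (counts < min_bin_obs))
        if small.size == 0 or np.count_nonzero(counts > 0) <= 1:
            break
        b = small[0]
        others = np.flatnonzero((counts > 0) & (np.arange(len(centers)) != b))
        nearest = others[np.argmin(np.abs(centers[others] - centers[b]))]
        logger.info(
            "pcvpc: merging bin at %g (n=%d) into bin at %g",
            centers[b], counts[b], centers[nearest],
        )
        ids[ids == b] = nearest

    pred = df["pred"].to_numpy(float)
    dv = df["dv"].to_numpy(float)
    alpha = (100.0 - ci_level) / 2.0
    rows = []
    inside = 0
    total = 0
    for b in np.unique(ids):
        m = ids == b
        med_pred = np.median(pred[m])
        corr = med_pred / pred[m]
        pc_obs = dv[m] * corr
        pc_sim = sims[:, m] * corr  # broadcasting over replicates
        for q in percentiles:
            obs_q = float(np.percentile(pc_obs, q))
            rep_q = np.percentile(pc_sim, q, axis=1)
            lo = float(np.percentile(rep_q, alpha))
            hi = float(np.percentile(rep_q, 100.0 - alpha))
            rows.append(
                {
                    "bin": float(centers[b]),
                    "percentile": q,
                    "observed": obs_q,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "n_obs": int(m.sum()),
                }
            )
            total += 1
            inside += int(lo <= obs_q <= hi)
    table = pd.DataFrame(rows)
    return VPCResult(
        table=table,
        coverage=inside / total if total else np.nan,
        percentiles=percentiles,
        n_replicates=sims.shape[0],
    )


# ---------------------------------------------------------------------------
# non-compartmental analysis
# ---------------------------------------------------------------------------


def auc_trapezoid(times, conc) -> float:
    """Linear trapezoidal AUC (ng*h/mL) over the observed span, no extrapolation."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise MetricError("AUC needs at least two points")
    if np.any(np.diff(t) <= 0):
        raise MetricError("times must be strictly increasing")
    if np.any(c < 0):
        raise MetricError("concentrations must be >= 0")
    return float(np.trapezoid(c, t))


@dataclass
class NCAResult:
    """Per-subject AUC plus per-nominal-time concentration summaries."""

    per_subject: pd.DataFrame  # subject_id, auc_0_last, n_obs
    timepoint_summary: pd.DataFrame  # time, mean, sd, n


def nca(dataset, time_column: str = "TIME") -> NCAResult:
    """Trapezoidal AUC(0-last) per subject and timepoint mean/SD summaries.

    Subjects with a single observation get NaN AUC.  The timepoint summary
    groups on ``NOMINAL_TIME`` when present (sparse designs), else on time.
    """
    obs = dataset.observations
    rows = []
    for sid, g in obs.groupby("ID", sort=False):
        t = g[time_column].to_numpy(float)
        c = g["DV"].to_numpy(float)
        t0 = t - t.min()
        auc = auc_trapezoid(t0, c) if t.size >= 2 else np.nan
        rows.append({"subject_id": sid, "auc_0_last": auc, "n_obs": t.size})
    group_col = "NOMINAL_TIME" if "NOMINAL_TIME" in obs.columns else time_column
    summary = (
        obs.groupby(group_col)["DV"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .rename(columns={group_col: "time"})
    )
    return NCAResult(per_subject=pd.DataFrame(rows), timepoint_summary=summary)
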