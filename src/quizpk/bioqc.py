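"""Bioanalytical method-validation statistics for the UPLC-MS/MS assay.

Covers the computational content of a regulatory bioanalytical validation:
weighted linear calibration with back-calculation, LLOQ acceptance
(signal-to-noise, accuracy, RSD), carryover and selectivity thresholds,
intra-/inter-day accuracy and precision from QC replicate batches, and
matrix effect / extraction recovery with internal-standard normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ThresholdConfig

logger = logging.getLogger("quizpk")

WEIGHTINGS = ("none", "1/x", "1/x2")


class AssayError(ValueError):
    """Invalid input to an assay-validation computation."""


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Weighted linear calibration: response ratio = slope * conc + intercept."""

    slope: float
    intercept: float
    r2: float
    weighting: str
    standards: tuple = ()

    def predict(self, conc):
        """Response ratio expected at a nominal concentration."""
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


def fit_calibration(
    nominal, response, weighting: str = "1/x2"
) -> CalibrationCurve:
    """Weighted linear least-squares calibration fit.

    Weights are 1 (``"none"``), 1/x (``"1/x"``) or 1/x^2 (``"1/x2"``) on the
    nominal concentration — the 1/x^2 default is the usual choice for wide
    calibration ranges, where low-end relative error matters most.  Returns
    the weighted coefficient of determination.
    """
    x = np.asarray(nominal, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size or x.size < 2:
        raise AssayError("calibration needs >= 2 matched (nominal, response) points")
    if np.unique(x).size < 2:
        raise AssayError("calibration needs >= 2 distinct nominal levels")
    if weighting not in WEIGHTINGS:
        raise AssayError(f"weighting must be one of {WEIGHTINGS}")
    if weighting != "none" and np.any(x <= 0):
        raise AssayError("1/x weighting requires positive nominal concentrations")
    w = {"none": np.ones_like(x), "1/x": 1.0 / x, "1/x2": 1.0 / x**2}[weighting]
    if np.ptp(y) == 0:
        raise AssayError("responses identical across distinct levels: degenerate fit")
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return CalibrationCurve(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        weighting=weighting,
        standards=tuple(zip(x.tolist(), y.tolist())),
    )


def back_calculate(curve: CalibrationCurve, response) -> np.ndarray | float:
    """Invert the calibration: conc = (response - intercept) / slope.

    Negative results are flagged (logged) but retained, so QC statistics
    remain honest about below-zero back-calculations.
    """
    if curve.slope == 0:
        raise AssayError("cannot back-calculate with zero slope")
    resp = np.asarray(response, dtype=float)
    conc = (resp - curve.intercept) / curve.slope
    if np.any(conc < 0):
        logger.warning(
            "%d back-calculated concentration(s) below zero (retained)",
            int(np.sum(conc < 0)),
        )
    return float(conc) if np.isscalar(response) else conc


# ---------------------------------------------------------------------------
# accuracy and precision
# ---------------------------------------------------------------------------


@dataclass
class LevelStats:
    mean: float
    sd: float
    rsd: float  # %
    accuracy: float  # % of nominal


@dataclass
class QCBatch:
    """Intra- and inter-day accuracy/precision at one nominal QC level."""

    nominal: float
    n_days: int
    n_per_day: dict
    intra_day: LevelStats
    inter_day: LevelStats
    method: str = "pooled"


def qc_statistics(
    batch: pd.DataFrame, nominal: float, method: str = "pooled"
) -> QCBatch:
    """Accuracy and precision from a replicate QC table at one level.

    ``batch`` needs columns ``day`` and ``conc`` (back-calculated ng/mL).
    Two estimator conventions are offered:

    * ``"pooled"`` (default): intra-day = mean of day means with the pooled
      within-day SD; inter-day = grand mean and total SD over all values.
    * ``"anova"``: one-way variance decomposition; intra-day SD =
      sqrt(MS_within), inter-day SD = sqrt(within + between variance
      components).

    Accuracy is 100 * mean / nominal at each aggregation level.
    """
    if nominal <= 0:
        raise AssayError("nominal concentration must be positive")
    df = batch.copy()
    if "conc" not in df or "day" not in df:
        raise AssayError("QC batch needs 'day' and 'conc' columns")
    counts = df.groupby("day")["conc"].count()
    if (counts < 2).any():
        raise AssayError("each day needs >= 2 replicates")
    day_means = df.groupby("day")["conc"].mean()
    day_vars = df.groupby("day")["conc"].var(ddof=1)
    n_days = len(day_means)
    values = df["conc"].to_numpy(float)

    if method == "pooled":
        intra_mean = float(day_means.mean())
        intra_sd = float(np.sqrt(day_vars.mean()))
        inter_mean = float(values.mean())
        inter_sd = float(values.std(ddof=1))
    elif method == "anova":
        grand = values.mean()
        ss_within = float((day_vars * (counts - 1)).sum())
        ms_within = ss_within / (len(values) - n_days)
        ss_between = float((counts * (day_means - grand) ** 2).sum())
        ms_between = ss_between / (n_days - 1) if n_days > 1 else ms_within
        n0 = counts.mean()  # balanced designs; harmonic refinement unneeded
        var_between = max(0.0, (ms_between - ms_within) / n0)
        intra_mean = float(day_means.mean())
        intra_sd = float(np.sqrt(ms_within))
        inter_mean = float(grand)
        inter_sd = float(np.sqrt(ms_within + var_between))
    else:
        raise AssayError(f"unknown estimator: {method!r}")

    if n_days < 3:
        logger.warning("QC batch has only %d day(s); statistics may be weak", n_days)
    return QCBatch(
        nominal=nominal,
        n_days=n_days,
        n_per_day=counts.to_dict(),
        intra_day=_level_stats(intra_mean, intra_sd, nominal),
        inter_day=_level_stats(inter_mean, inter_sd, nominal),
        method=method,
    )


def _level_stats(mean: float, sd: float, nominal: float) -> LevelStats:
    return LevelStats(
        mean=mean,
        sd=sd,
        rsd=100.0 * sd / mean if mean != 0 else np.inf,
        accuracy=100.0 * mean / nominal,
    )


def accuracy_percent(mean: float, nominal: float) -> float:
    """Accuracy (%) = 100 * mean / nominal."""
    if nominal <= 0:
        raise AssayError("nominal concentration must be positive")
    return 100.0 * mean / nominal


def rsd_percent(sd: float, mean: float) -> float:
    """Relative standard deviation (%) = 100 * SD / mean."""
    if mean == 0:
        raise AssayError("RSD undefined at zero mean")
    return 100.0 * sd / mean


# ---------------------------------------------------------------------------
# acceptance rules
# ---------------------------------------------------------------------------


def lloq_check(
    accuracy: float,
    rsd: float,
    snr: float,
    thresholds: ThresholdConfig | None = None,
) -> tuple[bool, list[str]]:
    """LLOQ acceptance: S/N >= 10, accuracy in [80, 120] %, RSD < 20 %.

    Returns (pass, reasons-for-failure).
    """
    th = thresholds or ThresholdConfig()
    reasons = []
    if snr < th.lloq_snr_min:
        reasons.append(f"signal-to-noise {snr:g} < {th.lloq_snr_min:g}")
    lo, hi = th.lloq_accuracy_range
    if not (lo <= accuracy <= hi):
        reasons.append(f"accuracy {accuracy:g}% outside [{lo:g}, {hi:g}]%")
    if not (rsd < th.lloq_rsd_max):
        reasons.append(f"RSD {rsd:g}% not below {th.lloq_rsd_max:g}%")
    return (not reasons, reasons)


def carryover_selectivity_check(
    blank_signal: float,
    lloq_signal: float,
    mode: str,
    thresholds: ThresholdConfig | None = None,
) -> bool:
    """Blank-signal acceptance relative to the LLOQ signal.

    Carryover passes when blank/LLOQ < 20 %; selectivity (interference in
    blank matrix) when blank/LLOQ < 2 %.  Both comparisons are strict.
    """
    th = thresholds or ThresholdConfig()
    if lloq_signal <= 0:
        raise AssayError("LLOQ signal must be positive")
    frac = blank_signal / lloq_signal
    if mode == "carryover":
        return bool(frac < th.carryover_max_frac)
    if mode == "selectivity":
        return bool(frac < th.selectivity_max_frac)
    raise AssayError(f"mode must be 'carryover' or 'selectivity', got {mode!r}")


# ---------------------------------------------------------------------------
# matrix effect and recovery
# ---------------------------------------------------------------------------


@dataclass
class MatrixRecoveryResult:
    """Matrix-effect and extraction-recovery ratios, raw and IS-normalized."""

    matrix_effect: float  # mean analyte post-spiked / neat
    is_matrix_effect: float  # same for the internal standard
    is_normalized_me: float  # mean (analyte ratio / IS ratio)
    recovery: float  # mean analyte pre-spiked / post-spiked
    is_recovery: float
    is_normalized_recovery: float
    me_rsd: float  # % across matched preparations
    recovery_rsd: float
    n: int
    excluded: int = 0


def _paired_ratios(num: np.ndarray, den: np.ndarray, label: str):
    keep = den > 0
    if not keep.all():
        logger.warning(
            "%s: excluding %d pair(s) with zero denominator area",
            label,
            int((~keep).sum()),
        )
    if not keep.any():
        raise AssayError(f"{label}: no valid area pairs")
    return num[keep] / den[keep], int((~keep).sum())


def matrix_recovery(
    neat: pd.DataFrame, post_spiked: pd.DataFrame, pre_spiked: pd.DataFrame
) -> MatrixRecoveryResult:
    """Matrix effect and recovery from matched area tables.

    Each table needs matched rows (same level/matrix order) with columns
    ``analyte_area`` and ``is_area``.  Matrix effect = mean(post/neat);
    recovery = mean(pre/post); the IS-normalized versions divide the
    analyte ratio by the IS ratio pairwise, so proportional suppression of
    analyte and IS normalizes to 1.
    """
    for name, df in (("neat", neat), ("post_spiked", post_spiked), ("pre_spiked", pre_spiked)):
        if not {"analyte_area", "is_area"} <= set(df.columns):
            raise AssayError(f"{name} table needs analyte_area and is_area columns")
    if not (len(neat) == len(post_spiked) == len(pre_spiked)):
        raise AssayError("the three preparations must have matched rows")

    a_neat = neat["analyte_area"].to_numpy(float)
    a_post = post_spiked["analyte_area"].to_numpy(float)
    a_pre = pre_spiked["analyte_area"].to_numpy(float)
    i_neat = neat["is_area"].to_numpy(float)
    i_post = post_spiked["is_area"].to_numpy(float)
    i_pre = pre_spiked["is_area"].to_numpy(float)

    me, excl1 = _paired_ratios(a_post, a_neat, "matrix effect (analyte)")
    me_is, _ = _paired_ratios(i_post, i_neat, "matrix effect (IS)")
    rec, excl2 = _paired_ratios(a_pre, a_post, "recovery (analyte)")
    rec_is, _ = _paired_ratios(i_pre, i_post, "recovery (IS)")
    n = min(me.size, me_is.size)
    norm_me = me[:n] / me_is[:n]
    m = min(rec.size, rec_is.size)
    norm_rec = rec[:m] / rec_is[:m]

    return MatrixRecoveryResult(
        matrix_effect=float(me.mean()),
        is_matrix_effect=float(me_is.mean()),
        is_normalized_me=float(norm_me.mean()),
        recovery=float(rec.mean()),
        is_recovery=float(rec_is.mean()),
        is_normalized_recovery=float(norm_rec.mean()),
        me_rsd=float(100.0 * me.std(ddof=1) / me.mean()) if me.size > 1 else 0.0,
        recovery_rsd=float(100.0 * rec.std(ddof=1) / rec.mean())
        if rec.size > 1
        else 0.0,
        n=int(me.size),
        excluded=excl1 + excl2,
    )


# ---------------------------------------------------------------------------
# batch-level convenience
# ---------------------------------------------------------------------------


def qc_report(
    raw_batch: pd.DataFrame,
    curve: CalibrationCurve,
    method: str = "pooled",
) -> pd.DataFrame:
    """Accuracy/precision table across QC levels from a raw peak-area batch.

    ``raw_batch`` carries (level, day, replicate, analyte_area, is_area);
    responses are area ratios back-calculated through ``curve``.  Returns a
    tidy table with one row per level: intra- and inter-day mean, SD,
    RSD (%) and accuracy (%).
    """
    df = raw_batch.copy()
    needed = {"level", "day", "analyte_area", "is_area"}
    if not needed <= set(df.columns):
        raise AssayError(f"raw batch needs columns {sorted(needed)}")
    df["conc"] = back_calculate(
        curve, (df["analyte_area"] / df["is_area"]).to_numpy()
    )
    rows = []
    for level, g in df.groupby("level"):
        qc = qc_statistics(g, nominal=float(level), method=method)
        rows.append(
            {
                "nominal": level,
                "intra_mean": qc.intra_day.mean,
                "intra_sd": qc.intra_day.sd,
                "intra_rsd": qc.intra_day.rsd,
                "intra_accuracy": qc.intra_day.accuracy,
                "inter_mean": qc.inter_day.mean,
                "inter_sd": qc.inter_day.sd,
                "inter_rsd": qc.inter_day.rsd,
                "inter_accuracy": qc.inter_day.accuracy,
            }
        )
    return pd.DataFrame(rows)
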