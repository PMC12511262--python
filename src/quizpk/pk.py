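"""Three-compartment oral-absorption PK engine for quizartinib.

The structural model is a linear mamillary system: a depot compartment with
first-order absorption (``ka``) of the bioavailable dose fraction (``f1``),
a central compartment (volume ``v2``) with first-order elimination
(clearance ``cl``) exchanging with two peripheral compartments (``v3``/``q3``
shallow, ``v4``/``q4`` deep).  Concentrations are central amount / ``v2``.

Units are fixed package-wide: dose mg, volumes L, clearances L/h, rate
constants 1/h, concentrations ng/mL.  The mg -> ug (x1000) conversion that
makes amount/volume come out in ug/L == ng/mL is applied exactly once, in
:func:`_dose_to_amount`.

The system is solved exactly: an eigendecomposition of the 4-state rate
matrix gives the impulse response as a sum of exponentials, superposed over
the dose history.  When the rate matrix is defective or ill-conditioned the
engine falls back to ``scipy.linalg.expm`` segment stepping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

logger = logging.getLogger("quizpk")

MG_TO_UG = 1000.0  # mg dose -> ug so that ug / L == ng/mL

#: order of random-effect slots in eta vectors
ETA_PARAMETERS = ("cl", "v2", "f1", "ka")


class DomainError(ValueError):
    """Invalid value in model-domain input (parameters, times, doses)."""


class ConvergenceError(RuntimeError):
    """Iterative computation failed to reach the requested tolerance."""

    def __init__(self, message: str, achieved_tol: float | None = None):
        super().__init__(message)
        self.achieved_tol = achieved_tol


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PKParameters:
    """Fixed structural parameters of the 3-compartment oral model.

    Parameters are apparent (oral) values: ``cl`` L/h, volumes L,
    inter-compartmental clearances L/h, ``ka`` 1/h, ``f1`` dimensionless
    bioavailability in (0, 1].  ``ke`` (elimination rate constant) and
    ``t_half`` (terminal half-life) are derived, never stored.
    """

    cl: float
    v2: float
    v3: float
    v4: float
    q3: float
    q4: float
    ka: float
    f1: float
    #: set False for realized individual parameters, where log-normal
    #: inter-individual variability may legitimately push f1 above 1
    strict: bool = True

    def __post_init__(self):
        vals = (self.cl, self.v2, self.v3, self.v4, self.q3, self.q4, self.ka, self.f1)
        if not all(np.isfinite(v) for v in vals):
            raise DomainError("all PK parameters must be finite")
        for name in ("cl", "v2", "v3", "v4", "ka", "f1"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.q3 < 0 or self.q4 < 0:
            raise DomainError("inter-compartmental clearances must be >= 0")
        if self.strict and self.f1 > 1:
            raise DomainError("f1 (bioavailability) must lie in (0, 1]")

    @property
    def ke(self) -> float:
        """Elimination rate constant cl / v2 (1/h)."""
        return self.cl / self.v2

    @property
    def t_half(self) -> float:
        """Terminal half-life (h): ln 2 over the slowest disposition eigenvalue."""
        lam = np.linalg.eigvals(_rate_matrix(self))
        neg = lam.real[lam.real < -1e-15]
        if neg.size == 0:
            raise DomainError("model has no eliminating eigenvalue")
        return float(np.log(2.0) / -neg.max())

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cl, self.v2, self.v3, self.v4, self.q3, self.q4, self.ka, self.f1]
        )


#: Default (typical-value) parameter vector for quizartinib, the fixed popPK
#: parameter medians used for external validation.
QUIZARTINIB_PARAMS = PKParameters(
    cl=1.76, v2=227.32, v3=176.03, v4=39.30, q3=26.56, q4=0.56, ka=1.68, f1=0.75
)


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: ``dose`` mg every ``interval`` h.

    ``n_doses`` may be an integer or ``"auto"``, in which case enough doses
    are administered to cover the requested time span (for transient
    profiles) or to converge (for steady state).
    """

    dose: float
    interval: float = 24.0
    n_doses: int | str = "auto"

    def __post_init__(self):
        if self.dose < 0:
            raise DomainError("dose must be >= 0")
        if self.interval <= 0:
            raise DomainError("dosing interval must be > 0")
        if self.n_doses != "auto" and (
            not isinstance(self.n_doses, (int, np.integer)) or self.n_doses < 1
        ):
            raise DomainError("n_doses must be a positive integer or 'auto'")


@dataclass(frozen=True)
class RandomEffectsModel:
    """Log-normal inter-individual variability plus combined residual error.

    ``omega`` is the variance-covariance matrix of the log-scale random
    effects on (cl, v2, f1, ka) in that order; a parameter with zero row and
    column carries no effect.  Residual error is combined proportional +
    additive: DV = C (1 + eps_p) + eps_a with eps_p ~ N(0, sigma_prop^2) and
    eps_a ~ N(0, sigma_add^2) ng/mL.
    """

    omega: np.ndarray = field(
        default_factory=lambda: np.diag([0.09, 0.09, 0.04, 0.0])
    )
    sigma_prop: float = 0.20
    sigma_add: float = 1.0

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (len(ETA_PARAMETERS),) * 2:
            raise DomainError(
                f"omega must be {len(ETA_PARAMETERS)}x{len(ETA_PARAMETERS)} "
                f"on {ETA_PARAMETERS}"
            )
        if not np.allclose(om, om.T):
            raise DomainError("omega must be symmetric")
        if np.linalg.eigvalsh(om).min() < -1e-12:
            raise DomainError("omega must be positive semidefinite")
        object.__setattr__(self, "omega", om)
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise DomainError("residual SDs must be >= 0")

    @property
    def affected(self) -> tuple[int, ...]:
        """Indices of eta slots with nonzero variance."""
        return tuple(int(i) for i in np.flatnonzero(np.diag(self.omega) > 0))

    def sample_eta(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` eta vectors ~ MVN(0, omega); shape (n, 4)."""
        return rng.multivariate_normal(
            np.zeros(len(ETA_PARAMETERS)), self.omega, size=n, method="svd"
        )


@dataclass(frozen=True)
class IndividualParameters:
    """A subject's realized parameters: base * exp(eta) on affected slots."""

    base: PKParameters
    eta: np.ndarray
    realized: PKParameters = None  # type: ignore[assignment]

    def __post_init__(self):
        eta = np.asarray(self.eta, dtype=float)
        if eta.shape != (len(ETA_PARAMETERS),):
            raise DomainError(
                f"eta must have length {len(ETA_PARAMETERS)} ({ETA_PARAMETERS})"
            )
        object.__setattr__(self, "eta", eta)
        if self.realized is None:
            kwargs = {
                name: getattr(self.base, name) * float(np.exp(eta[i]))
                for i, name in enumerate(ETA_PARAMETERS)
            }
            realized = replace(self.base, strict=False, **kwargs)
            object.__setattr__(self, "realized", realized)


def apply_iiv(
    base: PKParameters, eta: np.ndarray, model: RandomEffectsModel
) -> IndividualParameters:
    """Realize individual parameters base_i * exp(eta_i) on (cl, v2, f1, ka)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (model.omega.shape[0],):
        raise DomainError(
            f"eta has shape {eta.shape}, expected ({model.omega.shape[0]},)"
        )
    return IndividualParameters(base=base, eta=eta)


# ---------------------------------------------------------------------------
# linear-system machinery
# ---------------------------------------------------------------------------


def _rate_matrix(p: PKParameters) -> np.ndarray:
    """4-state rate matrix over (depot, central, peripheral-3, peripheral-4)."""
    k20 = p.cl / p.v2
    k23, k32 = p.q3 / p.v2, p.q3 / p.v3
    k24, k42 = p.q4 / p.v2, p.q4 / p.v4
    return np.array(
        [
            [-p.ka, 0.0, 0.0, 0.0],
            [p.ka, -(k20 + k23 + k24), k32, k42],
            [0.0, k23, -k32, 0.0],
            [0.0, k24, 0.0, -k42],
        ]
    )


def _dose_to_amount(dose_mg: float, f1: float) -> float:
    """Bioavailable depot amount in ug (the package's single mg->ug site)."""
    return f1 * dose_mg * MG_TO_UG


class _ImpulseSolution:
    """Central-compartment impulse response as a sum of exponentials.

    For a unit amount placed in the depot at t=0 the central concentration is
    ``c(t) = sum_i w_i exp(lambda_i t)``.  Falls back to matrix-exponential
    evaluation when the eigenvector matrix is ill-conditioned (e.g. ka equal
    to a disposition eigenvalue).
    """

    _COND_LIMIT = 1e10

    def __init__(self, params: PKParameters):
        self.params = params
        A = _rate_matrix(params)
        self._A = A
        lam, V = np.linalg.eig(A)
        self._use_eig = np.linalg.cond(V) < self._COND_LIMIT
        if self._use_eig:
            e0 = np.zeros(4)
            e0[0] = 1.0
            coef = np.linalg.solve(V, e0)
            # concentration weights for the central row
            self.lam = lam
            self.w = V[1, :] * coef / params.v2
        else:  # pragma: no cover - defective-matrix fallback
            logger.warning(
                "rate matrix near-defective; using expm fallback (cond >= %g)",
                self._COND_LIMIT,
            )

    def conc_unit(self, t: np.ndarray) -> np.ndarray:
        """Concentration per unit depot amount at times t >= 0 (ug/L per ug)."""
        t = np.asarray(t, dtype=float)
        if self._use_eig:
            out = np.real(np.exp(np.outer(t, self.lam)) @ self.w)
        else:  # pragma: no cover
            out = np.array(
                [(expm(self._A * ti) @ [1.0, 0, 0, 0])[1] / self.params.v2 for ti in t]
            )
        return out

    def steady_state_unit(self, tau: float, t_after_dose: np.ndarray) -> np.ndarray:
        """Steady-state concentration per unit depot dose every ``tau`` h.

        Analytic geometric-series superposition:
        ``sum_k c(t + k tau) = sum_i w_i exp(lambda_i t) / (1 - exp(lambda_i tau))``.
        """
        t = np.asarray(t_after_dose, dtype=float)
        if not self._use_eig:  # pragma: no cover
            return _steady_state_by_simulation(self, tau, t)
        denom = 1.0 - np.exp(self.lam * tau)
        if np.any(np.abs(denom) < 1e-14):
            # a non-eliminating mode that the depot feeds would accumulate
            # without bound; weights on such modes must vanish
            bad = np.abs(denom) < 1e-14
            if np.any(np.abs(self.w[bad]) > 1e-12):
                raise ConvergenceError("non-dissipating mode receives dose mass")
            denom = np.where(bad, 1.0, denom)
            w = np.where(bad, 0.0, self.w)
        else:
            w = self.w
        return np.real(np.exp(np.outer(t, self.lam)) @ (w / denom))


def _steady_state_by_simulation(
    sol: _ImpulseSolution,
    tau: float,
    t: np.ndarray,
    rtol: float = 1e-8,
    max_doses: int = 100_000,
) -> np.ndarray:  # pragma: no cover - fallback path
    prev = np.zeros_like(t, dtype=float)
    total = np.zeros_like(t, dtype=float)
    for k in range(max_doses):
        total = total + sol.conc_unit(t + k * tau)
        delta = np.max(np.abs(total - prev) / np.maximum(np.abs(total), 1e-30))
        if k > 0 and delta < rtol:
            return total
        prev = total.copy()
    raise ConvergenceError(
        f"steady state not reached within {max_doses} doses", achieved_tol=float(delta)
    )


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.size and (not np.all(np.isfinite(t)) or np.any(t < 0)):
        raise DomainError("times must be finite and non-negative")
    return t


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def concentration_from_doses(
    params: PKParameters,
    dose_times,
    dose_amounts_mg,
    times,
) -> np.ndarray:
    """Central concentration (ng/mL) from an arbitrary oral dose history.

    Superposes the impulse response over every administered dose; doses given
    after an observation time contribute nothing to it.
    """
    t = _check_times(times)
    dt = np.asarray(dose_times, dtype=float)
    da = np.asarray(dose_amounts_mg, dtype=float)
    if dt.shape != da.shape:
        raise DomainError("dose_times and dose_amounts must align")
    if np.any(da < 0):
        raise DomainError("dose amounts must be >= 0")
    sol = _ImpulseSolution(params)
    out = np.zeros_like(t)
    for td, amt in zip(dt, da):
        if amt == 0:
            continue
        elapsed = t - td
        mask = elapsed >= 0
        if np.any(mask):
            out[mask] += _dose_to_amount(amt, params.f1) * sol.conc_unit(elapsed[mask])
    return out


def concentration_profile(
    params: PKParameters, regimen: DosingRegimen, times
) -> np.ndarray:
    """Multiple-dose concentration profile (ng/mL) at absolute times (h).

    Doses are given at 0, tau, 2 tau, ...; with ``n_doses="auto"`` dosing
    continues over the whole requested span.
    """
    t = _check_times(times)
    if regimen.n_doses == "auto":
        n = int(np.floor(t.max(initial=0.0) / regimen.interval)) + 1
    else:
        n = int(regimen.n_doses)
    dose_times = np.arange(n) * regimen.interval
    return concentration_from_doses(
        params, dose_times, np.full(n, regimen.dose), t
    )


def steady_state_profile(
    params: PKParameters, regimen: DosingRegimen, times_after_dose
) -> np.ndarray:
    """Within-interval steady-state profile (ng/mL).

    Computed by the exact geometric-series superposition of the impulse
    response; the simulate-to-convergence route (relative tolerance 1e-8) is
    kept as a fallback for defective rate matrices.
    """
    t = _check_times(times_after_dose)
    sol = _ImpulseSolution(params)
    return _dose_to_amount(regimen.dose, params.f1) * sol.steady_state_unit(
        regimen.interval, t
    )


def amounts_profile(
    params: PKParameters, regimen: DosingRegimen, times
) -> np.ndarray:
    """Compartment amounts (ug) over time, including cumulative elimination.

    Returns an array of shape (len(times), 5): depot, central, peripheral-3,
    peripheral-4, eliminated.  Used for mass-balance verification; computed
    by matrix-exponential stepping on the augmented 5-state system.
    """
    t = _check_times(times)
    A4 = _rate_matrix(params)
    A = np.zeros((5, 5))
    A[:4, :4] = A4
    A[4, 1] = params.cl / params.v2  # elimination flux accumulator
    if regimen.n_doses == "auto":
        n = int(np.floor(t.max(initial=0.0) / regimen.interval)) + 1
    else:
        n = int(regimen.n_doses)
    amt = _dose_to_amount(regimen.dose, params.f1)
    out = np.zeros((t.size, 5))
    for k in range(n):
        elapsed = t - k * regimen.interval
        mask = elapsed >= 0
        for j in np.flatnonzero(mask):
            out[j] += amt * expm(A * elapsed[j])[:, 0]
    return out


def concentration_from_doses_batch(
    params: PKParameters,
    etas: np.ndarray,
    dose_times,
    dose_amounts_mg,
    times,
) -> np.ndarray:
    """Concentrations for many eta draws at once; shape (n_eta, n_times).

    Vectorized realization of ``base * exp(eta)`` on (cl, v2, f1, ka)
    followed by a batched eigendecomposition of the per-draw rate matrices;
    numerically identical to looping :func:`concentration_from_doses` over
    draws.  Rows whose rate matrix is near-defective fall back to the
    scalar path.
    """
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    t = _check_times(times)
    dt = np.asarray(dose_times, dtype=float)
    da = np.asarray(dose_amounts_mg, dtype=float)
    n = etas.shape[0]
    cl = params.cl * np.exp(etas[:, 0])
    v2 = params.v2 * np.exp(etas[:, 1])
    f1 = params.f1 * np.exp(etas[:, 2])
    ka = params.ka * np.exp(etas[:, 3])
    k20, k23, k24 = cl / v2, params.q3 / v2, params.q4 / v2
    k32 = params.q3 / params.v3
    k42 = params.q4 / params.v4
    A = np.zeros((n, 4, 4))
    A[:, 0, 0] = -ka
    A[:, 1, 0] = ka
    A[:, 1, 1] = -(k20 + k23 + k24)
    A[:, 1, 2] = k32
    A[:, 1, 3] = k42
    A[:, 2, 1] = k23
    A[:, 2, 2] = -k32
    A[:, 3, 1] = k24
    A[:, 3, 3] = -k42
    lam, V = np.linalg.eig(A)
    e0 = np.zeros((n, 4))
    e0[:, 0] = 1.0
    with np.errstate(all="ignore"):
        coef = np.linalg.solve(V, e0[..., None])[..., 0]
    w = V[:, 1, :] * coef / v2[:, None]
    conc = np.zeros((n, t.size))
    for td, amt in zip(dt, da):
        if amt == 0:
            continue
        el = t - td
        m = el >= 0
        if np.any(m):
            conc[:, m] += (
                amt
                * MG_TO_UG
                * np.real(
                    np.exp(lam[:, None, :] * el[m][None, :, None]) @ w[..., None]
                )[..., 0]
            )
    conc *= f1[:, None]
    bad = ~np.all(np.isfinite(conc), axis=1)
    for i in np.flatnonzero(bad):  # pragma: no cover - defective-matrix rows
        ind = IndividualParameters(base=params, eta=etas[i])
        conc[i] = concentration_from_doses(ind.realized, dt, da, t)
    return conc


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def add_residual_error(
    conc: np.ndarray,
    model: RandomEffectsModel,
    rng: np.random.Generator,
    max_resample: int = 100,
) -> np.ndarray:
    """DV = C (1 + eps_prop) + eps_add, negative draws resampled."""
    conc = np.asarray(conc, dtype=float)
    if model.sigma_prop == 0 and model.sigma_add == 0:
        logger.warning("both residual SDs are zero; returning noiseless profile")
        return conc.copy()
    dv = conc * (1 + rng.normal(0, model.sigma_prop, conc.shape)) + rng.normal(
        0, model.sigma_add, conc.shape
    )
    for _ in range(max_resample):
        neg = dv < 0
        if not np.any(neg):
            break
        dv[neg] = conc[neg] * (
            1 + rng.normal(0, model.sigma_prop, int(neg.sum()))
        ) + rng.normal(0, model.sigma_add, int(neg.sum()))
    np.maximum(dv, 0.0, out=dv)
    return dv


def simulate_observations(
    ind: IndividualParameters,
    regimen: DosingRegimen,
    times,
    model: RandomEffectsModel,
    seed,
) -> np.ndarray:
    """Simulate observed concentrations for one subject (ng/mL).

    Reproducible for a given seed; negative residual draws are resampled.
    """
    rng = _as_rng(seed)
    conc = concentration_profile(ind.realized, regimen, times)
    return add_residual_error(conc, model, rng)


# ---------------------------------------------------------------------------
# population and individual prediction
# ---------------------------------------------------------------------------


def _subject_arrays(dataset):
    """Yield (subject_id, dose_times, dose_amts, obs_times, dv, obs_index)."""
    df = dataset.frame
    for sid, g in df.groupby("ID", sort=False):
        doses = g[g["EVID"] == 1]
        obs = g[g["EVID"] == 0]
        yield (
            sid,
            doses["TIME"].to_numpy(float),
            doses["AMT"].to_numpy(float),
            obs["TIME"].to_numpy(float),
            obs["DV"].to_numpy(float),
            obs.index.to_numpy(),
        )


def population_predict(dataset, params: PKParameters) -> np.ndarray:
    """Typical-value predictions PRED (ng/mL), one per observation row.

    Random effects are fixed at zero; each subject's recorded dose history
    and actual sampling times are used.  Ordering matches the dataset's
    observation rows (sorted by subject then time).
    """
    preds = []
    for sid, dt, da, ot, _dv, _idx in _subject_arrays(dataset):
        try:
            preds.append(concentration_from_doses(params, dt, da, ot))
        except DomainError as err:
            raise DomainError(f"subject {sid}: {err}") from err
    return np.concatenate(preds) if preds else np.empty(0)


@dataclass
class MAPResult:
    """MAP empirical-Bayes estimate for one subject."""

    eta: np.ndarray
    ipred: np.ndarray
    objective: float
    converged: bool
    n_starts: int
    message: str = ""


def _map_objective(
    eta_aff: np.ndarray,
    affected: tuple[int, ...],
    params: PKParameters,
    model: RandomEffectsModel,
    omega_inv: np.ndarray,
    dose_times: np.ndarray,
    dose_amts: np.ndarray,
    obs_times: np.ndarray,
    dv: np.ndarray,
) -> float:
    eta = np.zeros(len(ETA_PARAMETERS))
    eta[list(affected)] = eta_aff
    ind = IndividualParameters(base=params, eta=eta)
    conc = concentration_from_doses(ind.realized, dose_times, dose_amts, obs_times)
    var = (model.sigma_prop * conc) ** 2 + model.sigma_add**2
    var = np.maximum(var, 1e-12)
    return float(
        np.sum((dv - conc) ** 2 / var + np.log(var)) + eta_aff @ omega_inv @ eta_aff
    )


def map_estimate(
    obs_times,
    dv,
    dose_times,
    dose_amounts_mg,
    params: PKParameters,
    model: RandomEffectsModel,
    n_restarts: int = 3,
    restart_seed: int = 0,
) -> MAPResult:
    """MAP (empirical-Bayes) estimate of a subject's random effects.

    Minimizes ``sum_j [(DV_j - C_j(eta))^2 / var_j + log var_j]
    + eta' Omega^-1 eta`` over the eta slots with nonzero omega variance,
    starting from eta = 0.  On optimizer failure, up to ``n_restarts``
    jittered restarts are tried and the lowest objective wins; the result is
    flagged rather than raised.
    """
    from scipy.optimize import minimize

    obs_times = np.asarray(obs_times, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if dv.size == 0:
        raise DomainError("MAP estimation requires at least one observation")
    affected = model.affected
    if not affected:
        ipred = concentration_from_doses(params, dose_times, dose_amounts_mg, obs_times)
        return MAPResult(
            eta=np.zeros(len(ETA_PARAMETERS)),
            ipred=ipred,
            objective=np.nan,
            converged=True,
            n_starts=0,
            message="no random effects in model",
        )
    om_aff = model.omega[np.ix_(affected, affected)]
    if np.linalg.eigvalsh(om_aff).min() <= 0:
        raise DomainError("omega must be positive definite on affected parameters")
    omega_inv = np.linalg.inv(om_aff)
    args = (
        affected,
        params,
        model,
        omega_inv,
        np.asarray(dose_times, dtype=float),
        np.asarray(dose_amounts_mg, dtype=float),
        obs_times,
        dv,
    )
    rng = np.random.default_rng(restart_seed)
    starts = [np.zeros(len(affected))]
    best = None
    for i, x0 in enumerate(starts):
        res = minimize(
            _map_objective, x0, args=args, method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success:
            break
        if i == len(starts) - 1 and len(starts) < 1 + n_restarts:
            starts.append(rng.normal(0, 0.3, len(affected)))
    # simplex polish: the quadratic model of L-BFGS-B can stall on the sharp
    # valleys a near-noiseless residual model produces
    polish = minimize(
        _map_objective, best.x, args=args, method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
    )
    if polish.fun < best.fun:
        best = polish
    eta = np.zeros(len(ETA_PARAMETERS))
    eta[list(affected)] = best.x
    ind = IndividualParameters(base=params, eta=eta)
    ipred = concentration_from_doses(
        ind.realized, dose_times, dose_amounts_mg, obs_times
    )
    if not best.success:
        logger.warning("MAP optimizer did not converge: %s", best.message)
    return MAPResult(
        eta=eta,
        ipred=ipred,
        objective=float(best.fun),
        converged=bool(best.success),
        n_starts=len(starts),
        message=str(best.message),
    )


def individual_predict(
    dataset, params: PKParameters, model: RandomEffectsModel
) -> tuple[np.ndarray, dict]:
    """MAP individual predictions IPRED for every observation in a cohort.

    Returns (ipred array aligned with observation rows, dict of per-subject
    :class:`MAPResult`).
    """
    ipreds, results = [], {}
    for sid, dt, da, ot, dv, _idx in _subject_arrays(dataset):
        res = map_estimate(ot, dv, dt, da, params, model)
        results[sid] = res
        ipreds.append(res.ipred)
    return (np.concatenate(ipreds) if ipreds else np.empty(0)), results
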