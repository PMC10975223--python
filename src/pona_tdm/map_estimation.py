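"""Individual (empirical-Bayes / MAP) PK estimation from sparse random-time samples.

Outpatient ponatinib levels are drawn at whatever time the control visit
happens to fall, not at trough.  Given a population prior (typical parameters
theta, log-normal between-subject variability Omega, combined residual error)
and one or more timed concentration samples, the MAP estimate minimises

    -2 [ sum_j log N(y_j; f_j, g_j^2) + log N(eta; 0, Omega) ]

over the log-scale deviations eta, where f_j is the model prediction at the
sample's dosing context (steady-state concentration at the annotated
time-since-last-dose) and g_j = sigma_add + sigma_prop * f_j.  Individual
parameters are theta * exp(eta).  The individualised steady-state trough
(C_min) is the quantity of clinical interest.

Optimisation is multi-start local (eta = 0 plus seeded perturbed starts,
L-BFGS-B within |eta_i| <= 5 omega_i), so results are deterministic given
(samples, prior, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import norm

from .exceptions import DomainError
from .pk import (
    DEFAULT_PK_PARAMETERS,
    DosingRegimen,
    PKParameters,
    _reduced_matrix_and_dose,
    steady_state_cmin,
)

#: assay lower limit of quantitation, ng/mL
LLOQ_NG_PER_ML = 5.0

#: PK parameters eligible for log-normal between-subject variability
MUTABLE_PARAMS = ("CL", "Vc", "Q", "Vp", "ktr", "ka")

#: supported handling modes for below-LLOQ samples
BLQ_MODES = ("halve", "exclude", "as_is", "censored")


@dataclass(frozen=True)
class PopulationPrior:
    """Population-typical parameters with log-normal between-subject variability.

    ``omega`` maps parameter names (subset of :data:`MUTABLE_PARAMS`) to
    log-scale standard deviations; entries define the random-effect dimension.
    ``omega_cov`` optionally supplies a full log-scale covariance in the key
    order of ``omega`` (diagonal built from ``omega`` otherwise).
    """

    theta: PKParameters = DEFAULT_PK_PARAMETERS
    omega: Mapping[str, float] = field(
        default_factory=lambda: {"CL": 0.40, "Vc": 0.25, "ktr": 0.25, "ka": 0.25}
    )
    omega_cov: np.ndarray | None = None
    sigma_prop: float = 0.2
    sigma_add: float = 0.5

    def __post_init__(self):
        for k, v in self.omega.items():
            if k not in MUTABLE_PARAMS:
                raise DomainError(f"unknown random-effect parameter {k!r}")
            if not (math.isfinite(v) and v >= 0):
                raise DomainError(f"omega[{k!r}] must be finite and >= 0, got {v!r}")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise DomainError("residual error components must be >= 0")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise DomainError("residual error model must not be identically zero")
        if self.omega_cov is not None:
            cov = np.asarray(self.omega_cov, dtype=float)
            k = len(self.omega)
            if cov.shape != (k, k):
                raise DomainError(f"omega_cov must be {k}x{k}")
            if not np.allclose(cov, cov.T):
                raise DomainError("omega_cov must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise DomainError("omega_cov must be positive semi-definite")
            object.__setattr__(self, "omega_cov", cov)

    @property
    def eta_names(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.omega.items() if v > 0)

    def covariance(self) -> np.ndarray:
        """Log-scale covariance restricted to the active (omega > 0) dimensions."""
        names = list(self.omega)
        active = [i for i, k in enumerate(names) if self.omega[k] > 0]
        if self.omega_cov is not None:
            return self.omega_cov[np.ix_(active, active)]
        return np.diag([self.omega[names[i]] ** 2 for i in active])


#: package default prior (synthetic calibration, see docs/methods.md)
DEFAULT_PRIOR = PopulationPrior()


@dataclass(frozen=True)
class ConcentrationSample:
    """One random-time plasma measurement with its dosing context."""

    t_since_last_dose_h: float
    conc_ng_per_ml: float
    dose_mg: float
    tau_h: float = 24.0
    below_loq: bool = False

    def __post_init__(self):
        if not (0 <= self.t_since_last_dose_h <= self.tau_h):
            raise DomainError(
                f"t_since_last_dose_h must lie in [0, tau_h], got {self.t_since_last_dose_h!r}"
            )
        if not (math.isfinite(self.conc_ng_per_ml) and self.conc_ng_per_ml >= 0):
            raise DomainError(f"concentration must be finite and >= 0, got {self.conc_ng_per_ml!r}")
        if not (math.isfinite(self.dose_mg) and self.dose_mg > 0):
            raise DomainError(f"dose_mg must be finite and > 0, got {self.dose_mg!r}")


@dataclass(frozen=True)
class IndividualEstimate:
    eta: dict[str, float]
    params: PKParameters
    predicted_cmin: float
    objective: float
    converged: bool


class _SteadyStatePredictor:
    """Steady-state concentration predictions for a fixed parameter vector.

    Caches the matrix exponential per dosing interval and per sampling offset;
    the pre-dose steady state is obtained by the exact linear fixed-point
    solve, and scales linearly with dose.
    """

    def __init__(self, params: PKParameters):
        self.params = params
        self.A, self._d_unit = _reduced_matrix_and_dose(params, 1.0)
        self._i_central = params.n_transit + 1
        self._ss_unit: dict[float, np.ndarray] = {}
        self._prop: dict[tuple[float, float], np.ndarray] = {}

    def _ss_state_unit(self, tau: float) -> np.ndarray:
        x = self._ss_unit.get(tau)
        if x is None:
            E = expm(self.A * tau)
            x = np.linalg.solve(np.eye(len(self._d_unit)) - E, E @ self._d_unit)
            self._ss_unit[tau] = x
        return x

    def conc(self, dose_mg: float, tau: float, t: float) -> float:
        P = self._prop.get((tau, t))
        if P is None:
            P = expm(self.A * t)
            self._prop[(tau, t)] = P
        x = dose_mg * (self._ss_state_unit(tau) + self._d_unit)
        return float((P @ x)[self._i_central] / self.params.Vc * 1000.0)

    def cmin(self, dose_mg: float, tau: float) -> float:
        x = dose_mg * self._ss_state_unit(tau)
        return float(x[self._i_central] / self.params.Vc * 1000.0)


def _neg2_log_posterior(
    eta_vec: np.ndarray,
    names: tuple[str, ...],
    prior: PopulationPrior,
    samples: Sequence[ConcentrationSample],
    omega_inv: np.ndarray,
    log_det_term: float,
    blq: str,
    lloq: float,
) -> float:
    params = prior.theta.with_log_deviations(dict(zip(names, eta_vec)))
    pred = _SteadyStatePredictor(params)
    ll = 0.0
    for s in samples:
        f = pred.conc(s.dose_mg, s.tau_h, s.t_since_last_dose_h)
        g = prior.sigma_add + prior.sigma_prop * f
        g = max(g, 1e-9)
        if s.below_loq:
            if blq == "exclude":
                continue
            if blq == "censored":
                ll += math.log(max(norm.cdf((lloq - f) / g), 1e-300))
                continue
            if blq == "halve":
                y = lloq / 2.0
                # additive floor: an imputed value should not be weighted as
                # if it were a precise measurement
                g = max(g, lloq / 4.0)
            else:  # as_is
                y = s.conc_ng_per_ml
        else:
            y = s.conc_ng_per_ml
        ll += -0.5 * math.log(2 * math.pi * g * g) - 0.5 * ((y - f) / g) ** 2
    prior_term = float(eta_vec @ omega_inv @ eta_vec) + log_det_term
    return -2.0 * ll + prior_term


def map_estimate(
    samples: Sequence[ConcentrationSample],
    prior: PopulationPrior = DEFAULT_PRIOR,
    *,
    regimen: DosingRegimen | None = None,
    blq: str = "halve",
    seed: int = 0,
    n_perturbed_starts: int = 4,
) -> IndividualEstimate:
    """MAP estimate of individual PK parameters and steady-state trough.

    ``regimen`` fixes the dosing context used for the reported
    ``predicted_cmin``; by default the last sample's dose and interval are
    used, which is the usual TDM situation of a patient on a stable regimen.
    With no samples the estimate is the prior mode (eta = 0) and ``regimen``
    is required.
    """
    if blq not in BLQ_MODES:
        raise DomainError(f"blq must be one of {BLQ_MODES}, got {blq!r}")
    samples = list(samples)
    if regimen is None:
        if not samples:
            raise DomainError("regimen is required when no samples are given")
        last = samples[-1]
        regimen = DosingRegimen(dose_mg=last.dose_mg, tau_h=last.tau_h)

    names = prior.eta_names
    k = len(names)
    if k == 0 or not samples:
        params = prior.theta
        return IndividualEstimate(
            eta={n: 0.0 for n in names},
            params=params,
            predicted_cmin=steady_state_cmin(params, regimen),
            objective=_objective_at(np.zeros(k), names, prior, samples, blq) if k else 0.0,
            converged=True,
        )

    cov = prior.covariance()
    omega_inv = np.linalg.inv(cov)
    sign, logdet = np.linalg.slogdet(2 * math.pi * cov)
    log_det_term = float(logdet)
    obj = lambda v: _neg2_log_posterior(
        v, names, prior, samples, omega_inv, log_det_term, blq, LLOQ_NG_PER_ML
    )
    sds = np.array([prior.omega[n] for n in names])
    bounds = [(-5 * s, 5 * s) for s in sds]
    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    for _ in range(n_perturbed_starts):
        starts.append(np.clip(rng.normal(0.0, sds), -4.9 * sds, 4.9 * sds))

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # the optimizer must never end above the prior mode
    f0 = obj(np.zeros(k))
    if f0 < best.fun:
        best_x, best_f = np.zeros(k), f0
    else:
        best_x, best_f = best.x, float(best.fun)

    eta = dict(zip(names, (float(v) for v in best_x)))
    params = prior.theta.with_log_deviations(eta)
    pred = _SteadyStatePredictor(params)
    return IndividualEstimate(
        eta=eta,
        params=params,
        predicted_cmin=pred.cmin(regimen.dose_mg, regimen.tau_h),
        objective=best_f,
        converged=any_success,
    )


def _objective_at(eta_vec, names, prior, samples, blq):
    if len(names) == 0:
        # pure likelihood term at the prior mode (no random effects)
        cov = np.eye(0)
        return _neg2_log_posterior(
            np.zeros(0), names, prior, samples, cov, 0.0, blq, LLOQ_NG_PER_ML
        )
    cov = prior.covariance()
    return _neg2_log_posterior(
        np.asarray(eta_vec, dtype=float),
        names,
        prior,
        samples,
        np.linalg.inv(cov),
        float(np.linalg.slogdet(2 * math.pi * cov)[1]),
        blq,
        LLOQ_NG_PER_ML,
    )


def predict_cmin_from_single_sample(
    sample: ConcentrationSample,
    prior: PopulationPrior = DEFAULT_PRIOR,
    *,
    blq: str = "halve",
    seed: int = 0,
) -> float:
    """Predicted steady-state trough from one random-time sample (MAP shrinkage)."""
    est = map_estimate([sample], prior, blq=blq, seed=seed)
    return est.predicted_cmin


def read_samples_csv(path) -> dict[str, list[ConcentrationSample]]:
    """Read samples grouped by patient from CSV.

    Columns: patient_id, dose_mg, tau_h, t_since_dose_h, conc_ng_ml, bloq_flag.
    """
    import pandas as pd

    from .exceptions import SchemaError

    df = pd.read_csv(path)
    required = ["patient_id", "dose_mg", "tau_h", "t_since_dose_h", "conc_ng_ml", "bloq_flag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError([f"missing column {c!r}" for c in missing])
    out: dict[str, list[ConcentrationSample]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["patient_id"]), []).append(
            ConcentrationSample(
                t_since_last_dose_h=float(row["t_since_dose_h"]),
                conc_ng_per_ml=float(row["conc_ng_ml"]),
                dose_mg=float(row["dose_mg"]),
                tau_h=float(row["tau_h"]),
                below_loq=bool(row["bloq_flag"]),
            )
        )
    return out
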