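"""Model family for joint (shared-component) disease mapping.

Two related diseases are observed on an area x gender x age lattice.  Cell
counts are Poisson with mean ``n * r`` and the log-rates combine:

* per-disease intercepts ``alpha_d``,
* a latent spatial surface ``kappa`` (common or gender-specific) shared by
  both diseases, entering disease 1 scaled by ``delta`` and disease 2 by
  ``1/delta``,
* an unstructured iid area effect ``u`` for diseases that deviate from the
  shared surface,
* age or age-gender effects ``eta``.

``kappa`` carries an intrinsic CAR (Besag) prior with precision
``tau_kappa * R`` per gender block; it is identified by sum-to-zero
constraints per gender (and per connected component).  ``eta`` is iid
normal and, because its level is confounded with the intercepts, it is
centred to sum to zero overall.  ``u`` is proper iid normal and needs no
constraint.

Convention: every ``tau`` in this package is a *precision* (inverse
variance), including ``tau_u`` and ``tau_eta`` — the standard
disease-mapping parameterisation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
from scipy.special import gammaln

from .graph import StructureMatrix

LOG_2PI = math.log(2.0 * math.pi)

DISEASE_LABELS = ("lung", "locp")
GENDER_LABELS = ("male", "female")
DEFAULT_AGE_LABELS = ("30-44", "45-59", "60-74", "75-89", "90+")


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CountData:
    """Deaths and populations on the disease x area x gender x age lattice.

    ``O`` and ``n`` have shape ``(2, I, 2, J)`` indexed by
    (disease, area, gender, age group); disease 1 is the abundant disease
    (lung), disease 2 the sparse one (lip-oral-cavity-pharynx).  Cells with
    ``n == 0`` must have ``O == 0`` and are treated as unobserved.
    """

    O: np.ndarray
    n: np.ndarray
    area_ids: tuple[str, ...]
    age_labels: tuple[str, ...] = DEFAULT_AGE_LABELS
    disease_labels: tuple[str, ...] = DISEASE_LABELS
    gender_labels: tuple[str, ...] = GENDER_LABELS

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O)
        self.n = np.asarray(self.n, dtype=float)
        self.area_ids = tuple(self.area_ids)
        self.age_labels = tuple(self.age_labels)
        self.validate()

    def validate(self) -> None:
        if self.O.shape != self.n.shape:
            raise ValueError("O and n shapes differ")
        if self.O.ndim != 4 or self.O.shape[0] != 2 or self.O.shape[2] != 2:
            raise ValueError(f"expected shape (2, I, 2, J), got {self.O.shape}")
        if self.O.shape[1] != len(self.area_ids):
            raise ValueError("area_ids length does not match data")
        if self.O.shape[3] != len(self.age_labels):
            raise ValueError("age_labels length does not match data")
        if np.any(self.O < 0):
            raise ValueError("negative death counts")
        if np.any(self.n < 0):
            raise ValueError("negative populations")
        if np.any((self.O > 0) & (self.n == 0)):
            raise ValueError("deaths observed in a cell with zero population at risk")

    @property
    def I(self) -> int:  # noqa: E743 - conventional symbol for number of areas
        return self.O.shape[1]

    @property
    def J(self) -> int:
        return self.O.shape[3]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of observed cells (``n > 0``)."""
        return self.n > 0


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Which components of the model family are switched on.

    ``shared_spatial``: ``"none"`` (no spatial term), ``"common"`` (one
    surface for both genders) or ``"by_gender"``.  ``specific_unstructured``
    lists the diseases (1-based) carrying an iid area effect.
    ``age_effect``: ``"none"``, ``"by_age"`` or ``"by_age_gender"``.
    """

    shared_spatial: str = "by_gender"
    specific_unstructured: frozenset = frozenset({2})
    age_effect: str = "by_age_gender"
    intercepts: bool = True

    def __post_init__(self) -> None:
        if self.shared_spatial not in ("none", "common", "by_gender"):
            raise ValueError(f"unknown shared_spatial {self.shared_spatial!r}")
        if self.age_effect not in ("none", "by_age", "by_age_gender"):
            raise ValueError(f"unknown age_effect {self.age_effect!r}")
        dis = frozenset(int(d) for d in self.specific_unstructured)
        if not dis <= {1, 2}:
            raise ValueError("specific_unstructured must be a subset of {1, 2}")
        object.__setattr__(self, "specific_unstructured", dis)

    @classmethod
    def base(cls) -> "ModelSpec":
        """The simplest shared model: one common surface, nothing else."""
        return cls(shared_spatial="common", specific_unstructured=frozenset(),
                   age_effect="none", intercepts=False)

    @classmethod
    def selected(cls) -> "ModelSpec":
        """Gender-specific shared surface + disease-2 iid effect + age-gender effects."""
        return cls()

    # -- derived dimensions -------------------------------------------------
    @property
    def has_spatial(self) -> bool:
        return self.shared_spatial != "none"

    @property
    def n_kappa_cols(self) -> int:
        return {"none": 0, "common": 1, "by_gender": 2}[self.shared_spatial]

    @property
    def n_eta_rows(self) -> int:
        return {"none": 0, "by_age": 1, "by_age_gender": 2}[self.age_effect]

    @property
    def u_diseases(self) -> tuple[int, ...]:
        return tuple(sorted(self.specific_unstructured))

    def to_dict(self) -> dict:
        return {
            "shared_spatial": self.shared_spatial,
            "specific_unstructured": sorted(self.specific_unstructured),
            "age_effect": self.age_effect,
            "intercepts": self.intercepts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            shared_spatial=d.get("shared_spatial", "by_gender"),
            specific_unstructured=frozenset(d.get("specific_unstructured", [2])),
            age_effect=d.get("age_effect", "by_age_gender"),
            intercepts=bool(d.get("intercepts", True)),
        )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ParameterState:
    """One point in parameter space for a given :class:`ModelSpec`.

    Shapes depend on the spec: ``kappa`` is ``(I, n_kappa_cols)`` (or
    ``None``), ``u`` is ``(len(u_diseases), I)`` with rows ordered by
    disease index, ``eta`` is ``(n_eta_rows, J)``.  ``delta`` lives on the
    log scale as ``log_delta``.
    """

    alpha: np.ndarray
    log_delta: float
    kappa: np.ndarray | None
    u: np.ndarray | None
    eta: np.ndarray | None
    tau_kappa: float = 1.0
    tau_u: float = 1.0
    tau_eta: float = 1.0
    constrained: bool = False

    @property
    def delta(self) -> float:
        return float(np.exp(self.log_delta))

    def copy(self) -> "ParameterState":
        return ParameterState(
            alpha=np.array(self.alpha, dtype=float),
            log_delta=float(self.log_delta),
            kappa=None if self.kappa is None else np.array(self.kappa, dtype=float),
            u=None if self.u is None else np.array(self.u, dtype=float),
            eta=None if self.eta is None else np.array(self.eta, dtype=float),
            tau_kappa=float(self.tau_kappa),
            tau_u=float(self.tau_u),
            tau_eta=float(self.tau_eta),
            constrained=self.constrained,
        )


def zero_state(spec: ModelSpec, I: int, J: int) -> ParameterState:
    """All-zero effects, ``delta = 1``, unit precisions."""
    return ParameterState(
        alpha=np.zeros(2),
        log_delta=0.0,
        kappa=np.zeros((I, spec.n_kappa_cols)) if spec.has_spatial else None,
        u=np.zeros((len(spec.u_diseases), I)) if spec.u_diseases else None,
        eta=np.zeros((spec.n_eta_rows, J)) if spec.n_eta_rows else None,
        constrained=True,
    )


def _check_dims(spec: ModelSpec, theta: ParameterState, I: int, J: int) -> None:
    if spec.has_spatial:
        if theta.kappa is None or theta.kappa.shape != (I, spec.n_kappa_cols):
            raise ValueError(
                f"kappa must have shape ({I}, {spec.n_kappa_cols}) for this spec"
            )
    if spec.u_diseases:
        if theta.u is None or theta.u.shape != (len(spec.u_diseases), I):
            raise ValueError(f"u must have shape ({len(spec.u_diseases)}, {I})")
    if spec.n_eta_rows:
        if theta.eta is None or theta.eta.shape != (spec.n_eta_rows, J):
            raise ValueError(f"eta must have shape ({spec.n_eta_rows}, {J})")


# ---------------------------------------------------------------------------
# linear predictor and likelihood
# ---------------------------------------------------------------------------

def linear_predictor_field(spec: ModelSpec, theta: ParameterState, I: int, J: int) -> np.ndarray:
    """log-rate array of shape ``(2, I, 2, J)`` for every lattice cell."""
    _check_dims(spec, theta, I, J)
    lp = np.zeros((2, I, 2, J))
    if spec.intercepts:
        lp += np.asarray(theta.alpha, dtype=float)[:, None, None, None]
    if spec.has_spatial:
        delta = np.exp(theta.log_delta)
        scale = np.array([delta, 1.0 / delta])
        if spec.shared_spatial == "by_gender":
            kap = theta.kappa  # (I, 2): one column per gender
        else:
            kap = np.repeat(theta.kappa, 2, axis=1)  # common surface
        lp += scale[:, None, None, None] * kap[None, :, :, None]
    for row, d in enumerate(spec.u_diseases):
        lp[d - 1] += theta.u[row][:, None, None]
    if spec.age_effect == "by_age":
        lp += theta.eta[0][None, None, None, :]
    elif spec.age_effect == "by_age_gender":
        lp += theta.eta[None, None, :, :]
    return lp


def linear_predictor(spec: ModelSpec, theta: ParameterState,
                     d: int, i: int, g: int, j: int) -> float:
    """Scalar log-rate for one cell; indices are 1-based for disease/gender.

    ``d`` in {1, 2}, ``g`` in {1: male, 2: female}; ``i`` and ``j`` are
    0-based array indices.
    """
    I = 1 if theta.kappa is None and theta.u is None else None
    # infer lattice size from whichever component exists
    if theta.kappa is not None:
        I = theta.kappa.shape[0]
    elif theta.u is not None:
        I = theta.u.shape[1]
    else:
        I = i + 1
    J = theta.eta.shape[1] if theta.eta is not None else j + 1
    field = linear_predictor_field(spec, theta, I, J)
    return float(field[d - 1, i, g - 1, j])


def log_likelihood(data: CountData, spec: ModelSpec, theta: ParameterState) -> float:
    """Poisson log-likelihood summed over observed cells.

    Cells with ``n == 0`` and ``O == 0`` contribute zero; ``O > 0`` with
    ``n == 0`` is rejected by :class:`CountData` validation.
    """
    data.validate()
    lp = linear_predictor_field(spec, theta, data.I, data.J)
    m = data.mask
    O, n = data.O[m], data.n[m]
    eta = lp[m]
    mu = n * np.exp(eta)
    return float(np.sum(O * (np.log(n) + eta) - mu - gammaln(O + 1.0)))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def pc_prior_logdensity(tau: float, U: float, alpha: float) -> float:
    """Penalised-complexity prior density for a precision, on the tau scale.

    The PC prior for a Gaussian random-effect precision is an exponential
    distribution on the standard deviation ``sigma = tau**-0.5``, calibrated
    so that ``P(sigma > U) = alpha``; transformed to ``tau`` this is
    ``log p(tau) = log(lam/2) - 1.5*log(tau) - lam*tau**-0.5`` with
    ``lam = -log(alpha)/U``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if U <= 0 or tau <= 0:
        raise ValueError("U and tau must be positive")
    lam = -math.log(alpha) / U
    return math.log(lam / 2.0) - 1.5 * math.log(tau) - lam / math.sqrt(tau)


def loggamma_logpdf(x: float, a: float, b: float) -> float:
    """Density of ``x = log(y)`` where ``y ~ Gamma(shape a, rate b)``."""
    if a <= 0 or b <= 0:
        raise ValueError("loggamma parameters must be positive")
    return a * math.log(b) - float(gammaln(a)) + a * x - b * math.exp(x)


def gamma_logpdf(tau: float, a: float, b: float) -> float:
    """Gamma(shape a, rate b) log-density on the tau scale."""
    if tau <= 0:
        return -np.inf
    return a * math.log(b) - float(gammaln(a)) + (a - 1.0) * math.log(tau) - b * tau


@dataclasses.dataclass(frozen=True)
class PriorConfig:
    """Hyperpriors for every precision, the scaling ``delta`` and intercepts.

    ``precision_prior`` selects the family used for all three precisions:

    * ``"pc"`` — PC prior, parameters ``(U, alpha)`` per precision with
      default ``P(sigma > 1) = 0.01``;
    * ``"uniform_sd"`` — improper uniform on the standard deviation,
      i.e. ``p(tau) \\propto tau**-1.5``;
    * ``"loggamma_logprec"`` — log-precision has a log-gamma prior, i.e.
      ``tau ~ Gamma(a, b)``; default ``(1, 5e-5)``.

    ``delta_prior = (a, b)`` puts a log-gamma(a, b) prior on ``log delta``
    (so ``delta ~ Gamma(a, b)``); the reference analysis uses ``(10, 10)``.
    Intercepts are ``N(0, precision p0)`` with ``p0 = 0.001`` by default;
    a ``("loggamma", (a, b))`` intercept prior is also accepted, which makes
    an intercept-only model conjugate (rate ``exp(alpha) ~ Gamma(a, b)``).
    """

    precision_prior: str = "pc"
    precision_params: tuple | dict | None = None
    delta_prior: tuple = (10.0, 10.0)
    intercept_prior: tuple = ("normal", 0.001)

    def __post_init__(self) -> None:
        if self.precision_prior not in ("pc", "uniform_sd", "loggamma_logprec"):
            raise ValueError(f"unknown precision prior {self.precision_prior!r}")
        a, b = self.delta_prior
        if a <= 0 or b <= 0:
            raise ValueError("delta_prior parameters must be positive")
        kind = self.intercept_prior[0]
        if kind == "normal":
            if self.intercept_prior[1] <= 0:
                raise ValueError("intercept precision must be positive")
        elif kind != "loggamma":
            raise ValueError(f"unknown intercept prior {kind!r}")

    def params_for(self, which: str) -> tuple:
        """Hyperparameters for precision ``which`` in {kappa, u, eta}."""
        defaults = {"pc": (1.0, 0.01), "uniform_sd": (), "loggamma_logprec": (1.0, 5e-5)}
        p = self.precision_params
        if p is None:
            return defaults[self.precision_prior]
        if isinstance(p, dict):
            return tuple(p.get(which, defaults[self.precision_prior]))
        return tuple(p)

    def precision_logpdf(self, tau: float, which: str) -> float:
        if tau <= 0:
            raise ValueError("precision must be positive")
        if self.precision_prior == "pc":
            U, al = self.params_for(which)
            return pc_prior_logdensity(tau, U, al)
        if self.precision_prior == "uniform_sd":
            # p(sigma) ∝ 1  =>  p(tau) ∝ tau**-1.5 (improper)
            return -1.5 * math.log(tau)
        a, b = self.params_for(which)
        return gamma_logpdf(tau, a, b)

    def intercept_logpdf(self, alpha_d: float) -> float:
        if self.intercept_prior[0] == "normal":
            p0 = self.intercept_prior[1]
            return 0.5 * (math.log(p0) - LOG_2PI) - 0.5 * p0 * alpha_d ** 2
        a, b = self.intercept_prior[1]
        return loggamma_logpdf(alpha_d, a, b)

    def delta_logpdf(self, log_delta: float) -> float:
        a, b = self.delta_prior
        return loggamma_logpdf(log_delta, a, b)

    def to_dict(self) -> dict:
        d = {
            "precision_prior": self.precision_prior,
            "delta_prior": list(self.delta_prior),
            "intercept_prior": [self.intercept_prior[0],
                                list(self.intercept_prior[1])
                                if isinstance(self.intercept_prior[1], (tuple, list))
                                else self.intercept_prior[1]],
        }
        if self.precision_params is not None:
            p = self.precision_params
            d["precision_params"] = (
                {k: list(v) for k, v in p.items()} if isinstance(p, dict) else list(p)
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        pp = d.get("precision_params")
        if isinstance(pp, dict):
            pp = {k: tuple(v) for k, v in pp.items()}
        elif isinstance(pp, list):
            pp = tuple(pp)
        ip = d.get("intercept_prior", ["normal", 0.001])
        ip = (ip[0], tuple(ip[1]) if isinstance(ip[1], (tuple, list)) else ip[1])
        return cls(
            precision_prior=d.get("precision_prior", "pc"),
            precision_params=pp,
            delta_prior=tuple(d.get("delta_prior", (10.0, 10.0))),
            intercept_prior=ip,
        )


def log_prior(theta: ParameterState, spec: ModelSpec, priors: PriorConfig,
              struct: StructureMatrix) -> float:
    """Joint log-prior of a constrained parameter state.

    The ICAR term is the proper density on the constrained subspace:
    ``(I - c)/2 * log(tau_kappa)`` per gender block (``c`` = number of
    connected components) plus ``-tau_kappa/2 * kappa' R kappa`` and the
    constant from the non-null eigenvalues of ``R``.  ``u`` and ``eta`` get
    iid normal densities with their tau read as a precision; hyperpriors
    follow :class:`PriorConfig`.
    """
    for name, tau in (("tau_kappa", theta.tau_kappa), ("tau_u", theta.tau_u),
                      ("tau_eta", theta.tau_eta)):
        if tau <= 0:
            raise ValueError(f"{name} must be positive")
    total = 0.0
    if spec.intercepts:
        total += sum(priors.intercept_logpdf(float(a)) for a in theta.alpha)
    if spec.has_spatial:
        _, lam = struct.eigenbasis()
        K = lam.size  # = I - n_components
        Rd = struct.dense()
        for c in range(theta.kappa.shape[1]):
            kap = theta.kappa[:, c]
            quad = float(kap @ Rd @ kap)
            total += 0.5 * K * (math.log(theta.tau_kappa) - LOG_2PI)
            total += 0.5 * float(np.sum(np.log(lam)))
            total += -0.5 * theta.tau_kappa * quad
        total += priors.precision_logpdf(theta.tau_kappa, "kappa")
        total += priors.delta_logpdf(theta.log_delta)
    if spec.u_diseases:
        m = theta.u.size
        total += 0.5 * m * (math.log(theta.tau_u) - LOG_2PI)
        total += -0.5 * theta.tau_u * float(np.sum(theta.u ** 2))
        total += priors.precision_logpdf(theta.tau_u, "u")
    if spec.n_eta_rows:
        m = theta.eta.size
        total += 0.5 * m * (math.log(theta.tau_eta) - LOG_2PI)
        total += -0.5 * theta.tau_eta * float(np.sum(theta.eta ** 2))
        total += priors.precision_logpdf(theta.tau_eta, "eta")
    return total


def apply_constraints(theta: ParameterState, spec: ModelSpec,
                      component_labels: np.ndarray | None = None) -> ParameterState:
    """Centre ``kappa`` (per gender column, per connected component) and
    ``eta`` (overall) to satisfy the sum-to-zero identifiability constraints.

    Idempotent; returns a new state flagged ``constrained``.
    """
    out = theta.copy()
    if spec.has_spatial and out.kappa is not None:
        if component_labels is None:
            component_labels = np.zeros(out.kappa.shape[0], dtype=int)
        for comp in np.unique(component_labels):
            sel = component_labels == comp
            out.kappa[sel] -= out.kappa[sel].mean(axis=0, keepdims=True)
    if spec.n_eta_rows and out.eta is not None:
        out.eta -= out.eta.mean()
    out.constrained = True
    return out
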