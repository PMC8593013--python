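"""Posterior sampling for the shared-component model and its summaries.

The sampler is Metropolis-within-Gibbs:

* all continuous latent quantities (intercepts, ``log delta``, the spatial
  surface, the unstructured effect, the age-gender effects) are updated
  jointly by a preconditioned Metropolis-adjusted Langevin (MALA) step —
  gradients of the Poisson log-posterior are cheap and exact;
* each log-precision is updated by univariate slice sampling from its full
  conditional, which works unchanged for every hyperprior family.

Identifiability constraints are built into the parameterisation rather than
enforced after the fact: the spatial surface is sampled in the eigenbasis
of ``R`` restricted off its null space (so each gender column sums to zero
per connected component, exactly, at every draw), and the age-gender block
is sampled in the orthogonal complement of the constant vector.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import arviz as az
import numpy as np
from scipy.linalg import null_space

from .graph import AreaGraph, StructureMatrix, icar_structure
from .model import (
    CountData,
    ModelSpec,
    ParameterState,
    PriorConfig,
    linear_predictor_field,
)
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PosteriorSamples:
    """Retained MCMC draws plus sampling metadata and diagnostics.

    ``draws`` maps parameter names to arrays with leading dimensions
    ``(chains, n_retained)``; :meth:`stacked` flattens the chain axis.
    """

    draws: dict
    spec: ModelSpec
    priors: PriorConfig
    meta: dict
    diagnostics: dict = dataclasses.field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        k = next(iter(self.draws))
        return self.draws[k].shape[0] * self.draws[k].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])

    def log_delta_draws(self) -> np.ndarray:
        """Flattened log-delta draws (constant array when delta was fixed)."""
        if "log_delta" in self.draws:
            return self.stacked("log_delta")
        fd = self.meta.get("fix_delta")
        val = 0.0 if fd is None else math.log(fd)
        return np.full(self.n_draws, val)


# ---------------------------------------------------------------------------
# internal posterior machinery
# ---------------------------------------------------------------------------

class _Posterior:
    """Packs the latent field into one vector and evaluates logp + gradient."""

    def __init__(self, data: CountData, spec: ModelSpec, priors: PriorConfig,
                 struct: StructureMatrix | None, fix_delta: float | None):
        self.data = data
        self.spec = spec
        self.priors = priors
        self.fix_delta = fix_delta
        I, J = data.I, data.J
        self.I, self.J = I, J
        self.O = data.O.astype(float)
        self.n = data.n
        m = data.mask
        self.const = float(np.sum(self.O[m] * np.log(self.n[m]) - gammaln(self.O[m] + 1.0)))

        self.cols = spec.n_kappa_cols
        if spec.has_spatial:
            assert struct is not None
            self.A, self.lam = struct.eigenbasis()
            self.K = self.lam.size
        else:
            self.A, self.lam, self.K = None, None, 0
        self.nu = len(spec.u_diseases)
        self.me = spec.n_eta_rows * J
        if self.me:
            self.B = null_space(np.ones((1, self.me)))  # (me, me-1), orthonormal
        else:
            self.B = None

        pos = 0
        self.slices: dict[str, slice] = {}
        if spec.intercepts:
            self.slices["alpha"] = slice(pos, pos + 2)
            pos += 2
        self.sample_delta = spec.has_spatial and fix_delta is None
        if self.sample_delta:
            self.slices["log_delta"] = slice(pos, pos + 1)
            pos += 1
        if spec.has_spatial:
            self.slices["zk"] = slice(pos, pos + self.cols * self.K)
            pos += self.cols * self.K
        if self.nu:
            self.slices["u"] = slice(pos, pos + self.nu * I)
            pos += self.nu * I
        if self.me:
            self.slices["ze"] = slice(pos, pos + self.me - 1)
            pos += self.me - 1
        self.dim = pos

    # -- packing --------------------------------------------------------
    def unpack(self, x: np.ndarray):
        sp = self.spec
        alpha = x[self.slices["alpha"]] if sp.intercepts else np.zeros(2)
        if self.sample_delta:
            ld = float(x[self.slices["log_delta"]][0])
        elif sp.has_spatial:
            ld = math.log(self.fix_delta)
        else:
            ld = 0.0
        zk = (x[self.slices["zk"]].reshape(self.K, self.cols)
              if sp.has_spatial else None)
        u = x[self.slices["u"]].reshape(self.nu, self.I) if self.nu else None
        ze = x[self.slices["ze"]] if self.me else None
        return alpha, ld, zk, u, ze

    def _field_parts(self, alpha, ld, zk, u, ze):
        sp = self.spec
        I, J = self.I, self.J
        lp = np.zeros((2, I, 2, J))
        kg = None
        if sp.intercepts:
            lp += alpha[:, None, None, None]
        if sp.has_spatial:
            kap = self.A @ zk  # (I, cols)
            kg = kap if self.cols == 2 else np.repeat(kap, 2, axis=1)
            delta = math.exp(ld)
            scale = np.array([delta, 1.0 / delta])
            lp += scale[:, None, None, None] * kg[None, :, :, None]
        if self.nu:
            for row, d in enumerate(sp.u_diseases):
                lp[d - 1] += u[row][:, None, None]
        if self.me:
            eta = (self.B @ ze).reshape(sp.n_eta_rows, J)
            if sp.age_effect == "by_age":
                lp += eta[0][None, None, None, :]
            else:
                lp += eta[None, None, :, :]
        return lp, kg

    # -- log posterior over the latent block ----------------------------
    def logpost_grad(self, x: np.ndarray, tk: float, tu: float, te: float):
        """(log posterior, gradient) at fixed precisions; (-inf, None) if overflow."""
        sp = self.spec
        alpha, ld, zk, u, ze = self.unpack(x)
        with np.errstate(over="ignore", invalid="ignore"):
            lp, kg = self._field_parts(alpha, ld, zk, u, ze)
            mu = self.n * np.exp(lp)
        if not np.all(np.isfinite(mu)):
            return -np.inf, None
        ll = self.const + float(np.sum(self.O * lp)) - float(mu.sum())
        G = self.O - mu  # d loglik / d lp per cell

        total = ll
        grad = np.zeros(self.dim)
        pr = self.priors
        if sp.intercepts:
            ga = G.sum(axis=(1, 2, 3))  # (2,)
            if pr.intercept_prior[0] == "normal":
                p0 = pr.intercept_prior[1]
                total += -0.5 * p0 * float(np.sum(alpha ** 2))
                ga = ga - p0 * alpha
            else:
                a, b = pr.intercept_prior[1]
                total += float(np.sum(a * alpha - b * np.exp(alpha)))
                ga = ga + a - b * np.exp(alpha)
            grad[self.slices["alpha"]] = ga
        if sp.has_spatial:
            delta = math.exp(ld)
            T = G.sum(axis=3)  # (2, I, 2)
            dk_full = delta * T[0] + (1.0 / delta) * T[1]  # (I, 2)
            dkap = dk_full if self.cols == 2 else dk_full.sum(axis=1, keepdims=True)
            gz = self.A.T @ dkap - tk * self.lam[:, None] * zk
            grad[self.slices["zk"]] = gz.ravel()
            total += (0.5 * self.cols * self.K * math.log(tk)
                      - 0.5 * tk * float(np.sum(self.lam[:, None] * zk ** 2)))
            if self.sample_delta:
                a, b = pr.delta_prior
                dld = (delta * float(np.sum(T[0] * kg))
                       - (1.0 / delta) * float(np.sum(T[1] * kg))
                       + a - b * delta)
                grad[self.slices["log_delta"]] = dld
                total += a * ld - b * delta
        if self.nu:
            du = np.stack([G[d - 1].sum(axis=(1, 2)) for d in sp.u_diseases])
            grad[self.slices["u"]] = (du - tu * u).ravel()
            total += 0.5 * self.nu * self.I * math.log(tu) - 0.5 * tu * float(np.sum(u ** 2))
        if self.me:
            E = G.sum(axis=(0, 1))  # (2, J)
            deta = E.sum(axis=0, keepdims=True) if sp.age_effect == "by_age" else E
            gze = self.B.T @ deta.ravel() - te * ze
            grad[self.slices["ze"]] = gze
            total += 0.5 * (self.me - 1) * math.log(te) - 0.5 * te * float(np.sum(ze ** 2))
        if not np.isfinite(total):
            return -np.inf, None
        return total, grad

    def design_matrix(self, ld: float) -> np.ndarray:
        """Jacobian of the cell log-rates w.r.t. the latent vector (except the
        ``log_delta`` column, which is filled at evaluation time)."""
        sp = self.spec
        I, J = self.I, self.J
        C = np.zeros((2, I, 2, J, self.dim))
        if sp.intercepts:
            a0 = self.slices["alpha"].start
            C[0, :, :, :, a0] = 1.0
            C[1, :, :, :, a0 + 1] = 1.0
        if sp.has_spatial:
            delta = math.exp(ld)
            s = np.array([delta, 1.0 / delta])
            z0 = self.slices["zk"].start
            Czk = np.zeros((2, I, 2, J, self.K, self.cols))
            block = s[:, None, None, None] * self.A[None, :, None, :]  # (2, I, 1, K)
            if self.cols == 2:
                for c in range(2):
                    Czk[:, :, c, :, :, c] = block
            else:
                Czk[:, :, :, :, :, 0] = block[:, :, None, :, :]
            C[..., z0:z0 + self.K * self.cols] = Czk.reshape(2, I, 2, J, -1)
        if self.nu:
            u0 = self.slices["u"].start
            eye = np.eye(I)
            for row, d in enumerate(sp.u_diseases):
                C[d - 1, :, :, :, u0 + row * I:u0 + (row + 1) * I] = eye[:, None, None, :]
        if self.me:
            z0 = self.slices["ze"].start
            if sp.age_effect == "by_age":
                Br = self.B.reshape(J, self.me - 1)
                C[..., z0:] = Br[None, None, None, :, :]
            else:
                Br = self.B.reshape(2, J, self.me - 1)
                C[..., z0:] = Br[None, None, :, :, :]
        return C

    def fisher_full(self, x: np.ndarray, tk: float, tu: float, te: float) -> np.ndarray:
        """Expected-information matrix of the latent block at ``x``.

        ``F = C' diag(mu) C + prior precision``; used as the MALA metric so
        the tightly correlated intercept/age-effect/surface directions are
        preconditioned exactly (up to the Gaussian approximation).
        """
        sp = self.spec
        alpha, ld, zk, u, ze = self.unpack(x)
        with np.errstate(over="ignore"):
            lp, kg = self._field_parts(alpha, ld, zk, u, ze)
            mu = self.n * np.exp(np.minimum(lp, 50.0))
        C = self.design_matrix(ld)
        if self.sample_delta:
            delta = math.exp(ld)
            col = self.slices["log_delta"].start
            C[0, :, :, :, col] = (delta * kg)[:, :, None]
            C[1, :, :, :, col] = (-kg / delta)[:, :, None]
        C2 = C.reshape(-1, self.dim)
        w = mu.ravel()
        F = C2.T @ (C2 * w[:, None])
        # prior curvature on the diagonal
        pr = self.priors
        diag = np.zeros(self.dim)
        if sp.intercepts:
            if pr.intercept_prior[0] == "normal":
                diag[self.slices["alpha"]] = pr.intercept_prior[1]
            else:
                diag[self.slices["alpha"]] = pr.intercept_prior[1][1] * np.exp(alpha)
        if sp.has_spatial:
            lam_block = np.repeat(self.lam, self.cols)  # matches zk.reshape(K, cols)
            diag[self.slices["zk"]] = tk * lam_block
            if self.sample_delta:
                diag[self.slices["log_delta"]] = pr.delta_prior[1] * math.exp(ld)
        if self.nu:
            diag[self.slices["u"]] = tu
        if self.me:
            diag[self.slices["ze"]] = te
        F[np.diag_indices_from(F)] += np.maximum(diag, 1e-10)
        return F

    def fisher_diag(self, x: np.ndarray, tk: float, tu: float, te: float) -> np.ndarray:
        """Diagonal of the expected curvature, used as the MALA preconditioner."""
        sp = self.spec
        alpha, ld, zk, u, ze = self.unpack(x)
        with np.errstate(over="ignore"):
            lp, kg = self._field_parts(alpha, ld, zk, u, ze)
            mu = self.n * np.exp(np.minimum(lp, 50.0))
        F = np.zeros(self.dim)
        pr = self.priors
        if sp.intercepts:
            fa = mu.sum(axis=(1, 2, 3))
            if pr.intercept_prior[0] == "normal":
                fa = fa + pr.intercept_prior[1]
            else:
                fa = fa + pr.intercept_prior[1][1] * np.exp(alpha)
            F[self.slices["alpha"]] = fa
        if sp.has_spatial:
            delta = math.exp(ld)
            M = mu.sum(axis=3)  # (2, I, 2)
            fk_full = delta ** 2 * M[0] + delta ** -2 * M[1]
            fkap = fk_full if self.cols == 2 else fk_full.sum(axis=1, keepdims=True)
            fz = (self.A ** 2).T @ fkap + tk * self.lam[:, None]
            F[self.slices["zk"]] = fz.ravel()
            if self.sample_delta:
                fld = (delta ** 2 * float(np.sum(M[0] * kg ** 2))
                       + delta ** -2 * float(np.sum(M[1] * kg ** 2))
                       + pr.delta_prior[1] * delta)
                F[self.slices["log_delta"]] = fld
        if self.nu:
            fu = np.stack([mu[d - 1].sum(axis=(1, 2)) for d in sp.u_diseases]) + tu
            F[self.slices["u"]] = fu.ravel()
        if self.me:
            E = mu.sum(axis=(0, 1))
            feta = E.sum(axis=0, keepdims=True) if sp.age_effect == "by_age" else E
            F[self.slices["ze"]] = (self.B ** 2).T @ feta.ravel() + te
        return np.maximum(F, 1e-12)

    # -- precision full conditionals -------------------------------------
    def tau_stats(self, x: np.ndarray) -> dict[str, tuple[int, float]]:
        """(effective dimension, sum of squares) per precision."""
        _, _, zk, u, ze = self.unpack(x)
        out = {}
        if self.spec.has_spatial:
            out["kappa"] = (self.cols * self.K,
                            float(np.sum(self.lam[:, None] * zk ** 2)))
        if self.nu:
            out["u"] = (self.nu * self.I, float(np.sum(u ** 2)))
        if self.me:
            out["eta"] = (self.me - 1, float(np.sum(ze ** 2)))
        return out


def _slice_sample(logf, x0: float, rng: np.random.Generator,
                  w: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampling with stepping out (Neal 2003)."""
    y = logf(x0) - rng.exponential()
    if not np.isfinite(y):
        return x0
    L = x0 - w * rng.uniform()
    R = L + w
    k = max_steps
    while k > 0 and logf(L) > y:
        L -= w
        k -= 1
    k = max_steps
    while k > 0 and logf(R) > y:
        R += w
        k -= 1
    while True:
        x1 = rng.uniform(L, R)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_state(post: _Posterior, taus: dict, rng: np.random.Generator) -> np.ndarray:
    """Crude-rate intercepts; random effects jittered from their tau=init prior
    (an exactly zero field makes the precision conditionals improper)."""
    x = np.zeros(post.dim)
    if post.spec.intercepts:
        al = np.zeros(2)
        for d in range(2):
            tot_n = post.n[d].sum()
            if tot_n > 0:
                al[d] = math.log((post.O[d].sum() + 0.5) / tot_n)
        x[post.slices["alpha"]] = al
    if post.spec.has_spatial:
        sd = np.broadcast_to((taus["kappa"] * post.lam) ** -0.5,
                             (post.cols, post.K)).T  # (K, cols)
        x[post.slices["zk"]] = (rng.standard_normal((post.K, post.cols)) * sd).ravel()
    if post.nu:
        x[post.slices["u"]] = rng.standard_normal(post.nu * post.I) / math.sqrt(taus["u"])
    if post.me:
        x[post.slices["ze"]] = rng.standard_normal(post.me - 1) / math.sqrt(taus["eta"])
    return x


def fit(data: CountData, spec: ModelSpec, priors: PriorConfig, graph: AreaGraph | None,
        *, chains: int = 2, iters: int = 1000, warmup: int = 1000, thin: int = 1,
        seed: int, fix_delta: float | None = None, allow_islands: bool = False,
        target_accept: float = 0.57, rhat_warn: float = 1.05) -> PosteriorSamples:
    """Draw from the joint posterior of ``spec`` given ``data`` by MCMC.

    ``graph`` supplies the contiguity structure for the spatial term (it is
    re-indexed to the count table's area order); it may be ``None`` only
    for non-spatial specs.  ``fix_delta`` pins the scaling parameter (used
    e.g. for single-disease fits where it is unidentifiable).  Results are
    reproducible given ``seed``; split-R-hat and bulk effective sample
    sizes are attached, with a warning when any R-hat exceeds ``rhat_warn``.
    """
    data.validate()
    struct = None
    if spec.has_spatial:
        if graph is None:
            raise ValueError("a graph is required for spatial specs")
        if graph.area_ids != data.area_ids:
            graph = graph.reindex(data.area_ids)
        if np.any(graph.degrees() == 0) and not allow_islands:
            raise ValueError(
                "graph has isolated areas; an ICAR prior over them is improper "
                "unless each singleton is its own constrained block — pass "
                "allow_islands=True to opt in"
            )
        struct = icar_structure(graph)
    if iters < 1 or warmup < 0 or thin < 1 or chains < 1:
        raise ValueError("invalid sampler configuration")

    post = _Posterior(data, spec, priors, struct, fix_delta)
    taus0 = {"kappa": 10.0, "u": 10.0, "eta": 10.0}
    x_check = _initial_state(post, taus0, np.random.default_rng([int(seed), 0]))
    lp0, _ = post.logpost_grad(x_check, taus0["kappa"], taus0["u"], taus0["eta"])
    if not np.isfinite(lp0):
        raise ValueError("non-finite log-posterior at initialisation (likelihood); "
                         "check counts and populations")

    S = iters
    rec: dict[str, np.ndarray] = {}
    I, J = data.I, data.J
    if spec.intercepts:
        rec["alpha"] = np.empty((chains, S, 2))
    if post.sample_delta:
        rec["log_delta"] = np.empty((chains, S))
    if spec.has_spatial:
        rec["kappa"] = np.empty((chains, S, I, post.cols))
        rec["tau_kappa"] = np.empty((chains, S))
    if post.nu:
        rec["u"] = np.empty((chains, S, post.nu, I))
        rec["tau_u"] = np.empty((chains, S))
    if post.me:
        rec["eta"] = np.empty((chains, S, spec.n_eta_rows, J))
        rec["tau_eta"] = np.empty((chains, S))
    rec["log_post"] = np.empty((chains, S))
    accept = np.zeros(chains)

    def tau_logf(stat, which):
        neff, ssq = stat

        def logf(logtau):
            if abs(logtau) > 30.0:  # precision bounds; never binding with data
                return -np.inf
            tau = math.exp(logtau)
            try:
                hyper = priors.precision_logpdf(tau, which)
            except (OverflowError, ValueError):
                return -np.inf
            return 0.5 * neff * logtau - 0.5 * tau * ssq + hyper + logtau

        return logf

    # index bookkeeping for the two non-MALA group moves (see below)
    shift_pairs: list[tuple[int, slice]] = []
    if spec.intercepts and post.nu:
        a0 = post.slices["alpha"].start
        u0 = post.slices["u"].start
        for row, d in enumerate(spec.u_diseases):
            shift_pairs.append((a0 + d - 1, slice(u0 + row * data.I, u0 + (row + 1) * data.I)))

    from scipy.linalg import cho_factor, cho_solve, solve_triangular

    for chain in range(chains):
        rng = np.random.default_rng([int(seed), chain])
        taus = dict(taus0)
        x = _initial_state(post, taus, rng)
        eps = 0.5
        scale_step, shift_step = 0.1, 0.1

        fisher = None
        fisher_cf = None

        def set_metric(at_x) -> None:
            nonlocal fisher, fisher_cf
            F = post.fisher_full(at_x, taus["kappa"], taus["u"], taus["eta"])
            try:
                cf = cho_factor(F, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                F = F + np.eye(post.dim) * 1e-6 * np.trace(F) / post.dim
                cf = cho_factor(F, lower=True, check_finite=False)
            fisher, fisher_cf = F, cf

        def m_dot(v):  # F^{-1} v
            return cho_solve(fisher_cf, v, check_finite=False)

        def m_noise(xi):  # draw with covariance F^{-1}
            return solve_triangular(fisher_cf[0], xi, lower=True, trans="T",
                                    check_finite=False)

        def m_quad(r):  # r' F r
            return float(r @ (fisher @ r))

        if post.dim > 0:
            set_metric(x)
        lp, g = post.logpost_grad(x, taus["kappa"], taus["u"], taus["eta"])
        n_total = warmup + S * thin
        kept = 0
        for t in range(n_total):
            in_warmup = t < warmup
            # --- MALA step over the latent block, Fisher-preconditioned ---
            if post.dim > 0:
                drift = x + 0.5 * eps ** 2 * m_dot(g)
                prop = drift + eps * m_noise(rng.standard_normal(post.dim))
                lp_p, g_p = post.logpost_grad(prop, taus["kappa"], taus["u"], taus["eta"])
                if np.isfinite(lp_p) and g_p is not None and np.all(np.isfinite(g_p)):
                    with np.errstate(over="ignore"):
                        drift_rev = prop + 0.5 * eps ** 2 * m_dot(g_p)
                        log_q_fwd = -m_quad(prop - drift) / (2 * eps ** 2)
                        log_q_rev = -m_quad(x - drift_rev) / (2 * eps ** 2)
                        log_ratio = lp_p - lp + log_q_rev - log_q_fwd
                    if np.isfinite(log_ratio):
                        acc = min(1.0, math.exp(min(0.0, log_ratio)))
                    else:
                        acc = 0.0
                    if acc > 0.0 and rng.uniform() < acc:
                        x, lp, g = prop, lp_p, g_p
                else:
                    acc = 0.0
                if in_warmup:
                    gain = (t + 10.0) ** -0.6
                    eps = math.exp(math.log(eps) + gain * (acc - target_accept))
                    if t % 100 == 0 and t > 0:
                        set_metric(x)  # metric frozen once warmup ends
                elif not in_warmup:
                    accept[chain] += acc / (S * thin)
            # --- scale move: delta * e^eps with kappa / e^eps ---
            # mixes the scaling ridge the diagonal preconditioner cannot see:
            # disease 1's field delta*kappa is invariant along it.
            if post.sample_delta:
                e = scale_step * rng.standard_normal()
                x2 = x.copy()
                x2[post.slices["log_delta"]] += e
                x2[post.slices["zk"]] *= math.exp(-e)
                lp2, g2 = post.logpost_grad(x2, taus["kappa"], taus["u"], taus["eta"])
                log_ratio = lp2 - lp - e * post.cols * post.K  # log-Jacobian
                acc_s = 0.0
                if np.isfinite(log_ratio):
                    acc_s = min(1.0, math.exp(min(0.0, log_ratio)))
                if acc_s > 0.0 and rng.uniform() < acc_s:
                    x, lp, g = x2, lp2, g2
                if in_warmup:
                    scale_step = math.exp(math.log(scale_step)
                                          + (acc_s - 0.44) / (t + 10.0) ** 0.6)
            # --- level-swap move: alpha_d + c with u_d - c (likelihood-invariant) ---
            for a_idx, u_sl in shift_pairs:
                c = shift_step * rng.standard_normal()
                x2 = x.copy()
                x2[a_idx] += c
                x2[u_sl] -= c
                lp2, g2 = post.logpost_grad(x2, taus["kappa"], taus["u"], taus["eta"])
                log_ratio = lp2 - lp
                acc_h = 0.0
                if np.isfinite(log_ratio):
                    acc_h = min(1.0, math.exp(min(0.0, log_ratio)))
                if acc_h > 0.0 and rng.uniform() < acc_h:
                    x, lp, g = x2, lp2, g2
                if in_warmup:
                    shift_step = math.exp(math.log(shift_step)
                                          + (acc_h - 0.44) / (t + 10.0) ** 0.6)
            # --- precision updates (slice sampling on the log scale) ---
            stats = post.tau_stats(x)
            changed = False
            for which, stat in stats.items():
                lt = _slice_sample(tau_logf(stat, which), math.log(taus[which]), rng)
                taus[which] = math.exp(lt)
                changed = True
            if changed:
                lp, g = post.logpost_grad(x, taus["kappa"], taus["u"], taus["eta"])
            # --- record ---
            if not in_warmup and (t - warmup) % thin == 0:
                alpha, ld, zk, u, ze = post.unpack(x)
                if spec.intercepts:
                    rec["alpha"][chain, kept] = alpha
                if post.sample_delta:
                    rec["log_delta"][chain, kept] = ld
                if spec.has_spatial:
                    rec["kappa"][chain, kept] = post.A @ zk
                    rec["tau_kappa"][chain, kept] = taus["kappa"]
                if post.nu:
                    rec["u"][chain, kept] = u
                    rec["tau_u"][chain, kept] = taus["u"]
                if post.me:
                    rec["eta"][chain, kept] = (post.B @ ze).reshape(spec.n_eta_rows, J)
                    rec["tau_eta"][chain, kept] = taus["eta"]
                rec["log_post"][chain, kept] = lp
                kept += 1

    meta = {
        "chains": chains, "iters": iters, "warmup": warmup, "thin": thin,
        "seed": int(seed), "fix_delta": fix_delta,
        "area_ids": list(data.area_ids), "age_labels": list(data.age_labels),
        "accept_rate": accept.tolist(),
    }
    samples = PosteriorSamples(draws=rec, spec=spec, priors=priors, meta=meta)
    samples.diagnostics = _diagnostics(samples)
    worst = max((v for v in samples.diagnostics.get("rhat", {}).values()
                 if np.isfinite(v)), default=1.0)
    if worst > rhat_warn:
        warnings.warn(
            f"max split-R-hat {worst:.3f} exceeds {rhat_warn}; "
            "increase warmup/iters or chains", RuntimeWarning, stacklevel=2,
        )
    return samples


def _scalar_chains(samples: PosteriorSamples) -> dict[str, np.ndarray]:
    out = {}
    d = samples.draws
    if "alpha" in d:
        out["alpha1"] = d["alpha"][:, :, 0]
        out["alpha2"] = d["alpha"][:, :, 1]
    if "log_delta" in d:
        out["log_delta"] = d["log_delta"]
    for k in ("tau_kappa", "tau_u", "tau_eta"):
        if k in d:
            out[f"log_{k}"] = np.log(d[k])
    return out


def _diagnostics(samples: PosteriorSamples) -> dict:
    chains_dict = _scalar_chains(samples)
    if not chains_dict:
        return {}

    def split(a: np.ndarray) -> np.ndarray:
        half = a.shape[1] // 2
        if half == 0:
            return a
        return np.concatenate([a[:, :half], a[:, half:2 * half]], axis=0)

    ds = az.convert_to_dataset({k: split(v) for k, v in chains_dict.items()})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    return {
        "rhat": {k: float(rhat[k].values) for k in chains_dict},
        "ess_bulk": {k: float(ess[k].values) for k in chains_dict},
    }


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def _lp_field_draws(samples: PosteriorSamples, I: int, J: int) -> np.ndarray:
    """Linear-predictor field per retained draw: shape ``(S, 2, I, 2, J)``."""
    spec = samples.spec
    S = samples.n_draws
    lp = np.zeros((S, 2, I, 2, J))
    if spec.intercepts:
        alpha = samples.stacked("alpha")
        lp += alpha[:, :, None, None, None]
    if spec.has_spatial:
        kap = samples.stacked("kappa")  # (S, I, cols)
        kg = kap if spec.n_kappa_cols == 2 else np.repeat(kap, 2, axis=2)
        delta = np.exp(samples.log_delta_draws())
        scale = np.stack([delta, 1.0 / delta], axis=1)  # (S, 2)
        lp += scale[:, :, None, None, None] * kg[:, None, :, :, None]
    if spec.u_diseases:
        u = samples.stacked("u")  # (S, nu, I)
        for row, d in enumerate(spec.u_diseases):
            lp[:, d - 1] += u[:, row][:, :, None, None]
    if spec.age_effect == "by_age":
        eta = samples.stacked("eta")
        lp += eta[:, 0][:, None, None, None, :]
    elif spec.age_effect == "by_age_gender":
        eta = samples.stacked("eta")
        lp += eta[:, None, None, :, :]
    return lp


def derive_rates(samples: PosteriorSamples, data: CountData) -> np.ndarray:
    """Per-draw mortality rates per 100,000: ``exp(log r) * 1e5``,
    shape ``(S, 2, I, 2, J)``."""
    lp = _lp_field_draws(samples, data.I, data.J)
    return np.exp(lp) * 1e5


def derive_shared_pattern(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw shared spatial pattern ``exp(kappa) * 1e5``, shape
    ``(S, I, n_kappa_cols)`` (columns: male, female for gender-specific)."""
    if "kappa" not in samples.draws:
        raise ValueError("this fit has no shared spatial component")
    return np.exp(samples.stacked("kappa")) * 1e5


def derive_specific_pattern(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw disease-specific pattern ``exp(u) * 1e5``, shape ``(S, nu, I)``."""
    if "u" not in samples.draws:
        raise ValueError("this fit has no unstructured disease-specific effect")
    return np.exp(samples.stacked("u")) * 1e5


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

MIN_DRAWS = 40  # fewer draws cannot pin down the 2.5% percentile


def summarize(draws: np.ndarray, axis_names=None, axis_labels=None,
              quantity: str = "value"):
    """Posterior medians and equal-tailed 95% intervals, one row per cell.

    ``draws`` has the sample dimension first; remaining axes become label
    columns named by ``axis_names`` with values from ``axis_labels``.
    Percentiles use linear interpolation between order statistics.
    """
    import pandas as pd

    draws = np.asarray(draws)
    S = draws.shape[0]
    if S < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws for a 95% interval, got {S}")
    med, lo, hi = np.percentile(draws, [50.0, 2.5, 97.5], axis=0)
    shape = draws.shape[1:]
    axis_names = list(axis_names or [f"axis{k}" for k in range(len(shape))])
    if axis_labels is None:
        axis_labels = [list(range(s)) for s in shape]
    rows = []
    for idx in np.ndindex(*shape) if shape else [()]:
        row = {"quantity": quantity}
        for name, labels, k in zip(axis_names, axis_labels, idx):
            row[name] = labels[k]
        row["median"] = float(med[idx]) if shape else float(med)
        row["ci_low"] = float(lo[idx]) if shape else float(lo)
        row["ci_high"] = float(hi[idx]) if shape else float(hi)
        rows.append(row)
    df = pd.DataFrame(rows)
    bad = (df["ci_low"] > df["median"]) | (df["median"] > df["ci_high"])
    assert not bad.any(), "interval ordering violated"
    return df


def summarize_rates(samples: PosteriorSamples, data: CountData):
    """Summary table of modelled rates per 100,000 for every lattice cell."""
    rates = derive_rates(samples, data)
    return summarize(
        rates,
        axis_names=["disease", "area", "gender", "age_group"],
        axis_labels=[list(data.disease_labels), list(data.area_ids),
                     list(data.gender_labels), list(data.age_labels)],
        quantity="rate",
    )


def summarize_shared_pattern(samples: PosteriorSamples, data: CountData):
    pat = derive_shared_pattern(samples)
    cols = (list(data.gender_labels) if samples.spec.n_kappa_cols == 2 else ["common"])
    return summarize(
        pat, axis_names=["area", "gender"],
        axis_labels=[list(data.area_ids), cols],
        quantity="shared_pattern",
    )


def summarize_specific_pattern(samples: PosteriorSamples, data: CountData):
    pat = derive_specific_pattern(samples)
    dis = [data.disease_labels[d - 1] for d in samples.spec.u_diseases]
    return summarize(
        pat, axis_names=["disease", "area"],
        axis_labels=[dis, list(data.area_ids)],
        quantity="specific_pattern",
    )


def summarize_parameters(samples: PosteriorSamples):
    """Summary of the scalar parameters (delta, precisions, intercepts)."""
    import pandas as pd

    frames = []
    if "alpha" in samples.draws:
        a = samples.stacked("alpha")
        frames.append(summarize(a[:, 0], axis_names=[], quantity="alpha1"))
        frames.append(summarize(a[:, 1], axis_names=[], quantity="alpha2"))
    if "log_delta" in samples.draws:
        frames.append(summarize(np.exp(samples.stacked("log_delta")),
                                axis_names=[], quantity="delta"))
    for k in ("tau_kappa", "tau_u", "tau_eta"):
        if k in samples.draws:
            frames.append(summarize(samples.stacked(k), axis_names=[], quantity=k))
    return pd.concat(frames, ignore_index=True)


def state_from_draw(samples: PosteriorSamples, s: int, I: int, J: int) -> ParameterState:
    """Reconstruct a full :class:`ParameterState` from retained draw ``s``."""
    spec = samples.spec
    d = samples.draws
    get = lambda k: samples.stacked(k)[s] if k in d else None
    alpha = get("alpha")
    return ParameterState(
        alpha=np.zeros(2) if alpha is None else alpha,
        log_delta=float(samples.log_delta_draws()[s]),
        kappa=get("kappa"),
        u=get("u"),
        eta=get("eta"),
        tau_kappa=float(samples.stacked("tau_kappa")[s]) if "tau_kappa" in d else 1.0,
        tau_u=float(samples.stacked("tau_u")[s]) if "tau_u" in d else 1.0,
        tau_eta=float(samples.stacked("tau_eta")[s]) if "tau_eta" in d else 1.0,
        constrained=True,
    )
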