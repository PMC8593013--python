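"""Model-comparison criteria computed from posterior draws.

Three criteria on the deviance scale (smaller is better):

* DIC = Dbar + pD with pD = Dbar - D(plug-in), the plug-in deviance taken
  at the posterior mean of each cell's *linear predictor* (not of the raw
  parameters), the convention used by latent-Gaussian software;
* WAIC = -2 (lppd - pWAIC) from the pointwise log predictive density;
* the logarithmic score LS = -mean(log CPO), with the conditional
  predictive ordinate estimated per cell by the harmonic mean of the
  per-draw likelihoods.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .inference import PosteriorSamples, _lp_field_draws
from .model import CountData

CPO_FLOOR = 1e-300


def pointwise_loglik(samples: PosteriorSamples, data: CountData) -> np.ndarray:
    """Per-draw, per-observed-cell Poisson log-likelihood, shape ``(S, C)``.

    Cells with zero population are excluded (they carry no information).
    """
    data.validate()
    lp = _lp_field_draws(samples, data.I, data.J)  # (S, 2, I, 2, J)
    m = data.mask
    O = data.O[m].astype(float)
    n = data.n[m]
    eta = lp[:, m]
    mu = n[None, :] * np.exp(eta)
    return O[None, :] * (np.log(n)[None, :] + eta) - mu - gammaln(O + 1.0)[None, :]


@dataclasses.dataclass
class CriteriaReport:
    """DIC, WAIC and logarithmic score for one fitted model."""

    dic: float
    dbar: float
    pd: float
    waic: float
    lppd: float
    p_waic: float
    ls: float
    cpo: np.ndarray

    def to_frame(self, model: str = "model") -> pd.DataFrame:
        return pd.DataFrame([{
            "model": model, "DIC": self.dic, "Dbar": self.dbar, "pD": self.pd,
            "WAIC": self.waic, "lppd": self.lppd, "pWAIC": self.p_waic,
            "LS": self.ls,
        }])


def dic(samples: PosteriorSamples, data: CountData) -> tuple[float, float, float]:
    """(DIC, Dbar, pD); deviance is ``-2 * log-likelihood``."""
    ll = pointwise_loglik(samples, data)
    dbar = float(np.mean(-2.0 * ll.sum(axis=1)))
    # plug-in at the posterior mean linear predictor per cell
    lp = _lp_field_draws(samples, data.I, data.J)
    m = data.mask
    eta_bar = lp[:, m].mean(axis=0)
    O, n = data.O[m].astype(float), data.n[m]
    mu = n * np.exp(eta_bar)
    d_hat = float(-2.0 * np.sum(O * (np.log(n) + eta_bar) - mu - gammaln(O + 1.0)))
    p_d = dbar - d_hat
    return dbar + p_d, dbar, p_d


def waic(samples: PosteriorSamples, data: CountData) -> tuple[float, float, float]:
    """(WAIC, lppd, pWAIC); pWAIC is the pointwise posterior variance."""
    ll = pointwise_loglik(samples, data)
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    if S > 1:
        p_w = float(np.sum(np.var(ll, axis=0, ddof=1)))
    else:
        p_w = 0.0
    return -2.0 * (lppd - p_w), lppd, p_w


def log_score(samples: PosteriorSamples, data: CountData) -> tuple[float, np.ndarray]:
    """(LS, per-cell CPO) with the harmonic-mean CPO estimator.

    Cells whose CPO underflows below ``1e-300`` are floored with a warning;
    the harmonic mean is notoriously unstable on extreme cells.
    """
    ll = pointwise_loglik(samples, data)
    S = ll.shape[0]
    log_cpo = -(logsumexp(-ll, axis=0) - np.log(S))
    floor = np.log(CPO_FLOOR)
    n_bad = int(np.sum(log_cpo < floor))
    if n_bad:
        warnings.warn(f"{n_bad} cells with CPO below {CPO_FLOOR}; floored",
                      RuntimeWarning, stacklevel=2)
        log_cpo = np.maximum(log_cpo, floor)
    ls = float(-np.mean(log_cpo))
    return ls, np.exp(log_cpo)


def criteria_report(samples: PosteriorSamples, data: CountData) -> CriteriaReport:
    """All three criteria in one pass."""
    dic_v, dbar, p_d = dic(samples, data)
    waic_v, lppd, p_w = waic(samples, data)
    ls, cpo = log_score(samples, data)
    return CriteriaReport(dic=dic_v, dbar=dbar, pd=p_d, waic=waic_v,
                          lppd=lppd, p_waic=p_w, ls=ls, cpo=cpo)
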