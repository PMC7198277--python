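"""Empirical-Bayes moderated two-sample t statistic.

Per row (genomic window or transcript), the pooled residual variance s^2 on
d = nA + nB - 2 degrees of freedom is shrunk toward a prior scale s0^2 with
prior degrees of freedom d0, both estimated across rows by moment-matching
the marginal distribution of log s^2 (the scaled inverse-chi-square /
F-distribution scheme underlying limma's lmFit + eBayes):

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t    = (meanA - meanB) / (s~ * sqrt(1/nA + 1/nB))

with two-sided p-values from Student's t on d0 + d degrees of freedom
(standard normal when d0 is infinite).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple:
    """Fit the scaled-F prior (d0, s0^2) to observed row variances.

    Moment-matches ``log s^2`` using digamma/trigamma identities; rows with
    zero variance are excluded from the fit.  Returns ``(df_prior,
    s2_prior)`` with ``df_prior = inf`` when the observed spread of log s^2
    is no larger than expected from chi-square sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior = math.exp(
            emean + special.digamma(df_prior / 2.0) - math.log(df_prior / 2.0)
        )
    else:
        df_prior = math.inf
        s2_prior = math.exp(emean)
    return df_prior, s2_prior


@dataclass
class ModeratedTResult:
    mean_a: np.ndarray
    mean_b: np.ndarray
    log_fc: np.ndarray          # mean_a - mean_b (inputs already on log2 scale)
    s2: np.ndarray              # pooled residual variance
    s2_post: np.ndarray         # moderated variance
    t: np.ndarray
    p: np.ndarray
    df_residual: float
    df_prior: float
    s2_prior: float
    df_total: float


def moderated_t(a: np.ndarray, b: np.ndarray, df_prior: float = None) -> ModeratedTResult:
    """Row-wise moderated t between two replicate matrices (rows x reps).

    ``df_prior`` overrides the estimated prior degrees of freedom: 0 gives
    the ordinary equal-variance two-sample t, ``inf`` fully pools variances.
    If every row variance is zero the prior is fit to the between-row spread
    of the mean difference instead (logged), with ``df_prior = inf``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("condition matrices must have the same number of rows")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per condition")
    d = float(na + nb - 2)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log_fc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    if df_prior is None:
        if np.all(s2 <= 0):
            logger.warning(
                "all residual variances are zero; falling back to df_prior=inf "
                "with the prior scale taken from the between-row spread"
            )
            scale = float(np.var(log_fc, ddof=1)) / (1.0 / na + 1.0 / nb)
            d0, s20 = math.inf, max(scale, np.finfo(float).tiny)
        else:
            d0, s20 = fit_f_dist(s2, d)
    else:
        d0 = float(df_prior)
        if d0 == 0:
            s20 = 0.0  # unused: no shrinkage
        elif math.isinf(d0):
            # limit of the moment-matched scale as d0 -> inf
            z = np.log(s2[s2 > 0])
            s20 = math.exp(float(z.mean()) - special.digamma(d / 2.0) + math.log(d / 2.0))
        else:
            _, s20 = fit_f_dist(s2, d)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s20)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = d
    else:
        s2_post = (d0 * s20 + d * s2) / (d0 + d)
        df_total = d0 + d

    denom = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, log_fc / denom, 0.0)
        t = np.where((denom == 0) & (log_fc != 0), np.sign(log_fc) * np.inf, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedTResult(
        mean_a, mean_b, log_fc, s2, s2_post, t, p, d, d0, float(s20), df_total
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
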