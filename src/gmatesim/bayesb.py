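"""BayesB marker-effect estimation and GEBV-based truncation selection.

The model is the classic variable-selection mixture: each marker effect is
zero with prior probability pi and otherwise normal with its own variance
drawn from a scaled-inverse-chi-square(nu, S^2) prior.  Effects and
indicators are updated jointly by Gibbs sampling with the effect integrated
out of the indicator draw; marker variances and the residual variance get
scaled-inverse-chi-square updates.  S^2 is solved from the expected genetic
variance so that the prior marker variance mass matches the assumed
architecture.

The reference population in the breeding loop is always the two most
recent generations; the chain is re-run from scratch each generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numba
import numpy as np

from .population import Population
from .rng import as_rng

__all__ = ["MarkerEffects", "fit_bayesb", "gebv", "select_parents"]


@dataclass(frozen=True)
class MarkerEffects:
    """Posterior summaries of a BayesB fit."""

    a: np.ndarray  # posterior-mean allele substitution effect per marker
    inclusion_prob: np.ndarray  # posterior probability the marker is in the model
    intercept: float  # on the raw-dosage scale
    var_e: float  # posterior mean residual variance
    var_e_sd: float  # posterior SD of the residual variance
    pi: float  # prior exclusion probability
    nu: float  # slab prior degrees of freedom
    s2: float  # slab prior scale

    def __post_init__(self) -> None:
        if len(self.a) != len(self.inclusion_prob):
            raise ValueError("a and inclusion_prob must have equal length")
        if np.any((self.inclusion_prob < 0) | (self.inclusion_prob > 1)):
            raise ValueError("inclusion probabilities must lie in [0, 1]")


@numba.njit(cache=True)
def _bayesb_chain(Xt, y, xtx, n_iter, burn_in, thin, pi, nu, s2, nu_e, s2_e, seed):
    """Single-site Gibbs sampler over centred genotype columns (rows of Xt)."""
    m, n = Xt.shape
    np.random.seed(seed)
    alpha = np.zeros(m)
    sig2 = np.full(m, nu * s2 / max(nu - 2.0, 0.5))
    mu = y.mean()
    ycorr = y - mu
    var_e = s2_e * nu_e / max(nu_e - 2.0, 0.5)
    log_pi = np.log(pi)
    log_1mpi = np.log(1.0 - pi)
    a_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    ve_sum = 0.0
    ve2_sum = 0.0
    kept = 0
    for it in range(n_iter):
        # intercept
        ssum = 0.0
        for i in range(n):
            ssum += ycorr[i]
        mu_new = mu + ssum / n + np.random.standard_normal() * np.sqrt(var_e / n)
        shift = mu_new - mu
        for i in range(n):
            ycorr[i] -= shift
        mu = mu_new
        # marker effects: indicator sampled with the effect integrated out
        for j in range(m):
            xx = xtx[j]
            if xx <= 0.0:
                continue
            xj = Xt[j]
            rhs = xx * alpha[j]
            for i in range(n):
                rhs += xj[i] * ycorr[i]
            v0 = xx * var_e
            v1 = xx * xx * sig2[j] + v0
            r2 = rhs * rhs
            ld0 = log_pi - 0.5 * (np.log(v0) + r2 / v0)
            ld1 = log_1mpi - 0.5 * (np.log(v1) + r2 / v1)
            included = np.random.random() < 1.0 / (1.0 + np.exp(ld0 - ld1))
            if included:
                c = xx + var_e / sig2[j]
                a_new = rhs / c + np.random.standard_normal() * np.sqrt(var_e / c)
            else:
                a_new = 0.0
            diff = alpha[j] - a_new
            if diff != 0.0:
                for i in range(n):
                    ycorr[i] += xj[i] * diff
            alpha[j] = a_new
            if included:
                sig2[j] = (nu * s2 + a_new * a_new) / np.random.chisquare(nu + 1.0)
            else:
                sig2[j] = nu * s2 / np.random.chisquare(nu)
        # residual variance
        sse = 0.0
        for i in range(n):
            sse += ycorr[i] * ycorr[i]
        var_e = (sse + nu_e * s2_e) / np.random.chisquare(n + nu_e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            mu_sum += mu
            ve_sum += var_e
            ve2_sum += var_e * var_e
            for j in range(m):
                a_sum[j] += alpha[j]
                if alpha[j] != 0.0:
                    incl_sum[j] += 1.0
    ve_mean = ve_sum / kept
    ve_var = max(ve2_sum / kept - ve_mean * ve_mean, 0.0)
    return a_sum / kept, incl_sum / kept, mu_sum / kept, ve_mean, np.sqrt(ve_var)


def fit_bayesb(
    M: np.ndarray,
    y: np.ndarray,
    n_iter: int = 20000,
    burn_in: int = 1000,
    thin: int = 20,
    pi: float = 0.95,
    nu: float = 4.2,
    genetic_var: float | None = None,
    seed: int | np.random.Generator = 0,
) -> MarkerEffects:
    """Fit BayesB on a dosage matrix ``M`` (n x m) and phenotypes ``y``.

    Columns are centred by twice the current allele frequency before
    sampling; markers monomorphic in the reference are excluded from the
    chain and reported with a = 0.  ``genetic_var`` anchors the slab prior
    scale (default: half the phenotypic variance).  The chain is fully
    deterministic for a fixed seed.
    """
    M = np.asarray(M)
    y = np.asarray(y, dtype=np.float64)
    n, m = M.shape
    if n < 2 or m < 1:
        raise ValueError("need at least 2 individuals and 1 marker")
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype rows")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if not 0 < pi < 1:
        raise ValueError("pi must lie strictly between 0 and 1")
    var_y = float(y.var())
    p = M.mean(axis=0) / 2.0
    if var_y == 0:
        warnings.warn("phenotypes have zero variance; returning null effects")
        return MarkerEffects(
            a=np.zeros(m),
            inclusion_prob=np.zeros(m),
            intercept=float(y[0]),
            var_e=0.0,
            var_e_sd=0.0,
            pi=pi,
            nu=nu,
            s2=0.0,
        )
    poly = (p > 0) & (p < 1)
    gv = 0.5 * var_y if genetic_var is None else float(genetic_var)
    sum_2pq = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    if sum_2pq > 0:
        s2 = gv * (nu - 2.0) / (nu * (1.0 - pi) * sum_2pq)
    else:
        s2 = gv
    nu_e = 4.0
    s2_e = 0.5 * var_y * (nu_e - 2.0) / nu_e
    rng = as_rng(seed)
    chain_seed = int(rng.integers(2**31))

    a = np.zeros(m)
    incl = np.zeros(m)
    if poly.any():
        Xc = M[:, poly].astype(np.float64) - 2.0 * p[poly]
        Xt = np.ascontiguousarray(Xc.T)
        xtx = np.einsum("ij,ij->i", Xt, Xt)
        a_poly, incl_poly, mu_post, ve, ve_sd = _bayesb_chain(
            Xt, y, xtx, n_iter, burn_in, thin, pi, nu, s2, nu_e, s2_e, chain_seed
        )
        a[poly] = a_poly
        incl[poly] = incl_poly
    else:
        mu_post, ve, ve_sd = float(y.mean()), var_y, 0.0
    intercept = float(mu_post - np.dot(a, 2.0 * p))
    return MarkerEffects(
        a=a,
        inclusion_prob=incl,
        intercept=intercept,
        var_e=float(ve),
        var_e_sd=float(ve_sd),
        pi=pi,
        nu=nu,
        s2=float(s2),
    )


def gebv(M: np.ndarray, effects: MarkerEffects) -> np.ndarray:
    """Genomic estimated breeding values: intercept + dosage-weighted effect sum."""
    M = np.asarray(M)
    if M.shape[1] != len(effects.a):
        raise ValueError(
            f"genotype matrix has {M.shape[1]} markers, effects have {len(effects.a)}"
        )
    return effects.intercept + M.astype(np.float64) @ effects.a


def select_parents(
    candidates: Population,
    gebvs: np.ndarray,
    n_sires: int,
    n_dams: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Truncation selection: top GEBV males and females, ties broken by id.

    Returns row indices into ``candidates`` (sires, dams), each sorted by
    descending GEBV.
    """
    gebvs = np.asarray(gebvs, dtype=np.float64)
    if len(gebvs) != candidates.n_individuals:
        raise ValueError("GEBV vector does not match candidate population")
    out = []
    for rows, need, label in (
        (candidates.males(), n_sires, "male"),
        (candidates.females(), n_dams, "female"),
    ):
        if len(rows) < need:
            raise ValueError(f"only {len(rows)} {label} candidates for {need} slots")
        order = np.lexsort((candidates.ids[rows], -gebvs[rows]))
        out.append(rows[order[:need]])
    return out[0], out[1]
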