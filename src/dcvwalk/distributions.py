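"""Closed-form probability laws of the heterogeneous random walk.

A walker advances by one lattice step with probability ``p`` per step time.
Conditional on ``p`` the displacement after ``n`` steps is Binomial(n, p) and
the number of steps needed for the k-th advance is negative binomial.  With
``p ~ Beta(alpha, beta)`` once per track, marginalizing gives

* displacement ``k`` after ``n`` steps: **beta-binomial**,
  ``P(k | n) = C(n, k) B(k + alpha, n - k + beta) / B(alpha, beta)``;
* first-passage step count ``n`` to reach ``k`` steps: **beta-negative
  binomial (BNB)**,
  ``F(n | k) = C(n-1, k-1) B(k + alpha, n - k + beta) / B(alpha, beta)``.

All pmfs are evaluated in log space through log-gamma differences and
exponentiated last, so they stay finite for ``n`` in the hundreds where direct
factorials overflow.  Physical-unit helpers convert between lattice
coordinates (k, n) and (µm, s) through :class:`~dcvwalk.params.ModelParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, xlog1py, xlogy
from scipy.stats import beta as _beta_dist

from .params import ModelParams

__all__ = [
    "beta_density",
    "binomial_pmf",
    "bb_log_pmf",
    "bb_pmf",
    "bb_mean_variance",
    "bnb_log_pmf",
    "bnb_pmf",
    "bnb_mean",
    "bnb_variance",
    "bnb_truncated_moments",
    "fpt_frame_probs",
    "TruncatedMoments",
]


def _as_float_or_array(x):
    """Return a scalar for 0-d input, else an ndarray."""
    x = np.asarray(x)
    return x.item() if x.ndim == 0 else x


def beta_density(p, params: ModelParams):
    """Beta density ``f(p) = B(alpha, beta)^-1 p^(alpha-1) (1-p)^(beta-1)``.

    This is the population law of the per-track movement probability.
    ``p`` outside [0, 1] raises ``ValueError``.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("movement probability p must lie in [0, 1]")
    return _as_float_or_array(_beta_dist.pdf(p_arr, params.alpha, params.beta))


def binomial_pmf(k, n, p):
    """Binomial displacement pmf conditional on a fixed movement probability.

    ``C(n, k) p^k (1-p)^(n-k)``, evaluated via log-gamma.  ``k > n`` or
    ``k < 0`` returns 0; ``p`` outside [0, 1] raises ``ValueError``.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("movement probability p must lie in [0, 1]")
    k, n, p_arr = np.broadcast_arrays(k, n, p_arr)
    valid = (k >= 0) & (k <= n)
    kf = np.where(valid, k, 0).astype(float)
    nf = n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_comb = gammaln(nf + 1) - gammaln(kf + 1) - gammaln(nf - kf + 1)
        logp = log_comb + xlogy(kf, p_arr) + xlog1py(nf - kf, -p_arr)
    out = np.where(valid, np.exp(logp), 0.0)
    return _as_float_or_array(out)


# ---------------------------------------------------------------------------
# Beta-binomial displacement law
# ---------------------------------------------------------------------------


def bb_log_pmf(k, n, params: ModelParams):
    """Log of the beta-binomial displacement pmf; -inf outside 0 <= k <= n."""
    k = np.asarray(k)
    n = np.asarray(n)
    k, n = np.broadcast_arrays(k, n)
    valid = (k >= 0) & (k <= n)
    kf = np.where(valid, k, 0).astype(float)
    nf = n.astype(float)
    log_comb = gammaln(nf + 1) - gammaln(kf + 1) - gammaln(nf - kf + 1)
    logp = (
        log_comb
        + betaln(kf + params.alpha, nf - kf + params.beta)
        - betaln(params.alpha, params.beta)
    )
    out = np.where(valid, logp, -np.inf)
    return _as_float_or_array(out)


def bb_pmf(k, n, params: ModelParams):
    """Beta-binomial pmf of the displacement ``k`` (steps) after ``n`` steps.

    Marginal of Binomial(n, p) over ``p ~ Beta(alpha, beta)``; sums to one
    over ``k = 0..n``.
    """
    log_pmf = bb_log_pmf(k, n, params)
    return _as_float_or_array(np.exp(np.asarray(log_pmf, dtype=float)))


def bb_mean_variance(t_seconds: float, params: ModelParams) -> tuple[float, float]:
    """Mean (µm) and variance (µm²) of the displacement at elapsed time ``t``.

    With ``n = t / tau`` and ``s = alpha + beta``::

        <x>    = alpha/s * a * n
        var(x) = alpha*beta / (s (1+s))     * a^2 * n
               + alpha*beta / (s^2 (1+s))   * a^2 * n^2

    The quadratic term is the population-heterogeneity contribution; it makes
    the walk superdiffusive (ballistic, var ~ t^2, at late times) and vanishes
    in the homogeneous limit ``s -> inf`` at fixed mean p.
    """
    n = params.n_steps(t_seconds)
    a = params.step_size_um
    al, be = params.alpha, params.beta
    s = al + be
    mean = al / s * a * n
    lin = al * be / (s * (1.0 + s)) * a * a * n
    quad = al * be / (s * s * (1.0 + s)) * a * a * n * n
    return mean, lin + quad


# ---------------------------------------------------------------------------
# Beta-negative-binomial first-passage law
# ---------------------------------------------------------------------------


def bnb_log_pmf(n, k, params: ModelParams):
    """Log BNB pmf of the first-passage step count ``n`` for threshold ``k``."""
    n = np.asarray(n)
    k = np.asarray(k)
    n, k = np.broadcast_arrays(n, k)
    if np.any(k < 1):
        raise ValueError("first-passage threshold k must be >= 1")
    valid = n >= k
    nf = np.where(valid, n, k).astype(float)
    kf = k.astype(float)
    log_comb = gammaln(nf) - gammaln(kf) - gammaln(nf - kf + 1)
    logp = (
        log_comb
        + betaln(kf + params.alpha, nf - kf + params.beta)
        - betaln(params.alpha, params.beta)
    )
    out = np.where(valid, logp, -np.inf)
    return _as_float_or_array(out)


def bnb_pmf(n, k, params: ModelParams):
    """BNB pmf: probability the k-th advance happens exactly at step ``n``.

    ``C(n-1, k-1) B(k + alpha, n - k + beta) / B(alpha, beta)`` for
    ``n >= k >= 1``; zero for ``n < k``.  For fixed ``k`` it sums to one over
    ``n = k, k+1, ...`` (the walk reaches any finite threshold almost surely).
    """
    log_pmf = bnb_log_pmf(n, k, params)
    return _as_float_or_array(np.exp(np.asarray(log_pmf, dtype=float)))


def bnb_mean(z_um: float, params: ModelParams) -> float:
    """Mean first-passage time (s) to travel a distance ``z`` (µm).

    ``<t> = tau * (z/a) * (alpha + beta - 1) / (alpha - 1)``; exists only for
    ``alpha > 1`` (heavier-than-Cauchy tails otherwise).
    """
    if params.alpha <= 1:
        raise ValueError(
            "mean first-passage time does not exist for alpha <= 1 "
            f"(got alpha={params.alpha})"
        )
    k = params.k_steps(z_um)
    if k < 1:
        raise ValueError("threshold distance must be at least one step")
    return params.step_time_s * k * (params.alpha + params.beta - 1) / (params.alpha - 1)


def bnb_variance(z_um: float, params: ModelParams) -> float:
    """Variance (s²) of the first-passage time to distance ``z`` (µm).

    Standard BNB variance, in walk units with ``k = z/a``::

        var(t) = tau^2 * k * beta * (k + alpha - 1) * (alpha + beta - 1)
                 / ((alpha - 2) (alpha - 1)^2)

    Exists only for ``alpha > 2``.  The ``- 1`` factors are the ones validated
    against direct pmf summation (see :func:`bnb_truncated_moments`); a
    ``+ 1`` variant of this formula circulates but fails that check by tens of
    percent at typical parameters.
    """
    if params.alpha <= 2:
        raise ValueError(
            "first-passage variance does not exist for alpha <= 2 "
            f"(got alpha={params.alpha})"
        )
    k = params.k_steps(z_um)
    if k < 1:
        raise ValueError("threshold distance must be at least one step")
    al, be = params.alpha, params.beta
    tau = params.step_time_s
    return (
        tau * tau * k * be * (k + al - 1) * (al + be - 1)
        / ((al - 2) * (al - 1) ** 2)
    )


@dataclass(frozen=True)
class TruncatedMoments:
    """Moments of the BNB law accumulated by direct summation.

    ``mass`` is the pmf mass captured by the truncation (should be ~1);
    ``tail_bound`` the analytic bound on what the truncation discarded from
    the heaviest running sum.
    """

    mean_steps: float
    var_steps: float
    mass: float
    n_terms: int
    tail_bound: float


def bnb_truncated_moments(
    k: int,
    params: ModelParams,
    *,
    rtol: float = 1e-9,
    n_cap: int | None = None,
    chunk: int = 65536,
) -> TruncatedMoments:
    """First-passage mean and variance by brute-force pmf summation.

    Accumulates ``sum n^m * F(n|k)`` in growing chunks until an analytic
    power-law tail bound falls below ``rtol`` of the running second moment, or
    ``n_cap`` terms (default ``10^6 * k``) are spent.  The BNB tail decays as
    ``n^-(alpha+1)``; after the last summed ``N`` the remaining
    ``sum_{n>N} n^m pmf(n)`` is appended as the integral of
    ``C x^(m-alpha-1)`` from ``N + 1/2`` with ``C`` matched to the pmf at
    ``N`` (accurate to relative O(1/N), far below the truncation itself for
    small ``alpha`` where the plain sum converges only like ``1/N``).  Serves
    as the independent arbiter for the closed-form :func:`bnb_mean` /
    :func:`bnb_variance`.
    """
    if k < 1:
        raise ValueError("threshold k must be >= 1")
    al = params.alpha
    if n_cap is None:
        n_cap = 1_000_000 * k
    s0 = 0.0  # mass
    s1 = 0.0  # sum n pmf
    s2 = 0.0  # sum n^2 pmf
    start = k
    tail = np.inf
    while start <= n_cap:
        stop = min(start + chunk, n_cap + 1)
        n = np.arange(start, stop, dtype=np.int64)
        pmf = np.asarray(bnb_pmf(n, k, params), dtype=float)
        s0 += pmf.sum()
        s1 += (n * pmf).sum()
        s2 += (n.astype(float) ** 2 * pmf).sum()
        last_n = float(stop - 1)
        last_pmf = float(pmf[-1])
        # integral bound on sum_{n>N} n^2 pmf(n), assuming pmf ~ C n^-(al+1)
        if al > 2:
            tail = last_pmf * last_n**3 / (al - 2)
            if tail < rtol * max(s2, 1e-300):
                start = stop
                break
        else:
            # second moment diverges; stop on the mass tail instead
            tail = last_pmf * last_n / al
            if tail < rtol * max(s0, 1e-300):
                start = stop
                break
        start = stop
    # power-law tail completion: pmf(n) ~ C n^-(alpha+1) for n > N
    c_match = last_pmf * last_n ** (al + 1.0)
    edge = last_n + 0.5
    s0 += c_match * edge ** (-al) / al
    if al > 1:
        s1 += c_match * edge ** (1.0 - al) / (al - 1.0)
    if al > 2:
        s2 += c_match * edge ** (2.0 - al) / (al - 2.0)
    mean = s1 / s0
    var = s2 / s0 - mean * mean
    return TruncatedMoments(
        mean_steps=mean, var_steps=var, mass=s0, n_terms=int(start - k),
        tail_bound=tail,
    )


def fpt_frame_probs(
    k: int,
    n_frames: int,
    params: ModelParams,
    *,
    steps_per_frame: int = 10,
) -> np.ndarray:
    """Probability that the threshold crossing is *observed* at each frame.

    A camera samples the walk every ``steps_per_frame`` elementary steps.
    Because the one-sided walk is monotone, the crossing is seen at frame
    ``m`` exactly when the true first-passage step ``n`` lies in
    ``(steps_per_frame*(m-1), steps_per_frame*m]``.  Returns an array of
    length ``n_frames`` for frames ``m = 1..n_frames``; entries for frames
    before the earliest possible crossing are zero.  The residual
    ``1 - sum`` is the probability the crossing happens after frame
    ``n_frames``.
    """
    if k < 1:
        raise ValueError("threshold k must be >= 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n_max = n_frames * steps_per_frame
    n = np.arange(k, n_max + 1)
    pmf = np.asarray(bnb_pmf(n, k, params), dtype=float)
    frame_idx = (n + steps_per_frame - 1) // steps_per_frame  # ceil(n / spf)
    out = np.zeros(n_frames, dtype=float)
    np.add.at(out, frame_idx - 1, pmf)
    return out
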