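"""Maximum-likelihood fitting of the beta-binomial displacement law.

Fits the beta-density shapes (alpha, beta) to integer displacement step
counts by minimizing the negative log-likelihood in (log alpha, log beta)
space (positivity without constraints) with the analytic digamma gradient,
initialized from method-of-moments estimates.  Standard errors come from the
observed-information matrix.  Goodness-of-fit summaries (binned chi-square,
total-variation distance) quantify model agreement for both displacement and
first-passage histograms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import polygamma, psi
from scipy.stats import chi2 as _chi2_dist

from .distributions import bb_log_pmf, bb_pmf, fpt_frame_probs
from .params import ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "DisplacementSample",
    "FitResult",
    "GofReport",
    "bb_neg_loglik",
    "mom_init",
    "fit_mle",
    "fit_joint",
    "gof_summary",
    "gof_fpt",
    "chi_square_binned",
]

LOG_BOUNDS = (-7.0, 7.0)


@dataclass(frozen=True)
class DisplacementSample:
    """Integer step counts observed at a common elapsed time t = n * tau."""

    k_values: np.ndarray
    n_trials: int
    t_seconds: float | None = None
    strain_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "k_values", np.asarray(self.k_values, dtype=np.int64)
        )
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.k_values.size and (
            self.k_values.min() < 0 or self.k_values.max() > self.n_trials
        ):
            raise ValueError("step counts must lie in [0, n_trials]")

    def __len__(self) -> int:
        return int(self.k_values.size)

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique step counts and their multiplicities."""
        return np.unique(self.k_values, return_counts=True)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a beta-binomial maximum-likelihood fit."""

    alpha_hat: float
    beta_hat: float
    neg_loglik: float
    converged: bool
    stderr_alpha: float
    stderr_beta: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "alpha_hat": self.alpha_hat,
            "beta_hat": self.beta_hat,
            "neg_loglik": self.neg_loglik,
            "converged": self.converged,
            "stderr_alpha": self.stderr_alpha,
            "stderr_beta": self.stderr_beta,
            "n_samples": self.n_samples,
        }


def _shapes(params) -> tuple[float, float]:
    if isinstance(params, ModelParams):
        return params.alpha, params.beta
    alpha, beta = params
    return float(alpha), float(beta)


def bb_neg_loglik(sample: DisplacementSample, params) -> float:
    """Negative log-likelihood of (alpha, beta) for one displacement sample.

    ``params`` may be a :class:`~dcvwalk.params.ModelParams` or an
    ``(alpha, beta)`` pair; the lattice constants do not enter the
    likelihood.  An empty sample contributes 0.
    """
    alpha, beta = _shapes(params)
    if len(sample) == 0:
        return 0.0
    uniq, cnt = sample.counts()
    p = ModelParams(alpha=alpha, beta=beta)
    return float(-(cnt * bb_log_pmf(uniq, sample.n_trials, p)).sum())


def mom_init(sample: DisplacementSample) -> tuple[float, float]:
    """Method-of-moments starting values for (alpha, beta).

    Solves the beta-binomial mean/variance equations; when the sample is not
    overdispersed relative to the binomial at its mean (or is degenerate) the
    equations have no positive solution and (1, 1) is returned with a
    warning.
    """
    k = sample.k_values
    n = sample.n_trials
    if len(sample) < 2:
        warnings.warn("too few samples for moment matching; starting from (1, 1)")
        return 1.0, 1.0
    mean = k.mean()
    var = k.var(ddof=1)
    p_hat = mean / n
    if not (0.0 < p_hat < 1.0) or var <= 0:
        warnings.warn("degenerate sample; starting from (1, 1)")
        return 1.0, 1.0
    binom_var = n * p_hat * (1 - p_hat)
    if n < 2 or var <= binom_var:
        warnings.warn(
            "sample not overdispersed relative to binomial; starting from (1, 1)"
        )
        return 1.0, 1.0
    rho = (var / binom_var - 1.0) / (n - 1.0)  # intra-class correlation
    if rho >= 1.0:
        warnings.warn("overdispersion beyond the beta-binomial range; (1, 1)")
        return 1.0, 1.0
    s = 1.0 / rho - 1.0  # alpha + beta
    return max(p_hat * s, 1e-6), max((1 - p_hat) * s, 1e-6)


def _nll_and_grad(log_ab: np.ndarray, samples: list[DisplacementSample]):
    """Summed negative log-likelihood and its gradient in log-shape space."""
    alpha, beta = np.exp(log_ab)
    nll = 0.0
    d_alpha = 0.0
    d_beta = 0.0
    for sample in samples:
        if len(sample) == 0:
            continue
        uniq, cnt = sample.counts()
        n = sample.n_trials
        total = cnt.sum()
        # log-likelihood terms that depend on (alpha, beta)
        nll -= float(
            (cnt * bb_log_pmf(uniq, n, ModelParams(alpha=alpha, beta=beta))).sum()
        )
        # d/d alpha of sum log B(k+a, n-k+b) - log B(a, b)
        common = psi(alpha + beta) - psi(n + alpha + beta)
        d_alpha -= float((cnt * (psi(uniq + alpha) - psi(alpha) + common)).sum())
        d_beta -= float(
            (cnt * (psi(n - uniq + beta) - psi(beta) + common)).sum()
        )
        del total
    grad = np.array([d_alpha * alpha, d_beta * beta])  # chain rule for log space
    return nll, grad


def _observed_information(alpha, beta, samples) -> np.ndarray:
    """Analytic Hessian of the negative log-likelihood in (alpha, beta)."""
    h = np.zeros((2, 2))
    for sample in samples:
        if len(sample) == 0:
            continue
        uniq, cnt = sample.counts()
        n = sample.n_trials
        tri = polygamma(1, alpha + beta) - polygamma(1, n + alpha + beta)
        haa = (cnt * (polygamma(1, uniq + alpha) - polygamma(1, alpha) + tri)).sum()
        hbb = (
            cnt * (polygamma(1, n - uniq + beta) - polygamma(1, beta) + tri)
        ).sum()
        hab = (cnt * tri).sum()
        h -= np.array([[haa, hab], [hab, hbb]])
    return h


def _stderrs(alpha, beta, samples) -> tuple[float, float]:
    h = _observed_information(alpha, beta, samples)
    try:
        cov = np.linalg.inv(h)
        se = np.sqrt(np.diag(cov))
        if np.any(~np.isfinite(se)):
            raise np.linalg.LinAlgError
        return float(se[0]), float(se[1])
    except np.linalg.LinAlgError:
        logger.warning("observed information not invertible; stderrs set to nan")
        return float("nan"), float("nan")


def _check_boundary(samples: list[DisplacementSample]) -> None:
    ks = np.concatenate([s.k_values for s in samples if len(s)])
    ns = np.concatenate(
        [np.full(len(s), s.n_trials) for s in samples if len(s)]
    )
    if np.all(ks == 0) or np.all(ks == ns):
        raise ValueError(
            "beta density degenerate: every count sits at the support boundary"
        )


def fit_joint(
    samples: list[DisplacementSample],
    *,
    min_samples: int = 10,
    init: tuple[float, float] | None = None,
    log_bounds: tuple[float, float] = LOG_BOUNDS,
) -> FitResult:
    """Fit one (alpha, beta) to displacement samples at several lags.

    Minimizes the summed negative log-likelihood over (log alpha, log beta)
    with L-BFGS-B from a method-of-moments start.  Each sample keeps its own
    trial count ``n``; with a single sample this is :func:`fit_mle`.  The
    joint likelihood treats lags as independent, ignoring that displacements
    of one track at different lags overlap.
    """
    if not samples:
        raise ValueError("no samples to fit")
    n_total = sum(len(s) for s in samples)
    if n_total < min_samples:
        raise ValueError(
            f"need at least {min_samples} observations, got {n_total}"
        )
    _check_boundary(samples)
    if init is None:
        richest = max(samples, key=len)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            init = mom_init(richest)
    x0 = np.clip(np.log(init), log_bounds[0], log_bounds[1])
    res = minimize(
        _nll_and_grad,
        x0,
        args=(samples,),
        jac=True,
        method="L-BFGS-B",
        bounds=[log_bounds, log_bounds],
    )
    alpha_hat, beta_hat = np.exp(res.x)
    if not res.success:
        logger.warning("MLE did not converge: %s", res.message)
    se_a, se_b = _stderrs(alpha_hat, beta_hat, samples)
    return FitResult(
        alpha_hat=float(alpha_hat),
        beta_hat=float(beta_hat),
        neg_loglik=float(res.fun),
        converged=bool(res.success),
        stderr_alpha=se_a,
        stderr_beta=se_b,
        n_samples=n_total,
    )


def fit_mle(sample: DisplacementSample, **kwargs) -> FitResult:
    """Maximum-likelihood (alpha, beta) for a single displacement sample."""
    return fit_joint([sample], **kwargs)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GofReport:
    chi2: float
    dof: int
    p_value: float
    tv_distance: float
    n_bins: int


def _merge_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float):
    """Greedy left-to-right merge until every bin's expectation >= min."""
    obs_bins: list[float] = []
    exp_bins: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_bins.append(acc_o)
            exp_bins.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if exp_bins:
            obs_bins[-1] += acc_o
            exp_bins[-1] += acc_e
        else:
            obs_bins.append(acc_o)
            exp_bins.append(acc_e)
    return np.asarray(obs_bins), np.asarray(exp_bins)


def chi_square_binned(
    observed_counts: np.ndarray,
    expected_counts: np.ndarray,
    *,
    n_fitted_params: int = 0,
    min_expected: float = 5.0,
) -> tuple[float, int, float]:
    """Pearson chi-square with adjacent-bin merging to expected >= min.

    Returns (statistic, degrees of freedom, p-value); dof is
    ``bins - 1 - n_fitted_params``, floored at 1.  Raises when merging cannot
    produce at least two bins.
    """
    obs, exp = _merge_bins(
        np.asarray(observed_counts, dtype=float),
        np.asarray(expected_counts, dtype=float),
        min_expected,
    )
    if len(obs) < 2:
        raise ValueError("too few observations to form chi-square bins")
    stat = float(((obs - exp) ** 2 / exp).sum())
    dof = max(len(obs) - 1 - n_fitted_params, 1)
    return stat, dof, float(_chi2_dist.sf(stat, dof))


def gof_summary(
    sample: DisplacementSample,
    fit: FitResult,
    *,
    min_expected: float = 5.0,
    n_fitted_params: int = 2,
) -> GofReport:
    """Chi-square and total-variation agreement of a fitted displacement law.

    Bins are the integer step counts 0..n merged to expected count >=
    ``min_expected``; the default dof adjustment assumes both shapes were
    fitted to this sample (set ``n_fitted_params=0`` when testing fixed,
    externally chosen parameters).
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    n = sample.n_trials
    params = ModelParams(alpha=fit.alpha_hat, beta=fit.beta_hat)
    support = np.arange(n + 1)
    pmf = np.asarray(bb_pmf(support, n, params), dtype=float)
    observed = np.bincount(sample.k_values, minlength=n + 1).astype(float)
    total = observed.sum()
    stat, dof, p = chi_square_binned(
        observed,
        pmf * total,
        n_fitted_params=n_fitted_params,
        min_expected=min_expected,
    )
    tv = 0.5 * float(np.abs(observed / total - pmf).sum())
    return GofReport(chi2=stat, dof=dof, p_value=p, tv_distance=tv, n_bins=dof + 1 + n_fitted_params)


def gof_fpt(
    fpt_times_s: np.ndarray,
    threshold_um: float,
    params: ModelParams,
    *,
    frame_interval_s: float = 0.1563,
    n_at_risk_frames: np.ndarray | None = None,
    min_expected: float = 5.0,
    n_fitted_params: int = 0,
) -> GofReport:
    """Chi-square agreement of empirical FPTs with the BNB prediction.

    ``fpt_times_s`` are uncensored first-passage times observed at frame
    resolution.  Expected frame-bin counts come from the BNB pmf aggregated
    over the elementary steps inside each frame; a final open bin collects
    the tail beyond the last observed frame.  When ``n_at_risk_frames``
    (number of tracks still long enough to reach each frame) is given it
    scales the expectation per frame, accounting for length censoring under
    the generator's length-independent-of-p design.
    """
    times = np.asarray(fpt_times_s, dtype=float)
    if times.size == 0:
        raise ValueError("no uncensored first passages to test")
    steps_per_frame = round(frame_interval_s / params.step_time_s)
    k = params.k_steps(threshold_um)
    frames = np.rint(times / frame_interval_s).astype(int)
    if frames.min() < 1:
        raise ValueError("first-passage times must be at least one frame")
    m_max = int(frames.max())
    probs = fpt_frame_probs(k, m_max, params, steps_per_frame=steps_per_frame)
    observed = np.bincount(frames, minlength=m_max + 1)[1:].astype(float)
    if n_at_risk_frames is not None:
        at_risk = np.asarray(n_at_risk_frames, dtype=float)[:m_max]
        expected = probs * at_risk
        tail_expected = 0.0  # censoring model absorbs the tail
    else:
        total = observed.sum()
        expected = probs * total
        tail_expected = max(total - expected.sum(), 0.0)
    observed = np.append(observed, 0.0)
    expected = np.append(expected, tail_expected)
    stat, dof, p = chi_square_binned(
        observed, expected, n_fitted_params=n_fitted_params, min_expected=min_expected
    )
    emp = observed[:-1] / observed.sum()
    theo = probs / probs.sum()
    tv = 0.5 * float(np.abs(emp - theo).sum())
    return GofReport(chi2=stat, dof=dof, p_value=p, tv_distance=tv, n_bins=dof + 1 + n_fitted_params)
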