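"""ABC inference of selection strength conditional on copy-number class.

Selection coefficients are proposed from a prior family, each proposal is
run through the forward simulator, and proposals whose sampled copy-number
class matches the observed class form the posterior sample. Posterior and
closed-form prior probabilities of exceeding an ``hs`` threshold combine
into Bayes odds. Deterministic mutation-selection-balance expectations and
the two-category mixture arithmetic for per-mutation deleterious rates live
here as well.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .wf_forward import COPY_LOW_MAX, SiteSimConfig, simulate_copies_batch

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "PosteriorSample",
    "BayesOddsResult",
    "sample_prior",
    "prior_prob_above",
    "abc_posterior",
    "posterior_prob_threshold",
    "bayes_odds",
    "msb_expected_frequency",
    "msb_expected_copies",
    "dfe_mixture_fraction",
    "per_mutation_deleterious_rate",
    "per_individual_rate",
]

PRIOR_FAMILIES = ("log_uniform_s", "beta_s", "lognormal_log_s", "gamma_Nes")


@dataclass(frozen=True)
class PriorSpec:
    """A prior family over the selection coefficient ``s``.

    Families and their ``params``:

    - ``log_uniform_s``: ``(log10_lo, log10_hi)``, default ``(-7, 0)``;
      ``log10(s) ~ Uniform``.
    - ``beta_s``: ``(alpha, beta)``; ``s ~ Beta``.
    - ``lognormal_log_s``: ``(mu, sigma)`` on the natural-log scale;
      ``ln(s) ~ Normal``. Draws above 1 are clamped to 1.
    - ``gamma_Nes``: ``(shape, scale)``; ``Ne_ref * s ~ Gamma``, then
      divided by ``Ne_ref``. Draws above 1 are clamped to 1.
    """

    family: str
    params: tuple = ()
    h: float = 0.5
    Ne_ref: float = 10_000.0

    def __post_init__(self) -> None:
        if self.family not in PRIOR_FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}; one of {PRIOR_FAMILIES}")
        params = tuple(self.params)
        if self.family == "log_uniform_s" and not params:
            params = (-7.0, 0.0)
        object.__setattr__(self, "params", params)
        if self.family == "log_uniform_s":
            lo, hi = params
            if not (lo < hi <= 0 and lo >= -7 - 1e-12):
                raise ValueError("log_uniform_s bounds must satisfy -7 <= lo < hi <= 0")
        elif self.family == "beta_s":
            a, b = params
            if a <= 0 or b <= 0:
                raise ValueError("beta_s requires alpha, beta > 0")
        elif self.family == "lognormal_log_s":
            _, sigma = params
            if sigma <= 0:
                raise ValueError("lognormal_log_s requires sigma > 0")
        elif self.family == "gamma_Nes":
            shape, scale = params
            if shape <= 0 or scale <= 0 or self.Ne_ref <= 0:
                raise ValueError("gamma_Nes requires shape, scale, Ne_ref > 0")


@dataclass(frozen=True)
class PosteriorSample:
    accepted_s: np.ndarray
    proposals: int
    condition: str
    n_sample: int
    h: float

    @property
    def acceptance_rate(self) -> float:
        return len(self.accepted_s) / self.proposals


@dataclass(frozen=True)
class BayesOddsResult:
    threshold: float  # on the hs scale
    posterior_prob: float
    prior_prob: float
    posterior_odds: float
    prior_odds: float
    bayes_odds: float


def sample_prior(spec: PriorSpec, m: int, seed: int = 0) -> np.ndarray:
    """Draw ``m`` i.i.d. selection coefficients from the prior."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    if spec.family == "log_uniform_s":
        lo, hi = spec.params
        s = 10.0 ** rng.uniform(lo, hi, size=m)
    elif spec.family == "beta_s":
        a, b = spec.params
        s = rng.beta(a, b, size=m)
    elif spec.family == "lognormal_log_s":
        mu, sigma = spec.params
        s = np.exp(rng.normal(mu, sigma, size=m))
    else:  # gamma_Nes
        shape, scale = spec.params
        s = rng.gamma(shape, scale, size=m) / spec.Ne_ref
    n_clamped = int(np.sum(s > 1.0))
    if n_clamped:
        logger.info("clamped %d of %d prior draws at s = 1", n_clamped, m)
        s = np.minimum(s, 1.0)
    return s


def prior_prob_above(spec: PriorSpec, threshold_hs: float) -> float:
    """Closed-form prior probability that ``h * s`` exceeds ``threshold_hs``.

    Clamping at ``s = 1`` piles tail mass onto 1, which leaves exceedance
    probabilities for thresholds below ``h`` unchanged.
    """
    x = threshold_hs / spec.h
    if x <= 0:
        return 1.0
    if x > 1:
        return 0.0
    if spec.family == "log_uniform_s":
        lo, hi = spec.params
        lx = math.log10(x)
        if lx <= lo:
            return 1.0
        if lx >= hi:
            return 0.0
        return (hi - lx) / (hi - lo)
    if spec.family == "beta_s":
        a, b = spec.params
        return float(stats.beta.sf(x, a, b))
    if spec.family == "lognormal_log_s":
        mu, sigma = spec.params
        return float(stats.norm.sf((math.log(x) - mu) / sigma))
    shape, scale = spec.params
    return float(stats.gamma.sf(x * spec.Ne_ref, shape, scale=scale))


def abc_posterior(
    prior: PriorSpec,
    sim_template: SiteSimConfig,
    observed: str,
    proposals: int,
    seed: int = 0,
) -> PosteriorSample:
    """Rejection-ABC posterior over ``s`` given an observed copy-number class.

    ``observed`` is ``zero``, ``low``, ``high``, ``segregating`` (low or
    high pooled) or ``any`` (no conditioning; posterior equals the prior up
    to Monte-Carlo noise). ``sim_template.s`` is ignored; each proposal
    draws its own ``s`` and runs one forward simulation.
    """
    if proposals < 1:
        raise ValueError("proposals must be >= 1")
    valid = ("zero", "low", "high", "segregating", "any")
    if observed not in valid:
        raise ValueError(f"observed must be one of {valid}")
    s_prop = sample_prior(prior, proposals, seed=seed)
    template = SiteSimConfig(
        u=sim_template.u, v=sim_template.v, s=0.0, h=prior.h,
        model=sim_template.model, n_sample=sim_template.n_sample, seed=seed,
    )
    copies, _ = simulate_copies_batch(template, s_values=s_prop)
    if observed == "any":
        mask = np.ones(proposals, dtype=bool)
    elif observed == "segregating":
        mask = (copies > 0) & (copies < template.n_sample)
    else:
        classes = np.where(
            copies == 0, "zero", np.where(copies <= COPY_LOW_MAX, "low", "high")
        )
        mask = classes == observed
    accepted = s_prop[mask]
    if len(accepted) == 0:
        warnings.warn("ABC accepted zero proposals; posterior is empty")
    return PosteriorSample(
        accepted_s=accepted, proposals=proposals, condition=observed,
        n_sample=template.n_sample, h=prior.h,
    )


def posterior_prob_threshold(post: PosteriorSample, threshold_hs: float) -> float:
    """Fraction of accepted draws with ``h * s >= threshold_hs``."""
    if len(post.accepted_s) == 0:
        raise ValueError("empty posterior")
    return float(np.mean(post.h * post.accepted_s >= threshold_hs))


def _odds(p: float) -> float:
    if p >= 1.0:
        return math.inf
    return p / (1.0 - p)


def bayes_odds(post: PosteriorSample, prior: PriorSpec, threshold_hs: float) -> BayesOddsResult:
    """Posterior odds of ``hs > threshold`` divided by the closed-form prior odds."""
    p_post = posterior_prob_threshold(post, threshold_hs)
    p_prior = prior_prob_above(prior, threshold_hs)
    if not 0.0 < p_prior < 1.0:
        raise ValueError("prior probability of exceeding the threshold must be in (0, 1)")
    post_odds = _odds(p_post)
    prior_odds = _odds(p_prior)
    if p_post in (0.0, 1.0):
        warnings.warn(f"posterior probability is {p_post}; Bayes odds degenerate")
    bo = post_odds / prior_odds if math.isfinite(post_odds) else math.inf
    return BayesOddsResult(
        threshold=threshold_hs, posterior_prob=p_post, prior_prob=p_prior,
        posterior_odds=post_odds, prior_odds=prior_odds, bayes_odds=bo,
    )


# ---------------------------------------------------------------------------
# deterministic mutation-selection balance and DFE mixture arithmetic
# ---------------------------------------------------------------------------

def msb_expected_frequency(u: float, hs: float) -> float:
    """Deterministic balance frequency ``u / hs`` (capped at 1)."""
    if hs <= 0:
        raise ValueError("hs must be > 0")
    if u < 0:
        raise ValueError("u must be >= 0")
    q = u / hs
    if q > 1.0:
        warnings.warn("u >= hs: mutation-selection balance approximation invalid; capped at 1")
        return 1.0
    return q


def msb_expected_copies(u: float, hs: float, n: int) -> float:
    """Expected derived-allele copies ``n * u / hs`` in a sample of ``n``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * msb_expected_frequency(u, hs)


def dfe_mixture_fraction(
    frac_invariant: float,
    p_del_given_invariant: float,
    p_del_given_segregating: float,
) -> float:
    """Deleterious fraction of de novo mutations from the two-category mixture."""
    for x in (frac_invariant, p_del_given_invariant, p_del_given_segregating):
        if not 0.0 <= x <= 1.0:
            raise ValueError("all mixture inputs must lie in [0, 1]")
    return (
        frac_invariant * p_del_given_invariant
        + (1.0 - frac_invariant) * p_del_given_segregating
    )


def per_mutation_deleterious_rate(
    frac_missense_del: float, p_missense: float,
    frac_lof_del: float, p_lof: float,
) -> float:
    """Probability a de novo point mutation is strongly deleterious.

    Combines per-class deleterious fractions with the probabilities that a
    de novo mutation falls in each class. The reciprocal gives "1 in X".
    """
    for x in (frac_missense_del, p_missense, frac_lof_del, p_lof):
        if not 0.0 <= x <= 1.0:
            raise ValueError("all inputs must lie in [0, 1]")
    rate = frac_missense_del * p_missense + frac_lof_del * p_lof
    if rate == 0.0:
        warnings.warn("per-mutation deleterious rate is zero (1 in infinity)")
    return rate


def per_individual_rate(per_mutation: float, mutations_per_birth: float) -> float:
    """Expected strongly deleterious de novo mutations per birth."""
    if per_mutation < 0 or mutations_per_birth < 0:
        raise ValueError("inputs must be >= 0")
    expectation = per_mutation * mutations_per_birth
    if expectation == 0.0:
        warnings.warn("expected count per birth is zero")
    return expectation


def one_in_x(probability: float) -> float:
    """Reciprocal "1 in X" formatting helper; inf for zero probability."""
    return math.inf if probability == 0 else 1.0 / probability
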