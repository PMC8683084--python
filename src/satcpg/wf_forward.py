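"""Forward Wright-Fisher simulation of a single bi-allelic site.

Each generation applies, in order: deterministic mutation pressure
(forward rate ``u``, back rate ``v``), deterministic diploid viability
selection (fitness ``1 - hs`` for heterozygotes, ``1 - s`` for derived
homozygotes), and binomial drift at the generation's diploid size. The
derived allele starts absent; a neutral burn-in of
``burn_in_multiplier * N_ancestral`` generations at the ancestral size
precedes the demographic epochs, and ``n_sample`` chromosomes are drawn
binomially from the final population frequency.

Replicate ``r`` runs on its own counter-derived RNG substream
(``SeedSequence((seed, r))``), so a given replicate is reproducible
regardless of how many replicates are requested or how they are batched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numba
import numpy as np

from .demography import DemographicModel

__all__ = [
    "COPY_LOW_MAX",
    "SiteSimConfig",
    "SiteSimResult",
    "MonteCarloProbability",
    "MockReferenceRates",
    "classify_copies",
    "simulate_site",
    "simulate_copies_batch",
    "segregating_probability",
    "mock_reference_rates",
]

#: inclusive upper bound of the "low" copy-number class
COPY_LOW_MAX = 10


@dataclass(frozen=True)
class SiteSimConfig:
    """Mutation, selection and sampling parameters for one site."""

    u: float
    v: float
    s: float
    model: DemographicModel
    n_sample: int
    h: float = 0.5
    seed: int = 0
    sampling: Literal["binomial", "hypergeometric"] = "binomial"

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")
        if not 0.0 <= self.h * self.s <= 1.0:
            raise ValueError("h*s must lie in [0, 1]")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must lie in [0, 1]")
        if self.n_sample < 1:
            raise ValueError("n_sample must be >= 1")


@dataclass(frozen=True)
class SiteSimResult:
    copies: int
    pop_freq: float
    segregating: bool
    copy_class: str


@dataclass(frozen=True)
class MonteCarloProbability:
    probability: float
    se: float
    reps: int


@dataclass(frozen=True)
class MockReferenceRates:
    """Rates of reference/ancestral discordance in mock-reference sampling."""

    p_derived_reference: float
    se_derived_reference: float
    p_reversed_reference: float
    se_reversed_reference: float
    reps: int


def classify_copies(copies: int, n_sample: int) -> str:
    """Copy-number class: ``zero`` (0), ``low`` (1-10) or ``high`` (>10)."""
    if copies < 0 or copies > n_sample:
        raise ValueError(f"copies must lie in [0, n_sample], got {copies}")
    if copies == 0:
        return "zero"
    return "low" if copies <= COPY_LOW_MAX else "high"


@numba.njit(cache=True)
def _wf_kernel(sizes, neutral_gens, u, v, s_arr, h, n_sample, seeds):  # pragma: no cover
    reps = s_arr.shape[0]
    copies = np.empty(reps, dtype=np.int64)
    qfin = np.empty(reps, dtype=np.float64)
    total = sizes.shape[0]
    for r in range(reps):
        np.random.seed(seeds[r])
        s = s_arr[r]
        w11 = 1.0 - s
        w01 = 1.0 - h * s
        q = 0.0
        for t in range(total):
            # mutation pressure
            q = q * (1.0 - v) + (1.0 - q) * u
            # viability selection (burn-in evolves neutrally)
            if s > 0.0 and t >= neutral_gens:
                wbar = q * q * w11 + 2.0 * q * (1.0 - q) * w01 + (1.0 - q) * (1.0 - q)
                if wbar > 0.0:
                    q = (q * q * w11 + q * (1.0 - q) * w01) / wbar
                else:
                    # s = 1 with the derived allele fixed: no survivors to
                    # shift frequency; keep q = 1 and let mutation re-seed
                    q = 1.0
            # drift
            n2 = 2 * sizes[t]
            q = np.random.binomial(n2, q) / n2
        copies[r] = np.random.binomial(n_sample, q)
        qfin[r] = q
    return copies, qfin


def _replicate_seeds(seed: int, reps: int, start: int = 0) -> np.ndarray:
    """Counter-based 32-bit seeds for replicates ``start .. start+reps-1``."""
    out = np.empty(reps, dtype=np.uint32)
    for i in range(reps):
        out[i] = np.random.SeedSequence((seed, start + i)).generate_state(1, np.uint32)[0]
    return out


def simulate_copies_batch(
    config: SiteSimConfig,
    s_values: np.ndarray | None = None,
    reps: int | None = None,
    first_replicate: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run a batch of independent site simulations.

    Either pass ``s_values`` (one selection coefficient per replicate, used
    by ABC) or ``reps`` to repeat ``config.s``. Returns ``(copies, pop_freq)``
    arrays. Replicate ``first_replicate + i`` uses the substream derived from
    ``(config.seed, first_replicate + i)``.
    """
    if s_values is None:
        if reps is None:
            raise ValueError("pass either s_values or reps")
        s_values = np.full(reps, float(config.s))
    s_values = np.ascontiguousarray(s_values, dtype=np.float64)
    sizes = config.model.generation_sizes(include_burn_in=True)
    neutral_gens = config.model.burn_in_generations
    seeds = _replicate_seeds(config.seed, len(s_values), start=first_replicate)
    copies, qfin = _wf_kernel(
        sizes, neutral_gens, float(config.u), float(config.v), s_values,
        float(config.h), int(config.n_sample), seeds,
    )
    if config.sampling == "hypergeometric":
        # resample copies without replacement from the realized allele counts;
        # drawn from a batch-level stream (documented deviation from the
        # per-replicate substream contract, only relevant when n ~ 2N)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x68797065)))
        n2 = 2 * int(config.model.size_at(0))
        ngood = np.round(qfin * n2).astype(np.int64)
        copies = rng.hypergeometric(ngood, n2 - ngood, int(config.n_sample))
    return copies, qfin


def simulate_site(config: SiteSimConfig, replicate: int = 0) -> SiteSimResult:
    """Simulate one site; ``replicate`` selects the RNG substream."""
    copies, qfin = simulate_copies_batch(config, reps=1, first_replicate=replicate)
    c = int(copies[0])
    return SiteSimResult(
        copies=c,
        pop_freq=float(qfin[0]),
        segregating=0 < c < config.n_sample,
        copy_class=classify_copies(c, config.n_sample),
    )


def segregating_probability(config: SiteSimConfig, reps: int) -> MonteCarloProbability:
    """Monte-Carlo probability that the site is segregating in the sample."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    copies, _ = simulate_copies_batch(config, reps=reps)
    seg = (copies > 0) & (copies < config.n_sample)
    p = float(seg.mean())
    se = math.sqrt(p * (1.0 - p) / reps)
    return MonteCarloProbability(probability=p, se=se, reps=reps)


def mock_reference_rates(config: SiteSimConfig, reps: int) -> MockReferenceRates:
    """Rates of mock-reference discordance with the ancestral allele.

    For each replicate one chromosome is drawn at the end of the simulation
    as a mock haploid reference. The first proportion is the fraction of
    replicates in which the reference carries the derived allele while the
    ancestral allele is still present in the population; the second repeats
    the experiment under the reversed mutation regime (ancestral state
    swapped, forward rate ``v``, back rate ``u``) and reports how often the
    original ancestral allele ends up as the reference.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    _, q1 = simulate_copies_batch(config, reps=reps)
    rev = SiteSimConfig(
        u=config.v, v=config.u, s=config.s, h=config.h, model=config.model,
        n_sample=config.n_sample, seed=config.seed + 1,
    )
    _, q2 = simulate_copies_batch(rev, reps=reps)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2**31)))
    ref1 = rng.random(reps) < q1
    ref2 = rng.random(reps) < q2
    e1 = ref1 & (q1 < 1.0)
    e2 = ref2
    p1, p2 = float(e1.mean()), float(e2.mean())
    return MockReferenceRates(
        p_derived_reference=p1,
        se_derived_reference=math.sqrt(p1 * (1 - p1) / reps),
        p_reversed_reference=p2,
        se_reversed_reference=math.sqrt(p2 * (1 - p2) / reps),
        reps=reps,
    )
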