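"""Synthetic site tables with known ground truth.

Generates per-opportunity site tables carrying the statistical structure the
saturation analysis assumes — annotation classes with class-specific
mutation-rate means, methylation levels, a per-class DFE over ``hs``, an
optional constraint score correlated with the true effect, and an optional
linked-selection covariate. Hidden truth (the per-site ``hs``) is written to
a separate table so downstream statistics cannot read it by accident.
Observations (segregating status / copy counts) come either from the
forward simulator or, for all-neutral tables, from a Poisson number of
mutations on simulated genealogy lengths; de novo counts are Poisson with
mean ``2 * n_trios * u_site``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .coalescent_lengths import sample_tree_lengths
from .demography import DemographicModel
from .wf_forward import COPY_LOW_MAX, SiteSimConfig, simulate_copies_batch

__all__ = [
    "ClassConfig",
    "SyntheticConfig",
    "generate_site_table",
    "simulate_observations",
    "simulate_dnms",
    "DEFAULT_RATES",
]

#: default per-site per-generation mutation-rate means by mutation class
DEFAULT_RATES = {
    "mCpG_transition": 1.17e-7,
    "CpG_lowmeth_transition": 2.0e-8,
    "C>T_other": 0.9e-8,
    "T>A": 1.2e-9,
}

_CONTEXTS = {
    "mCpG_transition": ("ACG", "CCG", "GCG", "TCG"),
    "CpG_lowmeth_transition": ("ACG", "CCG", "GCG", "TCG"),
    "C>T_other": ("ACA", "CCT", "GCC", "TCA"),
    "T>A": ("ATA", "CTG", "GTC", "TTA"),
}


@dataclass(frozen=True)
class ClassConfig:
    """One annotation class in a synthetic table.

    ``dfe`` is a sequence of ``(weight, hs)`` point masses; weights must sum
    to 1. ``u`` defaults to the mutation-class mean rate; ``u_jitter_sd``
    applies optional lognormal jitter (sd on the log scale) around it.
    """

    annotation: str
    n_sites: int
    mutation_class: str = "mCpG_transition"
    u: float | None = None
    u_jitter_sd: float = 0.0
    dfe: Sequence[tuple[float, float]] = ((1.0, 0.0),)
    compartment: str = "exon"

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        w = sum(p for p, _ in self.dfe)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"DFE weights must sum to 1, got {w}")
        if self.u is None and self.mutation_class not in DEFAULT_RATES:
            raise ValueError(f"no default rate for mutation class {self.mutation_class!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    classes: tuple[ClassConfig, ...]
    n_trios: int = 2976
    n_chromosomes: int = 780_000
    score_rank_noise: float | None = None  # sd of noise added to hs rank score
    covariate_confounding: float = 0.0  # shift of covariate mean per unit hs rank
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.n_trios < 0:
            raise ValueError("n_trios must be >= 0")
        if self.n_chromosomes < 0:
            raise ValueError("n_chromosomes must be >= 0")


def generate_site_table(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit ``(sites, truth)`` tables.

    ``sites`` has the public columns (annotation, mutation class, context,
    methylation, ``u_site``, optional score and covariate); ``truth`` holds
    ``site_id`` and the hidden per-site ``hs`` drawn from the class DFE.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    site_rows = []
    truth_rows = []
    sid = 0
    for cls in config.classes:
        base_u = cls.u if cls.u is not None else DEFAULT_RATES[cls.mutation_class]
        weights = np.array([p for p, _ in cls.dfe])
        hs_values = np.array([hs for _, hs in cls.dfe])
        for _ in range(cls.n_sites):
            if cls.u_jitter_sd > 0:
                u_site = base_u * math.exp(rng.normal(0.0, cls.u_jitter_sd))
            else:
                u_site = base_u
            if cls.mutation_class == "mCpG_transition":
                methylation = rng.uniform(0.65, 1.0)
            elif cls.mutation_class == "CpG_lowmeth_transition":
                methylation = rng.uniform(0.0, 0.65)
            else:
                methylation = math.nan
            hs = float(rng.choice(hs_values, p=weights))
            site_rows.append(
                dict(
                    site_id=sid,
                    mutation_class=cls.mutation_class,
                    annotation=cls.annotation,
                    methylation=methylation,
                    context=str(rng.choice(_CONTEXTS.get(cls.mutation_class, ("NNN",)))),
                    u_site=u_site,
                    compartment=cls.compartment,
                )
            )
            truth_rows.append(dict(site_id=sid, hs=hs))
            sid += 1
    sites = pd.DataFrame(site_rows)
    truth = pd.DataFrame(truth_rows)

    if len(sites):
        hs_rank = truth["hs"].rank(pct=True).to_numpy()
        if config.score_rank_noise is not None:
            sites["score"] = hs_rank + rng.normal(0.0, config.score_rank_noise, len(sites))
        if config.covariate_confounding != 0.0:
            sites["covariate"] = rng.normal(0.0, 1.0, len(sites)) + (
                config.covariate_confounding * hs_rank
            )
        else:
            sites["covariate"] = rng.normal(0.0, 1.0, len(sites))
    return sites, truth


def simulate_observations(
    table: pd.DataFrame,
    model: DemographicModel,
    n_chromosomes: int,
    seed: int = 0,
    engine: Literal["forward", "poisson_tree"] = "forward",
    truth: pd.DataFrame | None = None,
    u_forward_default_v: float = 5e-9,
    tree_reps: int = 200,
) -> pd.DataFrame:
    """Attach ``segregating`` (and ``copies`` for the forward engine) to a table.

    The ``forward`` engine runs one Wright-Fisher simulation per site using
    the hidden ``hs`` from ``truth`` (all-neutral when ``truth`` is None).
    The ``poisson_tree`` engine requires an all-neutral table and flags each
    site as segregating with probability ``1 - exp(-u_site * L)``, with
    ``L`` drawn from simulated genealogy lengths.
    """
    out = table.copy()
    if n_chromosomes == 0:
        out["segregating"] = False
        out["copies"] = 0
        return out
    if truth is not None:
        hs = truth.set_index("site_id").loc[out["site_id"], "hs"].to_numpy(float)
    else:
        hs = np.zeros(len(out))

    if engine == "poisson_tree":
        if np.any(hs != 0.0):
            raise ValueError("poisson_tree engine requires an all-neutral table")
        rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
        lengths = sample_tree_lengths(model, n_chromosomes, tree_reps, seed=seed)
        L = rng.choice(lengths, size=len(out))
        p_seg = -np.expm1(-out["u_site"].to_numpy(float) * L)
        out["segregating"] = rng.random(len(out)) < p_seg
        return out

    if engine != "forward":
        raise ValueError("engine must be 'forward' or 'poisson_tree'")

    copies = np.empty(len(out), dtype=np.int64)
    h = 0.5
    # group by identical (u, hs is per-site): run per unique u in batches
    u_arr = out["u_site"].to_numpy(float)
    for g, u in enumerate(np.unique(u_arr)):
        idx = np.where(u_arr == u)[0]
        cfg = SiteSimConfig(
            u=float(u), v=u_forward_default_v, s=0.0, h=h,
            model=model, n_sample=int(n_chromosomes), seed=seed + 7919 * g,
        )
        s_vals = np.clip(hs[idx] / h, 0.0, 1.0)  # s = hs / h
        c, _ = simulate_copies_batch(cfg, s_values=s_vals)
        copies[idx] = c
    out["copies"] = copies
    out["segregating"] = (copies > 0) & (copies < n_chromosomes)
    out["copy_class"] = np.where(
        copies == 0, "zero", np.where(copies <= COPY_LOW_MAX, "low", "high")
    )
    return out


def simulate_dnms(table: pd.DataFrame, n_trios: int, seed: int = 0) -> pd.DataFrame:
    """Add a Poisson ``dnm_count`` column with mean ``2 * n_trios * u_site``."""
    if n_trios < 0:
        raise ValueError("n_trios must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    out = table.copy()
    out["dnm_count"] = rng.poisson(2.0 * n_trios * out["u_site"].to_numpy(float))
    return out
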