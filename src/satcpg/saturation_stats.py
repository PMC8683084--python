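"""Site-table saturation statistics.

All operations act on a "site table": a pandas DataFrame with one row per
mutational opportunity and (a subset of) the columns

    site_id, mutation_class, annotation, functional_site, methylation,
    context, u_site, score, covariate, segregating, dnm_count,
    half_of_transcript, compartment

Fractions of segregating sites carry exact Clopper-Pearson 95 % intervals;
annotation classes are compared by rescaling to a neutral class and by
Fisher exact tests. Invariant-site p-values and FDRs, rate-matched bins of
sites, de novo mutation rates with exact Poisson intervals, and the
saturation-based genealogy-length estimators live here too.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSummary",
    "RescaledFraction",
    "clopper_pearson",
    "fraction_segregating",
    "rescale_to_neutral",
    "fisher_exact_2x2",
    "neutral_invariance_pvalue",
    "fdr_invariant",
    "matched_fraction_segregating",
    "bin_sites",
    "bin_frequency_deterministic",
    "dnm_rate",
    "multihit_counts",
    "pathogenic_enrichment_odds",
    "genealogy_length_from_saturation",
    "genealogy_length_threshold",
    "score_decile_summary",
]

SITE_COLUMNS = [
    "site_id", "mutation_class", "annotation", "functional_site", "methylation",
    "context", "u_site", "score", "covariate", "segregating", "dnm_count",
    "half_of_transcript", "compartment",
]


@dataclass(frozen=True)
class AnnotationSummary:
    """Fraction of sites segregating in one annotation class."""

    annotation: str
    n_sites: int
    n_segregating: int
    fraction: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RescaledFraction:
    """A class fraction rescaled to the neutral class, with approximate CI."""

    rescaled_fraction: float
    ci_low: float
    ci_high: float


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for ``k`` successes out of ``n``."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def fraction_segregating(
    records: pd.DataFrame, group_by: str = "annotation", conf: float = 0.95
) -> pd.DataFrame:
    """Per-group fraction of segregating sites with exact binomial CIs.

    Returns a DataFrame indexed by the grouping value with columns
    ``n_sites, n_segregating, fraction, ci_low, ci_high``.
    """
    if len(records) == 0:
        raise ValueError("empty site table")
    if group_by not in records.columns:
        raise KeyError(f"missing column {group_by!r}")
    rows = {}
    for key, grp in records.groupby(group_by, observed=True, dropna=True):
        n = len(grp)
        if n == 0:
            continue
        k = int(grp["segregating"].astype(bool).sum())
        lo, hi = clopper_pearson(k, n, conf)
        rows[key] = dict(n_sites=n, n_segregating=k, fraction=k / n, ci_low=lo, ci_high=hi)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = group_by
    return out


def summary_row(df: pd.DataFrame, key: str) -> AnnotationSummary:
    """Extract one :class:`AnnotationSummary` from a fraction table."""
    r = df.loc[key]
    return AnnotationSummary(
        annotation=str(key), n_sites=int(r.n_sites), n_segregating=int(r.n_segregating),
        fraction=float(r.fraction), ci_low=float(r.ci_low), ci_high=float(r.ci_high),
    )


def rescale_to_neutral(summary, neutral) -> RescaledFraction:
    """Ratio of a class fraction to the neutral fraction.

    The CI divides the class CI bounds by the neutral point estimate; the
    neutral class is assumed large enough for its uncertainty to be
    negligible.
    """
    if neutral.fraction <= 0:
        raise ValueError("neutral fraction must be > 0")
    return RescaledFraction(
        rescaled_fraction=summary.fraction / neutral.fraction,
        ci_low=summary.ci_low / neutral.fraction,
        ci_high=summary.ci_high / neutral.fraction,
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int, bonferroni: int = 1) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    ``bonferroni`` multiplies the p-value (capped at 1) for multiple-test
    correction. A zero margin carries no information: p = 1 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    if bonferroni < 1:
        raise ValueError("bonferroni multiplier must be >= 1")
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("Fisher exact test on a table with a zero margin; p = 1")
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return min(1.0, float(p) * bonferroni)


def neutral_invariance_pvalue(neutral) -> float:
    """p-value for observing an invariant site under the neutral null."""
    frac = neutral.fraction if hasattr(neutral, "fraction") else float(neutral)
    if not 0.0 <= frac <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return 1.0 - frac


def fdr_invariant(frac_invariant_neutral: float, frac_invariant_class: float) -> float:
    """FDR (in %) for invariant sites of a class, as neutral% / class%.

    Both arguments are on the printed percentage scale.
    """
    if frac_invariant_class <= 0:
        raise ValueError("class invariant fraction must be > 0")
    if frac_invariant_neutral < 0:
        raise ValueError("neutral invariant fraction must be >= 0")
    fdr = 100.0 * frac_invariant_neutral / frac_invariant_class
    if fdr > 100.0:
        warnings.warn("neutral invariant fraction exceeds class fraction; FDR > 100 %")
    return fdr


def matched_fraction_segregating(
    records: pd.DataFrame,
    covariate_field: str = "covariate",
    n_strata: int = 10,
    neutral: str = "synonymous",
    group_by: str = "annotation",
) -> pd.DataFrame:
    """Covariate-matched neutral fractions and rescaled class fractions.

    The pooled covariate distribution is cut into ``n_strata`` quantile
    strata. For each class, the matched neutral fraction is the
    stratum-wise neutral fraction weighted by the class's occupancy of each
    stratum; strata with no neutral sites are dropped and the weights
    renormalized. Returns per-class ``fraction, matched_neutral_fraction,
    rescaled_fraction``.
    """
    if records[covariate_field].isna().any():
        raise ValueError("covariate must be present for all records")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    df = records.copy()
    if n_strata == 1:
        df["_stratum"] = 0
    else:
        df["_stratum"] = pd.qcut(
            df[covariate_field].rank(method="first"), n_strata, labels=False
        )
    seg = df["segregating"].astype(bool)
    neutral_mask = df[group_by] == neutral
    if not neutral_mask.any():
        raise ValueError(f"no records in neutral class {neutral!r}")

    neutral_frac = (
        seg[neutral_mask].groupby(df.loc[neutral_mask, "_stratum"]).mean()
    )
    rows = {}
    for key, grp in df.groupby(group_by, observed=True):
        occupancy = grp["_stratum"].value_counts(normalize=False).sort_index()
        usable = occupancy.index.intersection(neutral_frac.index)
        dropped = occupancy.index.difference(neutral_frac.index)
        if len(dropped):
            logger.info(
                "class %s: dropped strata %s with no neutral sites", key, list(dropped)
            )
        w = occupancy.loc[usable] / occupancy.loc[usable].sum()
        matched = float((w * neutral_frac.loc[usable]).sum())
        frac = float(seg[df[group_by] == key].mean())
        rows[key] = dict(
            fraction=frac,
            matched_neutral_fraction=matched,
            rescaled_fraction=frac / matched if matched > 0 else math.nan,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = group_by
    return out


def bin_sites(records: pd.DataFrame, U: float, shuffle_seed: int = 0) -> pd.DataFrame:
    """Group rate-``u`` sites into bins whose total rate matches ``U``.

    ``k = round(U / mean(u_site))`` sites per bin; records are shuffled,
    chunked into consecutive bins of exactly ``k``, and the trailing
    remainder is dropped. All records must share ``mutation_class``.
    Returns one row per bin: ``k, total_rate, any_segregating``.
    """
    if records["mutation_class"].nunique() > 1:
        raise ValueError("bin_sites requires a single mutation_class")
    mean_u = float(records["u_site"].mean())
    if not U > records["u_site"].max():
        raise ValueError("target per-bin rate U must exceed every per-site rate")
    k = int(round(U / mean_u))
    if k < 1:
        k = 1
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    rng = np.random.default_rng(shuffle_seed)
    perm = rng.permutation(len(records))
    shuffled = records.iloc[perm].reset_index(drop=True)
    n_bins = len(shuffled) // k
    rows = []
    for b in range(n_bins):
        chunk = shuffled.iloc[b * k : (b + 1) * k]
        rows.append(
            dict(
                bin_id=b,
                k=k,
                total_rate=float(chunk["u_site"].sum()),
                any_segregating=bool(chunk["segregating"].astype(bool).any()),
            )
        )
    return pd.DataFrame(rows)


def bin_frequency_deterministic(U: float, hs_list) -> float:
    """Deterministic aggregate frequency of a bin under mutation-selection balance.

    With per-site rate ``U/k`` and heterozygous effects ``hs_i``, the bin
    frequency is ``(U/k) * sum(1/hs_i)``, i.e. ``U`` over the harmonic mean
    of ``hs``.
    """
    hs = np.asarray(hs_list, dtype=float)
    if hs.size == 0:
        raise ValueError("hs_list must be non-empty")
    if np.any(hs <= 0):
        raise ValueError("all hs must be > 0 for the deterministic balance")
    k = hs.size
    return float((U / k) * np.sum(1.0 / hs))


@dataclass(frozen=True)
class RateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    count: int
    denominator: float


def _poisson_ci(count: int, conf: float = 0.95) -> tuple[float, float]:
    # exact (Garwood) interval via chi-square quantiles
    alpha = 1.0 - conf
    low = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count) / 2)
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2)
    return low, high


def dnm_rate(dnm_total: int, n_trios: int, n_sites: int, conf: float = 0.95) -> RateEstimate:
    """De novo mutation rate per site per generation with an exact Poisson CI.

    The denominator is the haploid sample size (``2 * n_trios``) times the
    number of mutational opportunities.
    """
    if n_trios <= 0 or n_sites <= 0:
        raise ValueError("n_trios and n_sites must be > 0")
    if dnm_total < 0:
        raise ValueError("dnm_total must be >= 0")
    denom = 2.0 * n_trios * n_sites
    lo, hi = _poisson_ci(int(dnm_total), conf)
    return RateEstimate(
        rate=dnm_total / denom, ci_low=lo / denom, ci_high=hi / denom,
        count=int(dnm_total), denominator=denom,
    )


def multihit_counts(
    records: pd.DataFrame, compartment_field: str = "compartment"
) -> dict:
    """Single- vs multi-hit de novo counts per compartment, with a FET.

    Sites with exactly one DNM are "single", sites with >= 2 are "multi".
    Returns the per-compartment counts and the two-sided Fisher exact
    p-value of the 2x2 (compartment x {single, multi}) table.
    """
    comps = list(records[compartment_field].dropna().unique())
    if len(comps) != 2:
        raise ValueError("multihit_counts requires exactly two compartments")
    counts = {}
    for comp in comps:
        d = records.loc[records[compartment_field] == comp, "dnm_count"]
        counts[comp] = (int((d == 1).sum()), int((d >= 2).sum()))
    (s1, m1), (s2, m2) = counts[comps[0]], counts[comps[1]]
    if m1 == 0 and m2 == 0:
        warnings.warn("no multi-hit sites in either compartment; p = 1")
        p = 1.0
    else:
        p = fisher_exact_2x2(s1, m1, s2, m2)
    return {"counts": counts, "fet_p": p}


def pathogenic_enrichment_odds(
    path_inv: int, benign_inv: int, path_total: int, benign_total: int
) -> float:
    """Enrichment odds of pathogenic classification among invariant sites.

    ``(path_inv / benign_inv) / (path_total / benign_total)``; infinite when
    no benign site is invariant.
    """
    if path_total <= 0 or benign_total <= 0:
        raise ValueError("totals must be > 0")
    if benign_inv == 0:
        warnings.warn("no invariant benign sites; enrichment odds are infinite")
        return math.inf
    return (path_inv / benign_inv) / (path_total / benign_total)


def genealogy_length_from_saturation(f: float, u: float) -> float:
    """Genealogy length implied by a fraction ``f`` of rate-``u`` sites segregating.

    Inverts the Poisson probability of at least one mutation:
    ``L = -ln(1 - f) / u``.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("f must lie in [0, 1)")
    if u <= 0:
        raise ValueError("u must be > 0")
    return -math.log1p(-f) / u


def genealogy_length_threshold(u: float) -> float:
    """Genealogy length at which one mutation of rate ``u`` is expected (1/u)."""
    if u <= 0:
        raise ValueError("u must be > 0")
    return 1.0 / u


def score_decile_summary(
    records: pd.DataFrame, score_field: str = "score", n_trios: int | None = None
) -> pd.DataFrame:
    """Fraction segregating (and optionally DNM rate) by score decile.

    Deciles are pooled score quantiles; ties spanning decile edges go to the
    lower decile. When ``n_trios`` is given and ``dnm_count`` is populated,
    a per-decile DNM rate is included.
    """
    if records[score_field].isna().any():
        raise ValueError("score must be present for all records")
    df = records.copy()
    df["_decile"] = pd.qcut(df[score_field].rank(method="first"), 10, labels=False)
    rows = []
    for dec, grp in df.groupby("_decile"):
        n = len(grp)
        k = int(grp["segregating"].astype(bool).sum())
        lo, hi = clopper_pearson(k, n)
        row = dict(decile=int(dec), n_sites=n, fraction=k / n, ci_low=lo, ci_high=hi)
        if n_trios is not None and "dnm_count" in grp:
            est = dnm_rate(int(grp["dnm_count"].sum()), n_trios, n)
            row.update(dnm_rate=est.rate, dnm_ci_low=est.ci_low, dnm_ci_high=est.ci_high)
        rows.append(row)
    return pd.DataFrame(rows).set_index("decile")
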