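import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from satcpg import saturation_stats as sat


def make_table(rows):
    return pd.DataFrame(rows)


def site_rows(annotation, n, n_seg, u=1.17e-7, mutation_class="mCpG_transition", **kw):
    rows = []
    for i in range(n):
        rows.append(
            dict(
                site_id=f"{annotation}_{i}",
                annotation=annotation,
                mutation_class=mutation_class,
                u_site=u,
                segregating=i < n_seg,
                dnm_count=0,
                **kw,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# fraction segregating + CIs
# ---------------------------------------------------------------------------

class TestFractionSegregating:
    def test_basic_fraction_and_ci(self):
        df = make_table(site_rows("syn", 100, 99))
        out = sat.fraction_segregating(df)
        row = out.loc["syn"]
        assert row.fraction == pytest.approx(0.99)
        assert 0.94 < row.ci_low < 0.99 < row.ci_high <= 1.0

    def test_zero_segregating(self):
        out = sat.fraction_segregating(make_table(site_rows("x", 50, 0)))
        row = out.loc["x"]
        assert row.fraction == 0.0
        assert row.ci_low == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            sat.fraction_segregating(pd.DataFrame(columns=["annotation", "segregating"]))

    def test_clopper_pearson_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(0, 10), (3, 17), (99, 100), (50, 50)]:
            lo, hi = sat.clopper_pearson(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-12)
            assert hi == pytest.approx(shi, abs=1e-12)

    def test_coverage_simulation(self, rng):
        # Clopper-Pearson is conservative: empirical coverage >= 94 %
        p_true, n, sims = 0.3, 40, 10_000
        ks = rng.binomial(n, p_true, size=sims)
        covered = 0
        for k in np.unique(ks):
            lo, hi = sat.clopper_pearson(int(k), n)
            if lo <= p_true <= hi:
                covered += int((ks == k).sum())
        assert covered / sims >= 0.94


class TestRescaleToNeutral:
    def test_identity(self):
        df = make_table(site_rows("a", 100, 90) + site_rows("syn", 100, 90))
        out = sat.fraction_segregating(df)
        r = sat.rescale_to_neutral(sat.summary_row(out, "a"), sat.summary_row(out, "syn"))
        assert r.rescaled_fraction == pytest.approx(1.0)

    def test_quoted_deficits(self):
        a = sat.AnnotationSummary("missense", 1000, 935, 0.935, 0.9, 0.95)
        n = sat.AnnotationSummary("syn", 1000, 988, 0.988, 0.98, 0.99)
        r = sat.rescale_to_neutral(a, n)
        assert r.rescaled_fraction == pytest.approx(0.946, abs=0.001)
        lof = sat.AnnotationSummary("lof", 1000, 721, 0.7213, 0.69, 0.75)
        assert sat.rescale_to_neutral(lof, n).rescaled_fraction == pytest.approx(0.73, abs=0.003)

    def test_zero_neutral_rejected(self):
        a = sat.AnnotationSummary("a", 10, 5, 0.5, 0.2, 0.8)
        z = sat.AnnotationSummary("syn", 10, 0, 0.0, 0.0, 0.3)
        with pytest.raises(ValueError):
            sat.rescale_to_neutral(a, z)


# ---------------------------------------------------------------------------
# Fisher exact test vs full enumeration oracle
# ---------------------------------------------------------------------------

def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_no_association(self):
        assert sat.fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_perfect_association(self):
        expected = 2 / comb(20, 10, exact=True)
        assert sat.fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.08e-5, rel=1e-2)

    def test_against_enumeration_specific(self):
        p = sat.fisher_exact_2x2(1, 9, 9, 1)
        assert p == pytest.approx(fisher_enumeration_oracle(1, 9, 9, 1), rel=1e-9)

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_on_small_margins(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = sat.fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), rel=1e-9)

    def test_zero_margin_warns(self):
        with pytest.warns(UserWarning):
            assert sat.fisher_exact_2x2(0, 0, 5, 5) == 1.0

    def test_bonferroni(self):
        p1 = sat.fisher_exact_2x2(10, 2, 2, 10)
        p4 = sat.fisher_exact_2x2(10, 2, 2, 10, bonferroni=4)
        assert p4 == pytest.approx(min(1.0, 4 * p1))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sat.fisher_exact_2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# invariance p-values / FDR
# ---------------------------------------------------------------------------

class TestInvariancePvalue:
    @pytest.mark.parametrize(
        "fraction,p", [(0.988, 0.012), (0.10, 0.9), (0.05, 0.95), (0.27, 0.73)]
    )
    def test_quoted_values(self, fraction, p):
        s = sat.AnnotationSummary("syn", 1000, int(1000 * fraction), fraction, 0, 1)
        assert sat.neutral_invariance_pvalue(s) == pytest.approx(p)

    def test_accepts_bare_fraction(self):
        assert sat.neutral_invariance_pvalue(0.988) == pytest.approx(0.012)


class TestFdrInvariant:
    def test_quoted_values(self):
        assert sat.fdr_invariant(1.2, 7.4) == pytest.approx(16.2, abs=0.05)
        assert sat.fdr_invariant(1.2, 27) == pytest.approx(4.4, abs=0.05)

    def test_equal_fractions(self):
        assert sat.fdr_invariant(3.3, 3.3) == pytest.approx(100.0)

    def test_zero_class_rejected(self):
        with pytest.raises(ValueError):
            sat.fdr_invariant(1.0, 0.0)

    def test_exceeding_warns(self):
        with pytest.warns(UserWarning):
            assert sat.fdr_invariant(10, 5) == pytest.approx(200.0)

    @given(
        a=st.floats(0.01, 100), b=st.floats(0.01, 100)
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_algebra(self, a, b):
        if a > b:
            with pytest.warns(UserWarning):
                fdr = sat.fdr_invariant(a, b)
        else:
            fdr = sat.fdr_invariant(a, b)
        assert fdr * b == pytest.approx(100 * a, rel=1e-12)


# ---------------------------------------------------------------------------
# covariate matching
# ---------------------------------------------------------------------------

class TestMatchedFraction:
    def _confounded_table(self, rng, shift):
        rows = []
        for i in range(4000):
            cov = rng.normal()
            if rng.random() < 0.5:
                ann = "synonymous"
            else:
                # class membership shifted toward high covariate
                ann = "lof" if rng.random() < stats.norm.cdf(cov * shift) else "synonymous"
            p_seg = 0.9 - 0.25 * stats.norm.cdf(cov * 2)  # covariate hits p(seg)
            if ann == "lof":
                p_seg *= 0.9
            rows.append(
                dict(site_id=i, annotation=ann, covariate=cov,
                     segregating=rng.random() < p_seg)
            )
        return pd.DataFrame(rows)

    def test_single_stratum_equals_unmatched(self, rng):
        df = self._confounded_table(rng, 1.0)
        matched = sat.matched_fraction_segregating(df, n_strata=1)
        frac = sat.fraction_segregating(df)
        syn = frac.loc["synonymous", "fraction"]
        for ann in matched.index:
            unmatched = frac.loc[ann, "fraction"] / syn
            assert matched.loc[ann, "rescaled_fraction"] == pytest.approx(unmatched)

    def test_matching_reduces_confounded_deficit(self, rng):
        df = self._confounded_table(rng, 1.5)
        unmatched = sat.matched_fraction_segregating(df, n_strata=1)
        matched = sat.matched_fraction_segregating(df, n_strata=10)
        # the true class effect is a 10 % deficit; confounding exaggerates it
        deficit_un = 1 - unmatched.loc["lof", "rescaled_fraction"]
        deficit_m = 1 - matched.loc["lof", "rescaled_fraction"]
        assert deficit_m < deficit_un
        assert deficit_m == pytest.approx(0.10, abs=0.04)

    def test_independent_covariate_changes_little(self, rng):
        rows = site_rows("synonymous", 1000, 900) + site_rows("lof", 1000, 700)
        df = pd.DataFrame(rows)
        df["covariate"] = rng.normal(size=len(df))
        matched = sat.matched_fraction_segregating(df, n_strata=5)
        assert matched.loc["lof", "rescaled_fraction"] == pytest.approx(
            0.7 / 0.9, abs=0.03
        )

    def test_missing_covariate_rejected(self):
        df = pd.DataFrame(site_rows("synonymous", 10, 5))
        df["covariate"] = np.nan
        with pytest.raises(ValueError):
            sat.matched_fraction_segregating(df)


# ---------------------------------------------------------------------------
# bins of K sites
# ---------------------------------------------------------------------------

class TestBinSites:
    def _ta_table(self, n, seg_frac, rng):
        rows = site_rows("synonymous", n, int(n * seg_frac), u=1.2e-9,
                         mutation_class="T>A")
        df = pd.DataFrame(rows)
        return df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)

    def test_k_of_order_100(self, rng):
        df = self._ta_table(1000, 0.05, rng)
        out = sat.bin_sites(df, U=1.17e-7, shuffle_seed=0)
        k = int(out["k"].iloc[0])
        assert k in (97, 98)  # U/u = 97.5: "on the order of 100"
        assert (out["k"] == k).all()
        assert len(out) == 1000 // k

    def test_k_equals_one(self, rng):
        df = self._ta_table(50, 0.1, rng)
        out = sat.bin_sites(df, U=1.3e-9, shuffle_seed=0)
        assert (out["k"] == 1).all()
        assert len(out) == 50

    def test_total_rate_near_target(self, rng):
        df = self._ta_table(1000, 0.05, rng)
        out = sat.bin_sites(df, U=1.17e-7, shuffle_seed=1)
        assert np.allclose(out["total_rate"], 98 * 1.2e-9)

    def test_bin_count_algebra(self, rng):
        df = self._ta_table(997, 0.05, rng)
        out = sat.bin_sites(df, U=1.17e-7, shuffle_seed=2)
        k = int(out["k"].iloc[0])
        assert len(out) * k == k * (997 // k)

    def test_too_few_records(self, rng):
        df = self._ta_table(10, 0.0, rng)
        with pytest.raises(ValueError):
            sat.bin_sites(df, U=1.17e-7)

    def test_mixed_classes_rejected(self, rng):
        df = pd.concat([
            self._ta_table(100, 0.1, rng),
            pd.DataFrame(site_rows("synonymous", 10, 5)),
        ])
        with pytest.raises(ValueError):
            sat.bin_sites(df, U=1.17e-7)


class TestBinFrequency:
    def test_equal_selection_limit(self):
        assert sat.bin_frequency_deterministic(1e-7, [1e-3] * 5) == pytest.approx(1e-4)

    def test_quoted_arithmetic(self):
        assert sat.bin_frequency_deterministic(1e-7, [1e-3, 1e-2]) == pytest.approx(5.5e-5)

    def test_homogeneity(self):
        hs = [2e-3, 5e-4, 1e-2]
        assert sat.bin_frequency_deterministic(1e-7, [2 * x for x in hs]) == pytest.approx(
            sat.bin_frequency_deterministic(1e-7, hs) / 2
        )

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_harmonic_mean_identity(self, hs):
        U = 1e-7
        q = sat.bin_frequency_deterministic(U, hs)
        hmean = len(hs) / sum(1.0 / x for x in hs)
        assert q == pytest.approx(U / hmean, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sat.bin_frequency_deterministic(1e-7, [1e-3, 0.0])


# ---------------------------------------------------------------------------
# DNM rates, multi-hits, enrichment odds
# ---------------------------------------------------------------------------

class TestDnmRate:
    def test_arithmetic(self):
        est = sat.dnm_rate(100, 2976, 10**6)
        assert est.rate == pytest.approx(1.68e-8, rel=1e-3)

    def test_zero_count_upper_bound(self):
        est = sat.dnm_rate(0, 100, 1000)
        assert est.rate == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high == pytest.approx(3.689 / (2 * 100 * 1000), rel=1e-3)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            sat.dnm_rate(5, 100, 0)

    def test_ci_coverage(self, rng):
        u, n_trios, n_sites, sims = 1.17e-7, 2976, 10**5, 1000
        lam = 2 * n_trios * u * n_sites
        covered = 0
        for c in rng.poisson(lam, size=sims):
            est = sat.dnm_rate(int(c), n_trios, n_sites)
            if est.ci_low <= u <= est.ci_high:
                covered += 1
        assert covered / sims >= 0.93


class TestMultihit:
    def _poisson_table(self, rate1, rate2, n, rng):
        rows = []
        for comp, rate in (("exon", rate1), ("non_exon", rate2)):
            counts = rng.poisson(rate, size=n)
            for i, c in enumerate(counts):
                rows.append(dict(site_id=f"{comp}{i}", compartment=comp, dnm_count=c))
        return pd.DataFrame(rows)

    def test_null_p_not_extreme(self, rng):
        ps = [
            sat.multihit_counts(self._poisson_table(0.05, 0.05, 2000, rng))["fet_p"]
            for _ in range(20)
        ]
        assert np.median(ps) > 0.1

    def test_power_at_10x(self, rng):
        hits = 0
        for _ in range(10):
            out = sat.multihit_counts(self._poisson_table(0.3, 0.03, 3000, rng))
            hits += out["fet_p"] < 0.05
        assert hits >= 6

    def test_no_multihits_warns(self):
        df = pd.DataFrame(
            dict(site_id=range(10), compartment=["a"] * 5 + ["b"] * 5,
                 dnm_count=[1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        )
        with pytest.warns(UserWarning):
            assert sat.multihit_counts(df)["fet_p"] == 1.0


class TestEnrichmentOdds:
    def test_independent(self):
        assert sat.pathogenic_enrichment_odds(10, 20, 100, 200) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert sat.pathogenic_enrichment_odds(30, 5, 100, 100) == pytest.approx(6.0)

    def test_infinite(self):
        with pytest.warns(UserWarning):
            assert math.isinf(sat.pathogenic_enrichment_odds(5, 0, 100, 100))

    def test_enriched_synthetic_above_one(self, rng):
        # invariance enriched among pathogenic sites
        path_inv = int(rng.binomial(200, 0.4))
        benign_inv = int(rng.binomial(800, 0.05))
        odds = sat.pathogenic_enrichment_odds(path_inv, benign_inv, 200, 800)
        assert odds > 1


# ---------------------------------------------------------------------------
# genealogy-length estimators
# ---------------------------------------------------------------------------

class TestGenealogyLength:
    def test_quoted_inversion(self):
        L = sat.genealogy_length_from_saturation(0.99, 1.17e-7)
        assert L == pytest.approx(3.94e7, rel=0.01)

    def test_zero_fraction(self):
        assert sat.genealogy_length_from_saturation(0.0, 1e-7) == 0.0

    def test_saturated_rejected(self):
        with pytest.raises(ValueError):
            sat.genealogy_length_from_saturation(1.0, 1e-7)

    @given(st.floats(0.0, 0.999999))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, f):
        u = 1.17e-7
        L = sat.genealogy_length_from_saturation(f, u)
        assert 1 - math.exp(-u * L) == pytest.approx(f, abs=1e-12)

    def test_threshold(self):
        assert sat.genealogy_length_threshold(1.17e-7) == pytest.approx(8.547e6, rel=1e-3)
        assert sat.genealogy_length_threshold(1.0) == 1.0

    def test_threshold_identity(self):
        from satcpg.coalescent_lengths import expected_mutations

        u = 3.3e-8
        assert expected_mutations(u, sat.genealogy_length_threshold(u)) == pytest.approx(1.0)


class TestScoreDeciles:
    def test_flat_when_independent(self, rng):
        df = pd.DataFrame(site_rows("syn", 2000, 1600))
        df["segregating"] = rng.random(len(df)) < 0.8
        df["score"] = rng.normal(size=len(df))
        out = sat.score_decile_summary(df)
        assert len(out) == 10
        assert out["fraction"].max() - out["fraction"].min() < 0.15

    def test_monotone_when_score_tracks_selection(self, rng):
        rows = []
        for i in range(3000):
            score = rng.random()
            p_seg = 0.95 - 0.6 * score  # higher score = stronger selection
            rows.append(dict(site_id=i, score=score, segregating=rng.random() < p_seg,
                             dnm_count=0))
        out = sat.score_decile_summary(pd.DataFrame(rows))
        fr = out["fraction"].to_numpy()
        # overall decreasing trend: top decile well below bottom decile
        assert fr[-1] < fr[0] - 0.3
        assert (np.diff(fr) < 0.08).all()

    def test_dnm_rates_included(self, rng):
        df = pd.DataFrame(site_rows("syn", 500, 400))
        df["score"] = rng.normal(size=len(df))
        df["dnm_count"] = rng.poisson(0.1, size=len(df))
        out = sat.score_decile_summary(df, n_trios=2976)
        assert "dnm_rate" in out.columns
        assert (out["dnm_rate"] >= 0).all()
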