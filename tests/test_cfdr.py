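import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiocfdr.cfdr import (
    ccfdr,
    cfdr,
    cfdr_table,
    classify,
    conditional_exceedance,
    conditional_exceedance_reference,
)
from pleiocfdr.examples import example_loci


def _random_pair(rng, n, tie_frac=0.3):
    """Random p-value pair with heavy ties on both axes."""
    p1 = rng.uniform(size=n)
    p2 = rng.uniform(size=n)
    k = max(1, int(tie_frac * n))
    p1[rng.choice(n, k, replace=False)] = rng.choice([0.05, 0.5], size=k)
    p2[rng.choice(n, k, replace=False)] = rng.choice([0.01, 0.9], size=k)
    return p1, p2


class TestConditionalExceedance:
    def test_smallest_secondary_p_conditions_on_itself_alone(self):
        p1 = np.array([0.3, 0.7, 0.9])
        p2 = np.array([0.001, 0.5, 0.8])
        est = conditional_exceedance(p1, p2)
        assert est[0] == pytest.approx(1.0)

    def test_constant_secondary_reduces_to_ecdf(self):
        p1 = np.array([0.1, 0.2, 0.3, 0.4])
        p2 = np.full(4, 0.5)
        np.testing.assert_allclose(
            conditional_exceedance(p1, p2), [0.25, 0.5, 0.75, 1.0]
        )

    def test_ecdf_limit_uses_max_rank_on_ties(self):
        p1 = np.array([0.1, 0.2, 0.2, 0.4])
        p2 = np.full(4, 0.5)
        np.testing.assert_allclose(
            conditional_exceedance(p1, p2), [0.25, 0.75, 0.75, 1.0]
        )

    @pytest.mark.parametrize("seed,n", [(0, 10), (1, 100), (2, 500), (3, 2000)])
    def test_fast_path_equals_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        p1, p2 = _random_pair(rng, n)
        np.testing.assert_array_equal(
            conditional_exceedance(p1, p2), conditional_exceedance_reference(p1, p2)
        )

    def test_estimates_in_unit_interval(self):
        rng = np.random.default_rng(9)
        p1, p2 = _random_pair(rng, 300)
        est = conditional_exceedance(p1, p2)
        assert ((est > 0) & (est <= 1)).all()

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            conditional_exceedance(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            conditional_exceedance(np.array([0.0, 0.5]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            conditional_exceedance(np.array([0.5]), np.array([0.5, 0.6]))


class TestCfdr:
    def test_constant_secondary_closed_form(self):
        p1 = np.array([0.1, 0.2, 0.3, 0.4])
        p2 = np.full(4, 0.5)
        np.testing.assert_allclose(cfdr(p1, p2), [0.4, 0.4, 0.4, 0.4])

    def test_minimal_conditioning_set_returns_p(self):
        p1 = np.array([0.01, 0.5, 0.6])
        p2 = np.array([1e-6, 0.5, 0.9])
        assert cfdr(p1, p2)[0] == pytest.approx(0.01)

    def test_composed_oracle_on_mixture(self, small_pair):
        s1, s2, _ = small_pair
        p1 = s1["pvalue"].to_numpy()
        p2 = s2["pvalue"].to_numpy()
        expected = np.minimum(1.0, p1 / conditional_exceedance_reference(p1, p2))
        np.testing.assert_array_equal(cfdr(p1, p2), expected)

    def test_bounds_against_p_and_count(self):
        rng = np.random.default_rng(5)
        p1, p2 = _random_pair(rng, 400)
        c = cfdr(p1, p2)
        assert (c >= p1).all() and (c <= 1.0).all()
        n_cond = np.array([(p2 <= v).sum() for v in p2])
        assert (c <= np.minimum(1.0, p1 * n_cond)).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        p1, p2 = _random_pair(rng, 200)
        perm = rng.permutation(200)
        np.testing.assert_array_equal(cfdr(p1, p2)[perm], cfdr(p1[perm], p2[perm]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=60),
           st.integers(0, 2**31 - 1))
    def test_cfdr_dominates_p_property(self, p1_list, seed):
        p1 = np.asarray(p1_list)
        p2 = np.random.default_rng(seed).uniform(1e-8, 1.0, size=p1.size)
        c = cfdr(p1, p2)
        assert (c >= p1).all() and (c > 0).all() and (c <= 1).all()

    def test_global_null_rarely_passes_threshold(self):
        """Under pi0 = 1 the expected fraction of SNPs at cFDR <= 0.01 stays
        small (no strict FDR-calibration claim for the raw estimator)."""
        rng = np.random.default_rng(123)
        props = []
        for _ in range(200):
            p1 = rng.uniform(size=50_000)
            p2 = rng.uniform(size=50_000)
            props.append((cfdr(p1, p2) <= 0.01).mean())
        assert np.mean(props) < 0.05

    def test_enrichment_pleiotropic_below_primary_only(self):
        """Truly pleiotropic SNPs get lower primary-trait cFDR than
        primary-only SNPs matched on primary p-value decile."""
        from pleiocfdr.simulate import SimulationConfig, simulate_sumstats_pair

        cfg = SimulationConfig(
            n_snps=20_000, pi=(0.90, 0.04, 0.03, 0.03), seed=77
        )
        s1, s2, truth = simulate_sumstats_pair(cfg)
        c = cfdr(s1["pvalue"].to_numpy(), s2["pvalue"].to_numpy())
        df = pd.DataFrame(
            {"cfdr": c, "p": s1["pvalue"], "cls": truth["class"],
             "dec": pd.qcut(s1["pvalue"], 10, labels=False)}
        )
        diffs = []
        for _, g in df.groupby("dec"):
            pl = g.loc[g.cls == "pleiotropic", "cfdr"]
            po = g.loc[g.cls == "trait1_only", "cfdr"]
            if len(pl) >= 5 and len(po) >= 5:
                diffs.append((len(pl) + len(po), pl.mean() - po.mean()))
        assert diffs, "no decile had both classes represented"
        weighted = sum(w * d for w, d in diffs) / sum(w for w, _ in diffs)
        assert weighted < 0


class TestCcfdrAndClassify:
    def test_max_rule_on_example_rows(self):
        # two loci from the bundled example table plus idempotence
        assert ccfdr([5.57e-4], [3.76e-5])[0] == pytest.approx(5.57e-4)
        assert ccfdr([0.02], [3.58e-3])[0] == pytest.approx(0.02)
        x = np.array([0.37])
        assert ccfdr(x, x)[0] == 0.37

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ccfdr([0.1], [0.1, 0.2])

    def _table(self, c12, c21):
        df = pd.DataFrame(
            {
                "cfdr_primary_given_secondary": c12,
                "cfdr_secondary_given_primary": c21,
            }
        )
        df["ccfdr"] = np.maximum(df.iloc[:, 0], df.iloc[:, 1])
        return df

    def test_example_loci_counts(self):
        labels, counts = classify(example_loci(), alpha=0.01)
        assert (counts.n_primary, counts.n_secondary, counts.n_total,
                counts.n_pleiotropic) == (6, 9, 11, 4)
        assert (labels == "pleiotropic").sum() == 4

    def test_nothing_passes_when_all_one(self):
        labels, counts = classify(self._table([1.0] * 5, [1.0] * 5), alpha=0.01)
        assert (labels == "none").all()
        assert counts == type(counts)(0, 0, 0, 0)

    def test_threshold_boundary_is_inclusive(self):
        _, counts = classify(self._table([0.01], [0.01]), alpha=0.01)
        assert counts.n_pleiotropic == 1

    def test_labels_are_mutually_consistent(self):
        rng = np.random.default_rng(2)
        t = self._table(rng.uniform(size=200) ** 3, rng.uniform(size=200) ** 3)
        labels, counts = classify(t, alpha=0.05)
        pleio = t["ccfdr"] <= 0.05
        assert ((labels == "pleiotropic") == pleio).all()
        assert counts.n_total >= max(counts.n_primary, counts.n_secondary)


class TestCfdrTable:
    def test_table_columns_and_invariants(self, small_pair):
        s1, s2, _ = small_pair
        harm = pd.DataFrame(
            {"rsid": s1["rsid"], "p_primary": s1["pvalue"], "p_secondary": s2["pvalue"]}
        )
        out = cfdr_table(harm, alpha=0.01)
        assert {"cfdr_primary_given_secondary", "cfdr_secondary_given_primary",
                "ccfdr", "sig_class"} <= set(out.columns)
        np.testing.assert_array_equal(
            out["ccfdr"],
            np.maximum(out["cfdr_primary_given_secondary"],
                       out["cfdr_secondary_given_primary"]),
        )
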