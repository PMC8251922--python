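"""Differential expression, DL meta-analysis, BH, and differential stability.

Each statistic is checked against an independently coded oracle: scipy's
two-sample Welch test on raw data, a loop-written DerSimonian-Laird
combiner, and statsmodels' BH implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scntx.collapse import GeneMatrix
from scntx.diffexpr import (
    bh_adjust,
    call_de,
    differential_stability,
    dl_meta,
    donor_de,
    meta_analyze,
    welch_test,
)


# ---------- independent oracles ----------

def dl_oracle(y, v):
    """Brute-force DerSimonian-Laird, written independently of the package."""
    y = list(map(float, y))
    v = list(map(float, v))
    k = len(y)
    w = [1.0 / vi for vi in v]
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    Q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    C = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / C)
    ws = [1.0 / (vi + tau2) for vi in v]
    mu = sum(wi * yi for wi, yi in zip(ws, y)) / sum(ws)
    se = sum(ws) ** -0.5
    return mu, se, tau2


def make_gm(donor_id, values, structures=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    sids = [f"{donor_id}_s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "structure_acronym": structures or ["ctx"] * n,
            "hemisphere": ["L"] * n,
            "mni_x": 0.0,
            "mni_y": 0.0,
            "mni_z": 0.0,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    expr = pd.DataFrame(values, index=range(101, 101 + values.shape[0]), columns=sids)
    return GeneMatrix(donor_id=donor_id, expr=expr, samples=samples,
                      chosen_probe={g: f"p{g}" for g in expr.index})


def make_assignment(donor_id, labels):
    return pd.DataFrame(
        {
            "donor_id": donor_id,
            "sample_id": [f"{donor_id}_s{i}" for i in range(len(labels))],
            "network_label": labels,
        }
    )


# ---------- Welch donor-level DE ----------

class TestDonorDE:
    def test_worked_example(self):
        gm = make_gm("D1", [[1, 2, 3, 3, 4, 5]])
        asg = make_assignment("D1", ["C"] * 3 + ["A"] * 3)
        out = donor_de(gm, asg, "C", ["A"])
        row = out.iloc[0]
        assert row["fc"] == pytest.approx(-2.0)
        assert row["var"] == pytest.approx(2 / 3)
        assert row["t"] == pytest.approx(-2.449, abs=1e-3)
        assert row["df"] == pytest.approx(4.0)
        assert row["p_donor"] == pytest.approx(0.0705, abs=2e-4)

    def test_identical_groups_p_one(self):
        gm = make_gm("D1", [[2, 2, 4, 2, 2, 4]])
        asg = make_assignment("D1", ["C"] * 3 + ["A"] * 3)
        row = donor_de(gm, asg, "C", ["A"]).iloc[0]
        assert row["fc"] == 0.0
        assert row["t"] == 0.0
        assert row["p_donor"] == pytest.approx(1.0)

    def test_zero_variance_both_groups_invalid(self):
        gm = make_gm("D1", [[5, 5, 5, 5]])
        asg = make_assignment("D1", ["C", "C", "A", "A"])
        row = donor_de(gm, asg, "C", ["A"]).iloc[0]
        assert not row["valid"]
        assert np.isnan(row["p_donor"])

    def test_too_few_samples_yields_empty(self, caplog):
        gm = make_gm("D1", [[1, 2, 3]])
        asg = make_assignment("D1", ["C", "A", "A"])
        out = donor_de(gm, asg, "C", ["A"])
        assert out.empty

    def test_target_in_comparison_rejected(self):
        gm = make_gm("D1", [[1, 2, 3, 4]])
        asg = make_assignment("D1", ["C", "C", "A", "A"])
        with pytest.raises(ValueError):
            donor_de(gm, asg, "C", ["C", "A"])

    def test_none_labels_excluded(self):
        gm = make_gm("D1", [[1, 2, 3, 4, 100, 200]])
        asg = make_assignment("D1", ["C", "C", "A", "A", None, None])
        row = donor_de(gm, asg, "C", ["A"]).iloc[0]
        assert row["n_in"] == 2 and row["n_out"] == 2
        assert row["fc"] == pytest.approx(-2.0)

    def test_matches_scipy_welch_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = rng.integers(3, 12, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.normal(), size=n2)
            fc, var, t, df, p = welch_test(
                x.mean(), x.var(ddof=1), n1, y.mean(), y.var(ddof=1), n2
            )
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-8)


# ---------- DerSimonian-Laird meta-analysis ----------

class TestDLMeta:
    def test_worked_example(self):
        res = dl_meta([0.5, 1.5], [0.1, 0.1])
        assert res.tau2 == pytest.approx(0.4)
        assert res.fc_summary == pytest.approx(1.0)
        assert res.se_summary == pytest.approx(0.5)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_identical_effects_zero_heterogeneity(self):
        res = dl_meta([1.0] * 6, [0.2] * 6)
        assert res.tau2 == 0.0
        assert res.fc_summary == pytest.approx(1.0)

    def test_single_donor_identity(self):
        res = dl_meta([0.7], [0.09])
        assert res.k == 1
        assert res.fc_summary == pytest.approx(0.7)
        assert res.tau2 == 0.0
        assert res.se_summary == pytest.approx(0.3)

    def test_equal_variances_tau_zero_reduces_to_mean(self):
        y = [0.2, 0.25, 0.22, 0.21]
        res = dl_meta(y, [0.5] * 4)  # tiny spread -> tau2 truncated to 0
        assert res.tau2 == 0.0
        assert res.fc_summary == pytest.approx(np.mean(y))

    def test_nonpositive_variance_excluded(self):
        res = dl_meta([1.0, 2.0, 3.0], [0.1, 0.0, 0.1])
        assert res.k == 2
        mu, se, tau2 = dl_oracle([1.0, 3.0], [0.1, 0.1])
        assert res.fc_summary == pytest.approx(mu)

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            k = int(rng.integers(2, 7))
            y = rng.normal(size=k)
            v = rng.uniform(0.01, 1.0, size=k)
            res = dl_meta(y, v)
            mu, se, tau2 = dl_oracle(y, v)
            assert res.fc_summary == pytest.approx(mu, abs=1e-10)
            assert res.se_summary == pytest.approx(se, abs=1e-10)
            assert res.tau2 == pytest.approx(tau2, abs=1e-10)

    def test_vectorized_meta_matches_scalar(self):
        rng = np.random.default_rng(6)
        rows = []
        expected = {}
        for gene in range(50):
            k = int(rng.integers(2, 7))
            donors = [f"D{i}" for i in range(k)]
            y = rng.normal(size=k)
            v = rng.uniform(0.01, 1.0, size=k)
            expected[gene] = dl_meta(y, v)
            for d, yi, vi in zip(donors, y, v):
                rows.append({"gene": gene, "donor_id": d, "fc": yi, "var": vi, "valid": True})
        out = meta_analyze(pd.DataFrame(rows)).set_index("gene")
        for gene, res in expected.items():
            assert out.loc[gene, "fc_summary"] == pytest.approx(res.fc_summary, abs=1e-10)
            assert out.loc[gene, "tau2"] == pytest.approx(res.tau2, abs=1e-10)
            assert out.loc[gene, "se_summary"] == pytest.approx(res.se_summary, abs=1e-10)
            assert out.loc[gene, "p"] == pytest.approx(res.p, abs=1e-10)

    def test_donor_t_summary_test(self):
        y = [0.4, 0.6, 0.9, 1.1]
        res = dl_meta(y, [0.1] * 4, summary_test="donor-t")
        ref = stats.ttest_1samp(y, 0.0)
        assert res.p == pytest.approx(ref.pvalue)
        long = pd.DataFrame(
            {"gene": 1, "donor_id": [f"D{i}" for i in range(4)], "fc": y, "var": 0.1,
             "valid": True}
        )
        out = meta_analyze(long, summary_test="donor-t")
        assert out.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-12)


# ---------- Benjamini-Hochberg ----------

class TestBH:
    def test_worked_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9], atol=1e-12
        )
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([np.nan])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_permutation_invariant(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)


# ---------- DE calling ----------

class TestCallDE:
    def _meta(self, fc, p_bh):
        return pd.DataFrame({"gene": range(len(fc)), "fc_summary": fc, "p_bh": p_bh})

    def test_rule_application(self):
        meta = self._meta([1.2, 0.8, -1.5, 1.0], [0.01, 0.001, 0.01, 0.001])
        up, down = call_de(meta)
        assert up == [0]
        assert down == [2]
        # |FC| <= 1 never called regardless of significance; FC exactly 1 excluded
        assert 1 not in up and 3 not in up

    def test_alpha_strict(self):
        meta = self._meta([2.0], [0.05])
        up, down = call_de(meta, alpha=0.05)
        assert up == [] and down == []


# ---------- differential stability ----------

class TestDifferentialStability:
    def test_three_donor_worked_example(self):
        gms = [
            make_gm("D1", [[1, 2, 3, 4]], structures=["a", "b", "c", "d"]),
            make_gm("D2", [[2, 4, 6, 8]], structures=["a", "b", "c", "d"]),
            make_gm("D3", [[4, 3, 2, 1]], structures=["a", "b", "c", "d"]),
        ]
        out = differential_stability(gms)
        # pair correlations: +1, -1, -1 -> mean -1/3
        assert out.loc[0, "ds"] == pytest.approx(-1 / 3)
        assert out.loc[0, "n_pairs_used"] == 3

    def test_identical_profiles_ds_one(self):
        gms = [make_gm(d, [[1, 5, 2, 7]], structures=list("abcd")) for d in ("D1", "D2")]
        out = differential_stability(gms)
        assert out.loc[0, "ds"] == pytest.approx(1.0)

    def test_six_donors_fifteen_pairs(self):
        rng = np.random.default_rng(9)
        gms = [
            make_gm(f"D{i}", rng.normal(size=(3, 5)), structures=list("abcde"))
            for i in range(6)
        ]
        out = differential_stability(gms)
        assert (out["n_pairs_used"] == 15).all()
        assert len(list(itertools.combinations(range(6), 2))) == 15

    def test_structure_averaging_within_donor(self):
        # two samples of the same structure are averaged before correlating
        gms = [
            make_gm("D1", [[0, 2, 4, 6]], structures=["a", "a", "b", "c"]),
            make_gm("D2", [[1, 4, 9]], structures=["a", "b", "c"]),
        ]
        out = differential_stability(gms)
        ref = np.corrcoef([1, 4, 6], [1, 4, 9])[0, 1]
        assert out.loc[0, "ds"] == pytest.approx(ref)

    def test_min_shared_structures_skips_pair(self):
        gms = [
            make_gm("D1", [[1, 2]], structures=["a", "b"]),
            make_gm("D2", [[1, 2]], structures=["a", "b"]),
        ]
        out = differential_stability(gms, min_shared=3)
        assert out.loc[0, "n_pairs_used"] == 0
        assert pd.isna(out.loc[0, "ds"])
        assert pd.isna(out.loc[0, "decile"])

    def test_constant_profile_skipped(self):
        gms = [
            make_gm("D1", [[5, 5, 5, 5]], structures=list("abcd")),
            make_gm("D2", [[1, 2, 3, 4]], structures=list("abcd")),
        ]
        out = differential_stability(gms)
        assert out.loc[0, "n_pairs_used"] == 0

    def test_deciles_rank_highest_as_ten(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(20, 6))
        noise = [base + rng.normal(0, s, size=base.shape) for s in (0.01, 0.02)]
        gms = [
            make_gm(f"D{i}", m, structures=list("abcdef")) for i, m in enumerate(noise)
        ]
        out = differential_stability(gms)
        assert set(out["decile"].dropna().astype(int)) <= set(range(1, 11))
        assert out.loc[out["ds"].idxmax(), "decile"] == 10
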