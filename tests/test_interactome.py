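"""Unit tests for the ChIP-MS interactome scoring chain."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import _oracles as oracles
from conftest import quant_matrix
from corepressor_map.config import SimConfig
from corepressor_map import interactome as ia


class TestDigest:
    def test_cleaves_after_k_and_r_but_not_before_proline(self):
        # hand-applied rule: AAAAAAK | RPAAAAAA (no cleavage after R before P)
        assert ia.digest_protein("AAAAAAKRPAAAAAA", 6, 30) == [
            "AAAAAAK",
            "RPAAAAAA",
        ]

    def test_no_cleavage_sites_returns_whole_chain(self):
        assert ia.digest_protein("ACDEFGHILMN", 6, 30) == ["ACDEFGHILMN"]

    def test_length_window_applied(self):
        # K after 3 residues -> fragment of 4 below min_len
        assert ia.digest_protein("AAAKCCCCCCCC", 6, 30) == ["CCCCCCCC"]

    def test_invalid_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            ia.digest_protein("AAAKBB")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ia.digest_protein("")


class TestIbaq:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows,
            columns=["protein_id", "peptide", "sample_id", "condition",
                     "nuclease", "intensity"],
        )

    def test_sum_over_theoretical_count(self):
        table = self._table(
            [
                ("P1", "AAAAAK", "s1", "bait", "none", 6e8),
                ("P1", "CCCCCK", "s1", "bait", "none", 4e8),
            ]
        )
        m = ia.compute_ibaq(table, pd.Series({"P1": 10}))
        assert m.values.loc["P1", "s1"] == pytest.approx(1e8)

    def test_unobserved_cell_is_missing(self):
        table = self._table(
            [
                ("P1", "AAAAAK", "s1", "bait", "none", 6e8),
                ("P1", "AAAAAK", "s2", "control", "none", np.nan),
            ]
        )
        m = ia.compute_ibaq(table, pd.Series({"P1": 5}))
        assert np.isnan(m.values.loc["P1", "s2"])

    def test_zero_digest_count_rejected(self):
        table = self._table([("P1", "AAAAAK", "s1", "bait", "none", 1e8)])
        with pytest.raises(ValueError, match="denominator"):
            ia.compute_ibaq(table, pd.Series({"P1": 0}))

    def test_matches_brute_force_oracle(self, rng):
        proteins = [f"P{i}" for i in range(12)]
        samples = [f"s{j}" for j in range(6)]
        digest = pd.Series({p: int(rng.integers(1, 20)) for p in proteins})
        rows = []
        for _ in range(300):
            rows.append(
                (
                    proteins[rng.integers(12)],
                    "PEPTIDEK",
                    samples[rng.integers(6)],
                    "bait",
                    "none",
                    float(rng.lognormal(18, 2)),
                )
            )
        table = self._table(rows)
        m = ia.compute_ibaq(table, digest)
        expected = oracles.ibaq_oracle(
            [(r[0], r[2], r[5]) for r in rows], digest.to_dict()
        )
        for (pid, sid), val in expected.items():
            assert m.values.loc[pid, sid] == pytest.approx(val, rel=1e-6)


class TestNormalization:
    def test_median_centering(self):
        m = quant_matrix([[2.0], [8.0]], ["bait"])
        out = ia.log2_median_normalize(m)
        assert out.values.iloc[:, 0].tolist() == pytest.approx([-1.0, 1.0])

    def test_all_equal_sample_becomes_zero(self):
        m = quant_matrix([[4.0], [4.0], [4.0]], ["bait"])
        out = ia.log2_median_normalize(m)
        assert (out.values == 0).all().all()

    def test_per_sample_observed_median_zero(self, rng):
        vals = rng.lognormal(13, 1.5, (40, 5))
        vals[rng.random((40, 5)) < 0.3] = np.nan
        m = quant_matrix(vals, ["bait", "bait", "bait", "control", "control"])
        out = ia.log2_median_normalize(m)
        assert np.allclose(out.values.median(axis=0, skipna=True), 0, atol=1e-9)

    def test_empty_sample_rejected(self):
        m = quant_matrix([[1.0, np.nan], [2.0, np.nan]], ["bait", "control"])
        with pytest.raises(ValueError, match="zero observed"):
            ia.log2_median_normalize(m)

    def test_matches_oracle(self, rng):
        vals = rng.lognormal(13, 1.5, (25, 4))
        mask = rng.random((25, 4)) < 0.25
        vals[mask] = np.nan
        m = quant_matrix(vals, ["bait", "bait", "control", "control"])
        out = ia.log2_median_normalize(m)
        columns = {
            s: [None if np.isnan(v) else float(v) for v in vals[:, j]]
            for j, s in enumerate(out.values.columns)
        }
        exp = oracles.median_norm_oracle(columns)
        for j, s in enumerate(out.values.columns):
            got = out.values[s].to_numpy()
            for i, e in enumerate(exp[s]):
                if e is None:
                    assert np.isnan(got[i])
                else:
                    assert got[i] == pytest.approx(e, abs=1e-9)


class TestImputation:
    def _log2_matrix(self, rng, n=200, frac_missing=0.3):
        vals = rng.lognormal(13, 1.5, (n, 4))
        vals[rng.random(n) < frac_missing, 0] = np.nan
        return ia.log2_median_normalize(
            quant_matrix(vals, ["bait", "bait", "control", "control"])
        )

    def test_width_zero_is_deterministic_downshift(self, rng):
        m = self._log2_matrix(rng)
        obs = m.values.iloc[:, 0].dropna()
        out = ia.impute_missing(m, width=0.0, downshift=2.0, seed=1)
        imputed = out.values.iloc[:, 0][m.values.iloc[:, 0].isna()]
        expected = obs.mean() - 2.0 * obs.std(ddof=1)
        assert np.allclose(imputed, expected)

    def test_imputed_mean_matches_downshifted_gaussian(self, rng):
        # Monte-Carlo: ~1e5 imputed draws concentrate on mu - downshift*sigma
        vals = rng.lognormal(13, 1.0, (200_000, 2))
        vals[rng.random(len(vals)) < 0.5, 0] = np.nan
        m2 = ia.log2_median_normalize(quant_matrix(vals, ["bait", "control"]))
        v = m2.values
        obs = v.iloc[:, 0].dropna()
        mu, sd = obs.mean(), obs.std(ddof=1)
        out = ia.impute_missing(m2, width=0.25, downshift=2.0, seed=5)
        imputed = out.values.iloc[:, 0][v.iloc[:, 0].isna()]
        se = 0.25 * sd / np.sqrt(len(imputed))
        assert abs(imputed.mean() - (mu - 2.0 * sd)) < 3 * se

    def test_seeded_determinism_and_observed_untouched(self, rng):
        m = self._log2_matrix(rng)
        a = ia.impute_missing(m, seed=42)
        b = ia.impute_missing(m, seed=42)
        pd.testing.assert_frame_equal(a.values, b.values)
        obs_mask = m.values.notna()
        assert ((a.values == m.values) | ~obs_mask).all().all()

    def test_too_few_observed_rejected(self):
        m = quant_matrix([[2.0, 2.0], [np.nan, 4.0]], ["bait", "control"])
        m = ia.ProteinQuantMatrix(
            np.log2(m.values) - np.log2(m.values).median(), m.samples, "log2_median"
        )
        with pytest.raises(ValueError, match="< 2 observed"):
            ia.impute_missing(m)


class TestEnrichment:
    def _imputed(self, values, conditions):
        m = quant_matrix(values, conditions)
        return ia.ProteinQuantMatrix(m.values, m.samples, "imputed")

    def test_identical_arms_give_p_one(self):
        m = self._imputed(
            [[1.0, 1.0, 1.0, 1.0]], ["bait", "bait", "control", "control"]
        )
        res = ia.test_enrichment(m)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["t_statistic"].iloc[0] == 0.0

    def test_mean_difference_is_log2_enrichment(self, rng):
        jitter = rng.normal(0, 1e-9, 6)
        m = self._imputed(
            [np.array([3, 3, 3, 0, 0, 0]) + jitter],
            ["bait"] * 3 + ["control"] * 3,
        )
        res = ia.test_enrichment(m)
        assert res["log2_enrichment"].iloc[0] == pytest.approx(3.0, abs=1e-6)

    def test_matches_pooled_variance_oracle(self, rng):
        vals = rng.normal(0, 1, (30, 9))
        m = self._imputed(vals, ["bait"] * 4 + ["control"] * 5)
        res = ia.test_enrichment(m)
        for i in range(30):
            t, p = oracles.pooled_t_oracle(vals[i, :4], vals[i, 4:])
            assert res["p_value"].iloc[i] == pytest.approx(p, abs=1e-10)

    def test_requires_two_samples_per_arm(self):
        m = self._imputed([[1.0, 2.0, 3.0]], ["bait", "control", "control"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            ia.test_enrichment(m)


class TestInteractorCalls:
    def test_gate_boundaries(self):
        res = pd.DataFrame(
            {
                "protein_id": ["a", "b", "c"],
                "log2_enrichment": [3.33, 3.33, 3.0],
                "p_value": [0.005, 0.02, 0.005],
            }
        )
        out = ia.call_interactors(res, fold_cutoff=10, p_cutoff=0.01)
        # log2(10) ~ 3.3219: enrichment gate passes at 3.33, P gate at < 0.01
        assert out["is_interactor"].tolist() == [True, False, False]

    def test_nonpositive_fold_rejected(self):
        res = pd.DataFrame(
            {"protein_id": ["a"], "log2_enrichment": [5.0], "p_value": [0.001]}
        )
        with pytest.raises(ValueError):
            ia.call_interactors(res, fold_cutoff=0)

    def test_monotone_in_planted_effect(self):
        """Raising the spiked fold-enrichment never loses true interactors."""
        from corepressor_map.calibration import _run_interactome_stratum

        base = SimConfig(
            seed=7, n_proteins=60, n_true_interactors=10, n_dna_bridged=0,
            n_bait_samples=4, n_control_samples=4,
            protein_length_range=(80, 160),
        )
        called = []
        for effect in (1.0, 4.0, 16.0):
            cfg = replace(base, interactor_effect=effect)
            res, truth = _run_interactome_stratum(
                cfg, fold_cutoff=10, p_cutoff=0.01
            )
            hits = set(res.loc[res["is_interactor"], "protein_id"])
            called.append(len(hits & truth.true_interactors))
        assert called == sorted(called)


class TestNucleaseClassification:
    def _results(self, enrichments, interactor=None):
        df = pd.DataFrame(
            {
                "protein_id": list(enrichments),
                "log2_enrichment": list(enrichments.values()),
                "p_value": 0.001,
            }
        )
        if interactor is not None:
            df["is_interactor"] = interactor
        return df

    def test_retained_enrichment_is_direct(self):
        unt = self._results({"p1": np.log2(16)}, interactor=[True])
        benz = self._results({"p1": np.log2(12)})
        out = ia.classify_nuclease_sensitivity(unt, benz)
        assert out["nuclease_class"].tolist() == ["direct"]

    def test_collapsed_enrichment_is_dna_bridged(self):
        unt = self._results({"p1": np.log2(16)}, interactor=[True])
        benz = self._results({"p1": np.log2(2)})
        out = ia.classify_nuclease_sensitivity(unt, benz)
        assert out["nuclease_class"].tolist() == ["dna_bridged"]

    def test_absent_from_treated_stratum_is_indeterminate(self):
        unt = self._results({"p1": np.log2(16)}, interactor=[True])
        benz = self._results({"other": 1.0})
        out = ia.classify_nuclease_sensitivity(unt, benz)
        assert out["nuclease_class"].tolist() == ["indeterminate"]
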