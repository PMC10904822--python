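"""Cell scores, the anchor-correlation TIL gate, residual enrichment, signatures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timepair as tp
from conftest import make_log_matrix
from timepair.scoring import anchor_expression


@pytest.fixture()
def small_panel():
    return tp.MarkerPanel(
        populations={"popA": ["g1"], "popB": ["g2", "g3"]}, anchor_gene="PTPRC"
    )


def panel_matrix(rng, n_samples=6):
    genes = ["g1", "g2", "g3", "PTPRC"]
    return make_log_matrix(
        rng.normal(5, 1, size=(4, n_samples)), genes, [f"s{i}" for i in range(n_samples)]
    )


class TestPanelStructure:
    def test_default_panel_has_14_populations(self):
        panel = tp.MarkerPanel.default()
        assert len(panel.populations) == 14
        assert all(3 <= len(g) <= 8 for g in panel.populations.values())

    def test_default_signatures_have_9_characteristics(self):
        assert len(tp.SignatureSet.default().characteristics) == 9

    def test_anchor_may_not_be_a_population_member(self):
        with pytest.raises(tp.ValidationError):
            tp.MarkerPanel(populations={"p": ["PTPRC"]}, anchor_gene="PTPRC")

    def test_empty_population_rejected(self):
        with pytest.raises(tp.ValidationError):
            tp.MarkerPanel(populations={"p": []})


class TestCellScores:
    def test_single_gene_population_equals_that_gene(self, small_panel, rng):
        m = panel_matrix(rng)
        scores = tp.compute_cell_scores(m, small_panel)
        assert np.allclose(scores.loc["popA"], m.values.loc["g1"])

    def test_two_gene_mean(self, small_panel):
        m = make_log_matrix([[2.0], [2.0], [4.0], [1.0]], ["g1", "g2", "g3", "PTPRC"], ["s"])
        scores = tp.compute_cell_scores(m, small_panel)
        assert scores.loc["popB", "s"] == pytest.approx(3.0)

    def test_agrees_with_per_cell_brute_force(self, rng):
        genes = [f"g{i}" for i in range(100)] + ["PTPRC"]
        m = make_log_matrix(rng.normal(size=(101, 8)), genes, [f"s{i}" for i in range(8)])
        pops = {f"p{k}": list(rng.choice(genes[:-1], size=7, replace=False)) for k in range(10)}
        panel = tp.MarkerPanel(populations=pops)
        scores = tp.compute_cell_scores(m, panel)
        for pop, members in pops.items():
            for s in m.samples:
                brute = sum(m.values.loc[g, s] for g in members) / len(members)
                assert scores.loc[pop, s] == pytest.approx(brute, abs=1e-12)

    def test_permutation_invariance(self, small_panel, rng):
        m = panel_matrix(rng)
        shuffled = tp.ExpressionMatrix(
            values=m.values.iloc[::-1, ::-1], unit=tp.Unit.LOG2TPM
        )
        s1 = tp.compute_cell_scores(m, small_panel)
        s2 = tp.compute_cell_scores(shuffled, small_panel)
        assert np.allclose(s1, s2.loc[s1.index, s1.columns])

    def test_missing_gene_dropped_with_warning_then_strict_errors(self, rng):
        panel = tp.MarkerPanel(populations={"p": ["g1", "absent"]})
        m = panel_matrix(rng)
        with pytest.warns(UserWarning, match="absent"):
            scores = tp.compute_cell_scores(m, panel)
        assert np.allclose(scores.loc["p"], m.values.loc["g1"])
        with pytest.raises(tp.ValidationError):
            tp.compute_cell_scores(m, panel, strict=True)

    def test_fully_missing_population_always_errors(self, rng):
        panel = tp.MarkerPanel(populations={"p": ["nope"]})
        with pytest.warns(UserWarning):
            with pytest.raises(tp.ValidationError):
                tp.compute_cell_scores(panel_matrix(rng), panel)

    def test_wrong_unit_rejected(self, small_panel):
        m = tp.ExpressionMatrix(
            values=pd.DataFrame({"s": [1.0]}, index=["g1"]), unit=tp.Unit.TPM
        )
        with pytest.raises(tp.UnitError):
            tp.compute_cell_scores(m, small_panel)


class TestTilGate:
    def test_scores_equal_to_anchor_all_included(self, rng):
        anchor = pd.Series(rng.normal(size=6), index=[f"s{i}" for i in range(6)])
        cell_scores = pd.DataFrame([anchor, anchor], index=["a", "b"])
        res = tp.compute_til_score(cell_scores, anchor)
        assert res.included_populations == {"a", "b"}
        assert np.allclose(res.til_score, cell_scores.mean(axis=0))

    def test_anticorrelated_population_excluded(self, rng):
        anchor = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])
        cell_scores = pd.DataFrame({"up": anchor, "down": -anchor}).T
        res = tp.compute_til_score(cell_scores, anchor)
        assert res.included_populations == {"up"}
        assert res.correlations["down"] == pytest.approx(-1.0)

    def test_zero_variance_population_excluded_with_warning_record(self, rng):
        anchor = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])
        flat = pd.Series(np.ones(6), index=anchor.index)
        cell_scores = pd.DataFrame({"ok": anchor, "flat": flat}).T
        res = tp.compute_til_score(cell_scores, anchor)
        assert "flat" not in res.included_populations
        assert np.isnan(res.correlations["flat"])
        assert any("flat" in w for w in res.warnings)

    def test_empty_gate_is_an_explicit_error(self, rng):
        anchor = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])
        cell_scores = pd.DataFrame({"down": -anchor}).T
        with pytest.raises(tp.ValidationError, match="gate"):
            tp.compute_til_score(cell_scores, anchor)

    def test_fewer_than_three_samples_rejected(self):
        anchor = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(tp.ValidationError):
            tp.compute_til_score(pd.DataFrame({"p": anchor}).T, anchor)

    @given(st.floats(-0.9, 0.95))
    @settings(derandomize=True, max_examples=50)
    def test_gate_monotone_in_threshold(self, threshold):
        rng = np.random.default_rng(5)
        anchor = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        cell_scores = pd.DataFrame(
            {f"p{k}": anchor * rng.uniform(0.2, 1) + rng.normal(0, 0.7, 10) for k in range(8)}
        ).T
        lo = tp.compute_til_score(cell_scores, anchor, r_threshold=threshold)
        hi_thresh = min(threshold + 0.3, 0.99)
        try:
            hi = tp.compute_til_score(cell_scores, anchor, r_threshold=hi_thresh)
            assert hi.included_populations <= lo.included_populations
        except tp.ValidationError:
            pass  # raising the gate emptied it: still monotone

    def test_recovers_loading_populations_in_planted_simulation(self):
        # 10 populations share the anchor factor, 4 are independent noise
        recovered = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            factor = rng.normal(0, 1, size=12)
            anchor = pd.Series(factor + rng.normal(0, 0.3, 12),
                               index=[f"s{i}" for i in range(12)])
            rows = {}
            for k in range(10):
                rows[f"load{k}"] = factor * rng.uniform(0.8, 1.2) + rng.normal(0, 0.3, 12)
            for k in range(4):
                rows[f"noise{k}"] = rng.normal(0, 1, 12)
            cell_scores = pd.DataFrame(rows, index=anchor.index).T
            res = tp.compute_til_score(cell_scores, anchor)
            if res.included_populations == {f"load{k}" for k in range(10)}:
                recovered += 1
        assert recovered / n_runs >= 0.95


class TestEnrichmentResiduals:
    def _til(self, cell_scores, anchor):
        return tp.compute_til_score(cell_scores, anchor, r_threshold=-1.1)

    def test_population_equal_to_til_has_zero_residuals(self, rng):
        anchor = pd.Series(rng.normal(size=8), index=[f"s{i}" for i in range(8)])
        cell_scores = pd.DataFrame({"a": anchor, "b": anchor}).T
        til = self._til(cell_scores, anchor)
        resid = tp.compute_enrichment_scores(cell_scores, til)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_residuals_centered_and_orthogonal_to_til(self, rng):
        samples = [f"s{i}" for i in range(10)]
        anchor = pd.Series(rng.normal(size=10), index=samples)
        cell_scores = pd.DataFrame(
            rng.normal(size=(5, 10)) + anchor.to_numpy(), index=list("abcde"), columns=samples
        )
        til = self._til(cell_scores, anchor)
        resid = tp.compute_enrichment_scores(cell_scores, til)
        x = til.til_score.to_numpy()
        for pop in resid.index:
            r = resid.loc[pop].to_numpy()
            assert abs(r.sum()) < 1e-9
            assert abs(r @ x) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        samples = [f"s{i}" for i in range(9)]
        anchor = pd.Series(rng.normal(size=9), index=samples)
        cell_scores = pd.DataFrame(
            rng.normal(size=(6, 9)) + 0.5 * anchor.to_numpy(),
            index=list("abcdef"),
            columns=samples,
        )
        til = self._til(cell_scores, anchor)
        resid = tp.compute_enrichment_scores(cell_scores, til)
        x = til.til_score.to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        for pop in cell_scores.index:
            y = cell_scores.loc[pop].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(resid.loc[pop], y - X @ beta, atol=1e-9)

    def test_constant_til_degenerate(self):
        cell_scores = pd.DataFrame({"a": [1.0, 1.0, 1.0]}, index=["s0", "s1", "s2"]).T
        til = tp.scoring.TilScoreResult(
            til_score=pd.Series([2.0, 2.0, 2.0], index=["s0", "s1", "s2"]),
            included_populations={"a"},
            correlations={"a": 1.0},
        )
        with pytest.raises(tp.ValidationError):
            tp.compute_enrichment_scores(cell_scores, til)


class TestSignatureScores:
    def test_one_gene_characteristic(self, rng):
        sigs = tp.SignatureSet(characteristics={"c": ["g1"]})
        m = panel_matrix(rng)
        scores = tp.compute_signature_scores(m, sigs)
        assert np.allclose(scores.loc["c"], m.values.loc["g1"])

    def test_mean_and_sum_modes(self):
        sigs = tp.SignatureSet(characteristics={"c": ["g1", "g2", "g3"]})
        m = make_log_matrix([[1.0], [2.0], [3.0]], ["g1", "g2", "g3"], ["s"])
        assert tp.compute_signature_scores(m, sigs, mode="mean").loc["c", "s"] == pytest.approx(2.0)
        assert tp.compute_signature_scores(m, sigs, mode="sum").loc["c", "s"] == pytest.approx(6.0)

    def test_default_set_emits_exactly_nine_rows(self, default_bundle):
        from timepair.expression import counts_to_tpm, log2_normalize

        log_expr = log2_normalize(counts_to_tpm(default_bundle.counts, default_bundle.gene_lengths))
        scores = tp.compute_signature_scores(log_expr, tp.SignatureSet.default())
        assert scores.shape[0] == 9


class TestShiftInvariance:
    def test_constant_shift_moves_scores_but_not_correlations_or_residuals(self, rng):
        genes = [f"g{i}" for i in range(20)] + ["PTPRC"]
        samples = [f"s{i}" for i in range(8)]
        base = rng.normal(5, 1, size=(21, 8))
        panel = tp.MarkerPanel(
            populations={"p1": genes[:5], "p2": genes[5:10], "p3": genes[10:15]}
        )
        c = 2.75
        m1 = make_log_matrix(base, genes, samples)
        m2 = make_log_matrix(base + c, genes, samples)
        s1 = tp.compute_cell_scores(m1, panel)
        s2 = tp.compute_cell_scores(m2, panel)
        assert np.allclose(s2, s1 + c, atol=1e-9)
        t1 = tp.compute_til_score(s1, anchor_expression(m1), r_threshold=-1.1)
        t2 = tp.compute_til_score(s2, anchor_expression(m2), r_threshold=-1.1)
        for pop in s1.index:
            assert t1.correlations[pop] == pytest.approx(t2.correlations[pop], abs=1e-9)
        r1 = tp.compute_enrichment_scores(s1, t1)
        r2 = tp.compute_enrichment_scores(s2, t2)
        assert np.allclose(r1, r2, atol=1e-9)
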