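"""Normalization, fold changes, residual calling, and G/C composition tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agox.dsrna import (
    SampleSheet,
    consistent_calls,
    fold_change_table,
    gc_content,
    gc_test,
    log2fc,
    residual_calls,
    size_factors,
)
from agox.errors import ConfigurationError, InputError, NormalizationError
from agox.simulate import SimConfig, gen_counts


def test_size_factors_identical_columns_are_one():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
    assert size_factors(counts).to_numpy() == pytest.approx([1.0, 1.0])


def test_size_factors_two_sample_doubling_by_hand():
    # per-gene geometric mean of (c, 2c) is c*sqrt(2); ratios are 1/sqrt(2)
    # and sqrt(2), so the factor ratio is exactly 2
    counts = pd.DataFrame({"a": [10, 100, 50], "b": [20, 200, 100]})
    f = size_factors(counts)
    assert f["b"] / f["a"] == pytest.approx(2.0)
    assert f["a"] == pytest.approx(1 / np.sqrt(2))


def test_size_factors_invariant_to_gene_order():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(1, 1000, size=(50, 4)), columns=list("abcd")
    )
    shuffled = counts.sample(frac=1, random_state=1)
    pd.testing.assert_series_equal(size_factors(counts), size_factors(shuffled))


def test_size_factors_need_an_everywhere_nonzero_gene():
    counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
    with pytest.raises(NormalizationError):
        size_factors(counts)


def _sheet(n_reps=3):
    rows = []
    for assay in ("total", "dsrna"):
        for cond in ("control", "mutant1", "mutant2"):
            for r in range(1, n_reps + 1):
                rows.append(
                    {"sample": f"{assay}_{cond}_r{r}", "assay": assay,
                     "condition": cond, "replicate": r}
                )
    return SampleSheet(pd.DataFrame(rows))


def test_log2fc_identical_groups_is_zero():
    sheet = _sheet(2)
    cols = sheet.samples("total", "control") + sheet.samples("total", "mutant1")
    counts = pd.DataFrame({c: [100, 50, 10] for c in cols})
    lfc = log2fc(counts, sheet, "total", "mutant1")
    assert lfc.to_numpy() == pytest.approx(0.0)


def test_log2fc_recovers_planted_fourfold_shift():
    rng = np.random.default_rng(3)
    sheet = _sheet(3)
    base = rng.integers(500, 5000, 200).astype(float)
    data = {}
    for c in sheet.samples("total", "control"):
        data[c] = rng.poisson(base)
    for c in sheet.samples("total", "mutant1"):
        data[c] = rng.poisson(4 * base)
    counts = pd.DataFrame(data)
    # equal library sizes are confounded with the fold change under
    # median-of-ratios; spike the majority as unchanged
    data2 = {c: np.concatenate([v, rng.poisson(np.full(800, 1000))])
             for c, v in data.items()}
    counts = pd.DataFrame(data2)
    lfc = log2fc(counts, sheet, "total", "mutant1")
    assert lfc.iloc[:200].mean() == pytest.approx(2.0, abs=0.1)


def test_log2fc_all_zero_gene_is_zero():
    sheet = _sheet(2)
    cols = sheet.samples("total", "control") + sheet.samples("total", "mutant1")
    counts = pd.DataFrame({c: [0, 100, 200] for c in cols})
    lfc = log2fc(counts, sheet, "total", "mutant1")
    assert lfc.iloc[0] == 0.0


def test_single_replicate_rejected():
    sheet = _sheet(1)
    cols = [s for s in sheet.table["sample"] if s.startswith("total")]
    counts = pd.DataFrame({c: [10, 20] for c in cols})
    with pytest.raises(InputError):
        log2fc(counts, sheet, "total", "mutant1")
    with pytest.raises(ConfigurationError):
        gen_counts(SimConfig(n_reps=1))


def test_perfectly_collinear_fold_changes_give_no_calls():
    x = np.linspace(-2, 2, 100)
    fc = pd.DataFrame({"lfc_total": x, "lfc_dsrna": 2 * x + 1})
    calls = residual_calls(fc)
    assert (calls.call == "none").all()


def test_constant_total_lfc_rejected():
    fc = pd.DataFrame({"lfc_total": [1.0, 1.0, 1.0], "lfc_dsrna": [0, 1, 2]})
    with pytest.raises(InputError):
        residual_calls(fc)


def test_residuals_sum_to_zero_and_null_rate_matches_normal_tail():
    rng = np.random.default_rng(12)
    n = 10_000
    x = rng.normal(0, 1, n)
    y = 0.8 * x + 0.1 + rng.normal(0, 0.2, n)
    calls = residual_calls(pd.DataFrame({"lfc_total": x, "lfc_dsrna": y}))
    assert abs(calls.residual.sum()) < 1e-8 * n
    rate = (calls.call != "none").mean()
    expected = 2 * (1 - stats.norm.cdf(2.5))
    tol = 3 * np.sqrt(expected * (1 - expected) / n)
    assert rate == pytest.approx(expected, abs=tol)


def test_planted_shift_recovered_and_consistent(sim_counts):
    sheet = SampleSheet(sim_counts.samples)
    calls = {}
    for mutant in ("mutant1", "mutant2"):
        fc = fold_change_table(sim_counts.total, sim_counts.dsrna, sheet, mutant)
        calls[mutant] = residual_calls(fc)
    venn = consistent_calls(calls["mutant1"], calls["mutant2"])
    truth = sim_counts.truth
    shared_e = set(venn["enriched"]["shared"])
    shared_d = set(venn["depleted"]["shared"])
    assert len(shared_e & truth.enriched_ids) >= 0.9 * len(truth.enriched_ids)
    assert len(shared_d & truth.depleted_ids) >= 0.9 * len(truth.depleted_ids)
    for direction in ("enriched", "depleted"):
        parts = venn[direction]
        m1_calls = set(calls["mutant1"].index[calls["mutant1"].call == direction])
        assert set(parts["m1_only"]) | set(parts["shared"]) == m1_calls


def test_calls_invariant_to_gene_order(sim_counts):
    sheet = SampleSheet(sim_counts.samples)
    fc = fold_change_table(sim_counts.total, sim_counts.dsrna, sheet, "mutant1")
    a = residual_calls(fc).sort_index()
    b = residual_calls(fc.sample(frac=1, random_state=0)).sort_index()
    pd.testing.assert_frame_equal(a, b)


def test_sensitivity_monotone_in_effect_size():
    recovered = []
    for shift in (0.5, 1.5, 3.0):
        sim = gen_counts(SimConfig(seed=6, n_genes=1000,
                                   enrichment_lfc_shift=shift))
        sheet = SampleSheet(sim.samples)
        fc = fold_change_table(sim.total, sim.dsrna, sheet, "mutant1")
        calls = residual_calls(fc)
        hits = set(calls.index[calls.call == "enriched"]) & sim.truth.enriched_ids
        recovered.append(len(hits) / len(sim.truth.enriched_ids))
    assert recovered == sorted(recovered)


def test_consistent_calls_identical_and_disjoint():
    idx = pd.Index(["g1", "g2", "g3"])
    a = pd.DataFrame({"call": ["enriched", "depleted", "none"]}, index=idx)
    venn = consistent_calls(a, a.copy())
    assert venn["enriched"]["shared"] == ["g1"]
    assert venn["depleted"]["shared"] == ["g2"]
    assert not venn["enriched"]["m1_only"]
    b = pd.DataFrame({"call": ["none", "none", "enriched"]}, index=idx)
    venn = consistent_calls(a, b)
    assert venn["enriched"]["shared"] == []
    assert venn["enriched"]["m1_only"] == ["g1"]
    assert venn["enriched"]["m2_only"] == ["g3"]


def test_gc_content_trivial_cases():
    assert gc_content("GGCC") == 1.0
    assert gc_content("AATT") == 0.0
    with pytest.raises(InputError):
        gc_content("")


def test_gc_test_separates_planted_composition(sim_counts):
    truth = sim_counts.truth
    result = gc_test(truth.enriched_ids, truth.depleted_ids, sim_counts.gene_gc)
    by_set = result.set_index("set")
    assert by_set.loc["enriched", "p_value"] < 0.001
    assert by_set.loc["enriched", "median_gc"] > by_set.loc["all", "median_gc"]
    assert by_set.loc["depleted", "p_value"] < 0.001


def test_gc_test_identical_sets_not_significant():
    rng = np.random.default_rng(2)
    gc = pd.Series(rng.uniform(0.3, 0.7, 60), index=[f"g{i}" for i in range(60)])
    result = gc_test(set(gc.index), set(), gc)
    p = result.set_index("set").loc["enriched", "p_value"]
    assert p > 0.9
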