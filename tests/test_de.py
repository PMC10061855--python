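"""Size factors, BH adjustment and the NB contrast caller."""

import numpy as np
import pandas as pd
import pytest

from droughtmem.de import (
    bh_adjust,
    estimate_size_factors,
    make_calls,
    nb_test,
    read_contrast_table,
)
from droughtmem.errors import DroughtMemError
from droughtmem.expression import CountMatrix
from droughtmem.simulate import SimulationConfig, generate_counts


def brute_force_bh(p):
    """Definitional step-up: padj_i = min_{j: p_j >= p_i} min(1, m*p_j/rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        adj[i] = min(1.0, running)
    return adj


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_matches_definitional_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = rng.integers(1, 60)
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


def _matrix(columns: dict[str, list[int]], treatments: list[str]) -> CountMatrix:
    values = pd.DataFrame(columns)
    values.index = [f"g{i}" for i in range(len(values))]
    design = pd.DataFrame(
        {"ecotype": "AEX", "treatment": treatments,
         "replicate": list(range(1, len(columns) + 1))},
        index=list(columns),
    )
    return CountMatrix(values, design)


class TestSizeFactors:
    def test_identical_samples_get_equal_factors(self):
        cm = _matrix({"a": [10, 20, 5], "b": [10, 20, 5]}, ["R0", "S1"])
        sf = estimate_size_factors(cm)
        assert sf["a"] == pytest.approx(sf["b"])

    def test_doubled_sample_gets_double_factor(self):
        cols = {"a": [10, 20, 5, 80, 33], "b": [20, 40, 10, 160, 66]}
        cm = _matrix(cols, ["R0", "S1"])
        sf = estimate_size_factors(cm)
        # brute-force median of ratios on the 5-gene toy
        a = np.array(cols["a"], float)
        b = np.array(cols["b"], float)
        ref = np.exp((np.log(a) + np.log(b)) / 2)
        assert sf["a"] == pytest.approx(np.median(a / ref))
        assert sf["b"] == pytest.approx(np.median(b / ref))
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-9)

    def test_no_common_gene_falls_back_to_library_size(self, caplog):
        cm = _matrix({"a": [10, 0], "b": [0, 30]}, ["R0", "S1"])
        with caplog.at_level("WARNING"):
            sf = estimate_size_factors(cm)
        assert "library-size" in caplog.text
        assert sf["b"] / sf["a"] == pytest.approx(3.0)

    def test_all_zero_matrix_errors(self):
        cm = _matrix({"a": [0, 0], "b": [0, 0]}, ["R0", "S1"])
        with pytest.raises(DroughtMemError):
            estimate_size_factors(cm)


class TestNBTest:
    def test_identical_groups_are_null(self):
        cm = _matrix(
            {"a": [10, 50], "b": [12, 55], "c": [10, 50], "d": [12, 55]},
            ["R0", "R0", "S1", "S1"],
        )
        res = nb_test(cm, "R0", "S1").set_index("gene")
        assert (res["log2fc"] == 0).all()
        assert (res["call"] == "ns").all()

    def test_all_zero_gene_excluded(self, toy_counts, caplog):
        with caplog.at_level("WARNING"):
            res = nb_test(toy_counts, "R0", "S1")
        assert "g_zero" not in set(res["gene"])
        assert "all-zero" in caplog.text

    def test_too_few_replicates_rejected(self):
        cm = _matrix({"a": [10], "b": [12], "c": [11]}, ["R0", "R0", "S1"])
        with pytest.raises(DroughtMemError, match="replicate"):
            nb_test(cm, "R0", "S1")

    def test_planted_fourfold_gene_called_up(self):
        cfg = SimulationConfig(
            n_genes=500,
            category_proportions={"[+/=]": 0.1, "none": 0.9},
            effect_log2fc=2.0, dispersion=0.02, n_replicates=5,
            n_tfs=5, n_switch_modules=0, seed=11,
        )
        ds = generate_counts(cfg)
        res = nb_test(ds.counts, "R0", "S1", ecotype="AEX").set_index("gene")
        planted = [g for g, c in ds.truth_categories.items() if c == "[+/=]"]
        calls = res.loc[planted, "call"]
        assert (calls == "up").mean() > 0.95

    def test_swapping_groups_negates_log2fc_and_flips_calls(self):
        cfg = SimulationConfig(
            n_genes=300, effect_log2fc=2.0, dispersion=0.05,
            n_replicates=3, n_tfs=5, n_switch_modules=0, seed=5,
        )
        ds = generate_counts(cfg)
        fwd = nb_test(ds.counts, "R0", "S1", ecotype="AEX").set_index("gene")
        rev = nb_test(ds.counts, "S1", "R0", ecotype="AEX").set_index("gene")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert (rev["call"] == fwd["call"].map(flip)).all()

    def test_log2fc_recovery_of_planted_effect(self):
        """Median absolute estimation error of a planted log2fc = 2 shift
        below 0.25 at 5 replicates, dispersion 0.05, under the generator's
        default direction-balanced trajectory mix."""
        cfg = SimulationConfig(
            n_genes=1000, effect_log2fc=2.0, dispersion=0.05, n_replicates=5,
            n_tfs=5, n_switch_modules=0, seed=13,
        )
        ds = generate_counts(cfg)
        res = nb_test(ds.counts, "R0", "S1", ecotype="AEX").set_index("gene")
        up = [g for g, c in ds.truth_categories.items()
              if c in ("[+/+]", "[+/-]", "[+/=]")]
        down = [g for g, c in ds.truth_categories.items()
                if c in ("[-/-]", "[-/+]", "[-/=]")]
        assert (res.loc[up, "log2fc"] - 2.0).abs().median() < 0.25
        assert (res.loc[down, "log2fc"] + 2.0).abs().median() < 0.25


def test_global_null_type_i_error_controlled_after_bh():
    """Under a full null (no planted effects, 2,000 genes), the probability
    of making any BH-adjusted call should not exceed the nominal 0.05.
    With 12 seeded simulations, observing more than 2 contaminated runs
    would be evidence of anticonservative behaviour (P(X > 2 | p=0.05)
    ~= 0.02)."""
    contaminated = 0
    for s in range(12):
        cfg = SimulationConfig(
            n_genes=2000, category_proportions={"none": 1.0},
            n_replicates=3, n_tfs=5, n_switch_modules=0, seed=500 + s,
        )
        ds = generate_counts(cfg)
        res = nb_test(ds.counts, "R0", "S1", ecotype="AEX")
        contaminated += int((res["call"] != "ns").any())
    assert contaminated <= 2


def test_call_thresholds_are_strict_on_padj_and_inclusive_on_lfc():
    log2fc = np.array([1.0, 1.0, 0.99, -1.0, 2.0])
    padj = np.array([0.049, 0.05, 0.01, 0.01, 1.0])
    calls = make_calls(log2fc, padj, alpha=0.05, lfc_min=1.0)
    assert list(calls) == ["up", "ns", "ns", "down", "ns"]


def test_external_contrast_table_reader(tmp_path):
    p = tmp_path / "deseq.tsv"
    pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "log2FoldChange": [2.0, 0.2],
            "pvalue": [1e-6, 0.4],
            "padj": [1e-5, 0.6],
        }
    ).to_csv(p, sep="\t", index=False)
    df = read_contrast_table(p)
    assert list(df["call"]) == ["up", "ns"]
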