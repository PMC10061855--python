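"""Signed co-expression, edge filtering and switch-module detection."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from droughtmem.errors import DroughtMemError
from droughtmem.expression import (
    GeneAnnotation,
    compute_fpkm,
    effective_mapped_reads,
    log_fpkm,
)
from droughtmem.simulate import SimulationConfig, simulate
from droughtmem.switch import (
    correlate,
    correlation_pvalue,
    detect_switch_modules,
    filter_edges,
    split_regulatory,
)


class TestSplit:
    def test_partition(self):
        assert split_regulatory({"a", "b", "c"}, {"b"}) == ({"b"}, {"a", "c"})

    def test_no_regulators(self):
        assert split_regulatory({"a", "b"}, set()) == (set(), {"a", "b"})

    def test_all_regulators_leaves_no_functional_genes(self):
        reg, func = split_regulatory({"a", "b"}, {"a", "b"})
        assert func == set()
        assert detect_switch_modules(pd.DataFrame(columns=["tf", "target", "sign"])) == []

    def test_outside_regulators_ignored(self, caplog):
        with caplog.at_level("WARNING"):
            reg, _ = split_regulatory({"a"}, {"a", "zz"})
        assert reg == {"a"}
        assert "ignored" in caplog.text


def _expr(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(next(iter(rows.values()))))]).T


class TestCorrelate:
    def test_identical_and_reflected_profiles(self):
        x = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        mirrored = list(2 * np.mean(x) - np.array(x))
        expr = _expr({"tf": x, "same": x, "anti": mirrored})
        edges = correlate(expr, {"tf"}, {"same", "anti"}).set_index("target")
        assert edges.loc["same", "r"] == pytest.approx(1.0)
        assert edges.loc["same", "pvalue"] < 1e-9
        assert edges.loc["anti", "r"] == pytest.approx(-1.0)
        assert edges.loc["anti", "sign"] == "-"

    def test_too_few_samples_rejected(self):
        expr = _expr({"tf": [1.0, 2.0], "t": [2.0, 1.0]})
        with pytest.raises(DroughtMemError):
            correlate(expr, {"tf"}, {"t"})

    def test_constant_genes_skipped(self, caplog):
        expr = _expr({"tf": [1.0, 2.0, 3.0, 4.0], "flat": [5.0] * 4})
        with caplog.at_level("WARNING"):
            edges = correlate(expr, {"tf"}, {"flat"})
        assert edges.empty
        assert "constant" in caplog.text

    def test_p_against_exhaustive_permutation_oracle(self):
        """The t-based two-sided p tracks the exhaustive 720-permutation p
        for strongly correlated 6-sample profiles (the regime the edge
        filter operates in): typical agreement within a couple of the
        enumeration's resolution steps, worst case bounded by the t
        approximation's small-sample error."""
        rng = np.random.default_rng(11)
        perms = [list(p) for p in permutations(range(6))]

        def pearson(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return float(a @ b / np.sqrt((a @ a) * (b @ b)))

        gaps = []
        for _ in range(40):
            x = rng.normal(size=6)
            y = x + rng.normal(scale=0.35, size=6)
            r0 = abs(pearson(x, y))
            if r0 < 0.8:
                continue
            p_perm = np.mean([abs(pearson(x, y[p])) >= r0 - 1e-12 for p in perms])
            p_t = float(correlation_pvalue(r0, 6))
            gaps.append(abs(p_t - p_perm))
        assert len(gaps) >= 20
        assert float(np.median(gaps)) < 0.02
        assert max(gaps) < 0.1


class TestFilter:
    def test_conjunction_of_strict_thresholds(self):
        edges = pd.DataFrame(
            {
                "tf": ["A"] * 4,
                "target": ["t1", "t2", "t3", "t4"],
                "r": [0.95, 0.95, -0.95, 0.90],
                "pvalue": [0.01, 0.06, 0.01, 0.01],
                "sign": ["+", "+", "-", "+"],
            }
        )
        kept = filter_edges(edges)
        assert set(kept["target"]) == {"t1", "t3"}  # t2 fails p, t4 fails |r|>0.9
        assert kept.set_index("target").loc["t3", "sign"] == "-"

    def test_monotone_in_r_min(self):
        rng = np.random.default_rng(3)
        edges = pd.DataFrame(
            {
                "tf": "A",
                "target": [f"t{i}" for i in range(50)],
                "r": rng.uniform(-1, 1, 50),
                "pvalue": rng.uniform(0, 0.1, 50),
                "sign": "+",
            }
        )
        sizes = [len(filter_edges(edges, r_min=r)) for r in (0.5, 0.7, 0.9, 0.99)]
        assert sizes == sorted(sizes, reverse=True)


def _edges(sig_per_target: dict[str, dict[str, str]]) -> pd.DataFrame:
    rows = [
        {"tf": tf, "target": t, "r": 0.95 if s == "+" else -0.95, "pvalue": 0.01, "sign": s}
        for t, sig in sig_per_target.items()
        for tf, s in sig.items()
    ]
    return pd.DataFrame(rows)


def brute_force_modules(sig_per_target, min_size=5):
    """Exhaustive signature grouping oracle."""
    groups: dict[frozenset, set] = {}
    for t, sig in sig_per_target.items():
        groups.setdefault(frozenset(sig.items()), set()).add(t)
    out = set()
    for sig, members in groups.items():
        pos = {tf for tf, s in sig if s == "+"}
        neg = {tf for tf, s in sig if s == "-"}
        if pos and neg and len(members) >= min_size:
            out.add((frozenset(pos), frozenset(neg), frozenset(members)))
    return out


class TestDetect:
    def test_tf_pair_controlling_one_gene_set(self):
        """One positive and one negative TF over the same 29 targets yields
        a single module containing exactly those targets."""
        sig = {f"t{i}": {"A": "+", "B": "-"} for i in range(29)}
        mods = detect_switch_modules(_edges(sig))
        assert len(mods) == 1
        assert mods[0].positive_tfs == frozenset({"A"})
        assert mods[0].negative_tfs == frozenset({"B"})
        assert len(mods[0].members) == 29

    def test_single_sign_group_is_not_a_switch(self):
        sig = {f"t{i}": {"A": "+"} for i in range(10)}
        assert detect_switch_modules(_edges(sig)) == []

    def test_small_groups_dropped(self):
        sig = {f"t{i}": {"A": "+", "B": "-"} for i in range(4)}
        assert detect_switch_modules(_edges(sig), min_module_size=5) == []
        assert len(detect_switch_modules(_edges(sig), min_module_size=4)) == 1

    def test_matches_brute_force_signature_oracle(self):
        rng = np.random.default_rng(23)
        tfs = ["A", "B", "C", "D"]
        sig_per_target = {}
        for i in range(200):
            chosen = rng.choice(tfs, size=rng.integers(1, 4), replace=False)
            sig_per_target[f"t{i}"] = {
                tf: ("+" if rng.random() < 0.5 else "-") for tf in chosen
            }
        mods = detect_switch_modules(_edges(sig_per_target), min_module_size=3)
        got = {(m.positive_tfs, m.negative_tfs, m.members) for m in mods}
        assert got == brute_force_modules(sig_per_target, min_size=3)

    def test_grouping_is_order_invariant_and_idempotent(self):
        sig = {f"t{i}": {"A": "+", "B": "-"} for i in range(6)}
        edges = _edges(sig)
        shuffled = edges.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = detect_switch_modules(edges)
        b = detect_switch_modules(shuffled)
        assert [m.to_dict() for m in a] == [m.to_dict() for m in b]

    def test_module_count_non_increasing_in_thresholds(self):
        sig = {f"t{i}": {"A": "+", "B": "-"} for i in range(6)}
        sig.update({f"u{i}": {"C": "+", "D": "-"} for i in range(4)})
        e = _edges(sig)
        assert len(detect_switch_modules(e, min_module_size=4)) >= len(
            detect_switch_modules(e, min_module_size=5)
        )


class TestPlantedRecovery:
    def test_noiseless_profiles_correlate_exactly(self):
        cfg = SimulationConfig(
            n_genes=300, n_replicates=2, noise_sd=0.0, n_switch_modules=1,
            module_size_range=(5, 5), seed=3,
        )
        ds = simulate(cfg)
        pos, neg, members = ds.truth_modules[0]
        prof = ds.truth_profiles
        for eco_cols in (prof.columns[:6], prof.columns[6:]):
            sub = prof[eco_cols]
            base = sub.loc[sorted(pos)[0]].to_numpy()
            for g in members | pos:
                r = np.corrcoef(base, sub.loc[g].to_numpy())[0, 1]
                assert r == pytest.approx(1.0, abs=1e-12)
            for g in neg:
                r = np.corrcoef(base, sub.loc[g].to_numpy())[0, 1]
                assert r == pytest.approx(-1.0, abs=1e-12)

    def test_single_planted_module_recovered_exactly(self):
        cfg = SimulationConfig(
            n_genes=300, n_replicates=3, noise_sd=0.05, n_switch_modules=1,
            module_size_range=(5, 5), seed=3,
        )
        ds = simulate(cfg)
        fpkm = compute_fpkm(
            ds.counts,
            GeneAnnotation(ds.gene_lengths),
            effective_mapped_reads(ds.counts),
        )
        cols = ds.counts.samples_for(ecotype="AEX")
        reg, func = split_regulatory(ds.truth_dmgs(), set(ds.truth_regulators))
        edges = filter_edges(correlate(log_fpkm(fpkm[cols]), reg, func))
        mods = detect_switch_modules(edges)
        truth = {(p, n, m) for p, n, m in ds.truth_modules}
        got = {(m.positive_tfs, m.negative_tfs, m.members) for m in mods}
        assert truth <= got

    def test_no_modules_requested_means_none_planted(self):
        cfg = SimulationConfig(n_genes=100, n_switch_modules=0, seed=1)
        ds = simulate(cfg)
        assert ds.truth_modules == []
        assert detect_switch_modules(
            pd.DataFrame(columns=["tf", "target", "r", "pvalue", "sign"])
        ) == []
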