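"""CRE-seq analysis tests: counting, filtering, expression, mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asedyn.cre import (
    ChimeraResult,
    CreCounts,
    classify_chimera_range,
    count_barcodes,
    cre_expression,
    correlate_with_endogenous,
    filter_cres,
    map_chimera,
    map_timepoints,
)
from asedyn.cre import test_cre_dynamics as cre_dynamics
from asedyn.cre import test_cre_levels as cre_levels
from asedyn.cre import test_variant as variant_test
from asedyn.synthetic import CreSimulationConfig, simulate_cre_counts


def make_manifest(constructs, n_bc=4):
    """constructs: {construct_id: allele_label}; unique 10 bp barcodes."""
    alphabet = "ACGT"
    rows = []
    i = 0
    for cid, label in constructs.items():
        for _ in range(n_bc):
            bc = "".join(alphabet[(i // 4**k) % 4] for k in range(5)) + "TACGT"
            rows.append(
                {"construct_id": cid, "gene": "g", "region_index": 0,
                 "allele_label": label, "variant_ids": "", "barcode": bc}
            )
            i += 1
    return pd.DataFrame(rows)


class TestCountBarcodes:
    def test_exact_match_only(self):
        manifest = make_manifest({"c1": "P1"}, n_bc=1)
        bc = manifest["barcode"].iloc[0]
        mismatched = ("T" if bc[0] == "A" else "A") + bc[1:]
        reads = {"RNA_t0": ["GG" + bc + "AA", "GG" + mismatched + "AA"]}
        counts = count_barcodes(reads, manifest)
        assert counts.rna.loc[bc, "RNA_t0"] == 1
        assert counts.discarded_reads["RNA_t0"] == 1

    def test_round_trip_from_simulated_counts(self, small_manifest):
        cfg = CreSimulationConfig(n_timepoints=3, rna_depth=20, dna_depth=20, seed=2)
        dna, rna = simulate_cre_counts(small_manifest, {}, cfg)
        reads = {}
        for frame in (rna, dna):
            for col in frame.columns:
                reads[col] = [
                    "TT" + bc + "GG"
                    for bc, k in frame[col].items()
                    for _ in range(int(k))
                ]
        counts = count_barcodes(reads, small_manifest)
        assert counts.rna.loc[rna.index].to_numpy().tolist() == rna.to_numpy().tolist()
        assert counts.dna.loc[dna.index].to_numpy().tolist() == dna.to_numpy().tolist()

    def test_empty_reads_all_zero(self, small_manifest):
        counts = count_barcodes({"RNA_t0": []}, small_manifest)
        assert (counts.rna.to_numpy() == 0).all()

    def test_duplicate_barcode_rejected(self, small_manifest):
        dup = pd.concat([small_manifest, small_manifest.iloc[[0]]])
        with pytest.raises(ValueError):
            count_barcodes({"RNA_t0": []}, dup)


class TestFilterCres:
    def _counts(self, rna, dna, manifest=None):
        rna = pd.DataFrame(
            rna, index=[f"b{i}" for i in range(len(rna))],
            columns=[f"RNA_t{j}" for j in range(len(rna[0]))],
        )
        dna = pd.DataFrame(
            dna, index=rna.index, columns=[f"DNA_{j}" for j in range(len(dna[0]))]
        )
        return CreCounts(rna, dna, manifest if manifest is not None else pd.DataFrame({"barcode": rna.index}))

    def test_zero_fraction_threshold(self):
        base = [1000] * 19
        seven_zeros = [0] * 7 + [1000] * 12
        six_zeros = [0] * 6 + [1000] * 13
        counts = self._counts(
            [seven_zeros, six_zeros, base], [[500, 500]] * 3
        )
        kept = filter_cres(counts)
        assert "b0" not in kept and "b1" in kept and "b2" in kept

    def test_mean_dna_boundary(self):
        counts = self._counts(
            [[1000] * 19, [1000] * 19], [[99, 99], [100, 100]]
        )
        kept = filter_cres(counts)
        assert "b0" not in kept and "b1" in kept

    def test_mean_rna_boundary(self):
        counts = self._counts(
            [[99] * 19, [100] * 19], [[500, 500]] * 2
        )
        kept = filter_cres(counts)
        assert "b0" not in kept and "b1" in kept


class TestCreExpression:
    def test_hand_fixture_ratios(self):
        # symmetric rows keep all size factors at 1 (hand-checked medians)
        rna = pd.DataFrame(
            {"RNA_t0": [100, 100, 100], "RNA_t1": [200, 50, 100]},
            index=["b1", "b2", "b3"],
        )
        dna = pd.DataFrame(
            {"DNA_0": [100, 100, 100], "DNA_1": [100, 100, 100]},
            index=rna.index,
        )
        counts = CreCounts(rna, dna, pd.DataFrame({"barcode": rna.index}))
        expr = cre_expression(counts)
        assert np.allclose(
            expr.expression.to_numpy(), [[1, 2], [1, 0.5], [1, 1]]
        )

    def test_zero_rna_count_is_missing(self):
        rna = pd.DataFrame(
            {"RNA_t0": [100, 100], "RNA_t1": [0, 100]}, index=["b1", "b2"]
        )
        dna = pd.DataFrame({"DNA_0": [100, 100]}, index=rna.index)
        expr = cre_expression(CreCounts(rna, dna, pd.DataFrame({"barcode": rna.index})))
        assert np.isnan(expr.expression.loc["b1", "RNA_t1"])

    def test_zero_dna_barcode_dropped_with_flag(self):
        rna = pd.DataFrame({"RNA_t0": [100, 100]}, index=["b1", "b2"])
        dna = pd.DataFrame({"DNA_0": [0, 100]}, index=rna.index)
        expr = cre_expression(CreCounts(rna, dna, pd.DataFrame({"barcode": rna.index})))
        assert expr.dropped_zero_dna == ["b1"]
        assert list(expr.expression.index) == ["b2"]

    def test_recovers_generating_curves(self, small_manifest):
        """Simulated counts -> expression recovers the truth within noise."""
        T = 19
        t = np.arange(T)
        curve = 1.0 + 1.0 / (1.0 + np.exp(-(t - 9)))
        cfg = CreSimulationConfig(
            n_timepoints=T, rna_depth=10_000, dna_depth=10_000, seed=8
        )
        dna, rna = simulate_cre_counts(small_manifest, {"conB": curve}, cfg)
        expr = cre_expression(CreCounts(rna, dna, small_manifest))
        # normalization is blind to the design, so per-timepoint depth cannot
        # be told apart from shared expression; the between-construct ratio is
        # the identifiable quantity and must recover the generating curve
        ratio = (
            expr.construct_mean("conB") / expr.construct_mean("conA")
        ).to_numpy()
        rmse = np.sqrt(np.mean((ratio / curve - 1.0) ** 2))
        assert rmse < 0.10


class TestEndogenousCorrelation:
    def test_identical_and_negated_series(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=19)
        regions = pd.DataFrame([base, -base], index=["r1", "r2"])
        out = correlate_with_endogenous(regions, base)
        assert out.loc["r1", "r"] == pytest.approx(1.0)
        assert out.loc["r2", "r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        regions = pd.DataFrame([[1.0] * 10], index=["r1"])
        out = correlate_with_endogenous(regions, np.arange(10.0))
        assert out.loc["r1", "flag"] == "zero_variance"
        assert np.isnan(out.loc["r1", "r"])

    def test_nearest_time_mapping_unique_and_ordered(self):
        cre_times = np.linspace(0, 13, 27)
        rna_times = np.linspace(0, 13, 19)
        idx = map_timepoints(cre_times, rna_times)
        assert len(np.unique(idx)) == 19
        assert (np.diff(idx) > 0).all()

    def test_tie_goes_to_earlier_sample(self):
        assert map_timepoints([0.0, 2.0], [1.0])[0] == 0


class TestCreLevels:
    def _expr(self, group_a, group_b, seed=0, T=10):
        rng = np.random.default_rng(seed)
        rows = {}
        labels = {}
        for i, mu in enumerate(group_a):
            rows[f"a{i}"] = mu * np.exp(rng.normal(0, 0.05, T))
            labels[f"a{i}"] = "P1"
        for i, mu in enumerate(group_b):
            rows[f"b{i}"] = mu * np.exp(rng.normal(0, 0.05, T))
            labels[f"b{i}"] = "P2"
        return pd.DataFrame(rows).T, pd.Series(labels)

    def test_null_pvalues_uniform(self):
        ps = []
        for rep in range(2000):
            expr, labels = self._expr([1, 1, 1, 1], [1, 1, 1, 1], seed=rep)
            ps.append(cre_levels(expr, labels)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_twofold_shift_detected(self):
        expr, labels = self._expr([1] * 4, [2] * 4, seed=1)
        assert cre_levels(expr, labels)["p"] < 0.01

    def test_single_barcode_group_untestable(self):
        expr, labels = self._expr([1, 1], [1], seed=2)
        labels[:] = ["P1", "P1", "P2"]
        assert cre_levels(expr, labels)["untestable"]

    def test_offset_barcode_triggers_level_not_dynamics(self):
        """A 10x barcode with identical dynamics is a level artifact only."""
        T = 10
        base = np.linspace(1, 2, T)
        expr = pd.DataFrame(
            {"a0": base, "a1": base, "b0": base * 10, "b1": base},
        ).T
        labels = pd.Series({"a0": "P1", "a1": "P1", "b0": "P2", "b1": "P2"})
        weights = pd.DataFrame(
            np.full((4, T), 100.0), index=expr.index, columns=expr.columns
        )
        dyn = cre_dynamics(expr, weights, labels, n_perm=200, seed=0)
        assert dyn.p > 0.5  # allele share constant over time
        lev = cre_levels(expr, labels)
        assert lev["p"] < 0.5 or not np.isfinite(lev["p"])


class TestCreDynamics:
    def test_level_difference_alone_gives_uniform_p(self):
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(200):
            T = 19
            base = 1.0 + 0.5 * rng.random()
            a = base * np.exp(rng.normal(0, 0.05, (4, T)))
            b = 2 * base * np.exp(rng.normal(0, 0.05, (4, T)))
            expr = pd.DataFrame(
                np.vstack([a, b]), index=[f"x{i}" for i in range(8)]
            )
            labels = pd.Series(
                ["P1"] * 4 + ["P2"] * 4, index=expr.index
            )
            weights = pd.DataFrame(
                np.full((8, T), 500.0), index=expr.index, columns=expr.columns
            )
            ps.append(cre_dynamics(expr, weights, labels, n_perm=200, seed=rep).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_delayed_allele_detected(self, small_manifest):
        T = 19
        t = np.arange(T)
        hits = 0
        for rep in range(10):
            c1 = 1 + 1.0 / (1 + np.exp(-(t - 9)))
            c2 = 1 + 1.0 / (1 + np.exp(-(t - 12)))
            cfg = CreSimulationConfig(
                n_timepoints=T, rna_depth=10_000, dna_depth=10_000, seed=100 + rep
            )
            dna, rna = simulate_cre_counts(
                small_manifest, {"conA": c1, "conB": c2}, cfg
            )
            expr = cre_expression(CreCounts(rna, dna, small_manifest))
            labels = small_manifest.set_index("barcode")["allele_label"]
            res = cre_dynamics(
                expr.expression, expr.weights, labels.loc[expr.expression.index],
                n_perm=500, seed=rep,
            )
            if res.p < 0.05:
                hits += 1
        assert hits >= 9


class TestVariantTest:
    def _region(self, seed, effect_on_variant0=True):
        labels = {
            "par_P1": "P1",
            "par_P2": "P2",
            "sw0_a": "swap(v0,P2->P1)",
            "sw0_b": "swap(v0,P1->P2)",
            "sw1_a": "swap(v1,P2->P1)",
            "sw1_b": "swap(v1,P1->P2)",
        }
        region = make_manifest(labels)
        # filler constructs from other regions anchor the blind size factors,
        # as the flat majority of a real library does
        filler = {f"fill{i}": "P1" for i in range(12)}
        manifest = make_manifest({**labels, **filler})
        T = 19
        t = np.arange(T)
        flat = np.full(T, 1.5)
        bump = 1.0 / (1 + np.exp(-(t - 9)))
        dynamic = 1.5 + (bump - bump.mean())  # mean-matched: dynamics only
        # constructs carrying the P2 allele at v0 respond dynamically
        p2_at_v0 = {"par_P2", "sw0_a", "sw1_b"}
        effects = {
            cid: (dynamic if (cid in p2_at_v0 and effect_on_variant0) else flat)
            for cid in labels
        }
        cfg = CreSimulationConfig(
            n_timepoints=T, rna_depth=10_000, dna_depth=10_000, seed=seed
        )
        dna, rna = simulate_cre_counts(manifest, effects, cfg)
        region_barcodes = manifest["construct_id"].isin(labels)
        region_manifest = manifest[region_barcodes]
        return cre_expression(CreCounts(rna, dna, manifest)), region_manifest

    def test_rate_effect_found_by_dynamics_not_levels(self):
        dyn_hits, lvl_hits = 0, 0
        n = 10
        for rep in range(n):
            expr, manifest = self._region(seed=200 + rep)
            res = variant_test(expr, manifest, "v0", n_perm=500, seed=rep)
            dyn_hits += res["p_dyn"] < 0.05
            lvl_hits += res["p_level"] < 0.05
        assert dyn_hits >= 0.8 * n
        assert lvl_hits <= 0.3 * n

    def test_null_variant_not_flagged(self):
        ps = []
        for rep in range(20):
            expr, manifest = self._region(seed=300 + rep, effect_on_variant0=False)
            ps.append(variant_test(expr, manifest, "v1", n_perm=200, seed=rep)["p_dyn"])
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2

    def test_missing_genotype_group_untestable(self):
        expr, manifest = self._region(seed=400)
        only_p1 = manifest[manifest["allele_label"] == "P1"]
        res = variant_test(expr, only_p1, "v0", n_perm=50, seed=0)
        assert res["untestable"]


class TestChimeraMapping:
    def _chimera_region(self, seed, effect_half="proximal"):
        labels = {
            "par_P1": "P1",
            "par_P2": "P2",
            "chim_AB": "chimera(left=P1)",
            "chim_BA": "chimera(left=P2)",
        }
        manifest = make_manifest(labels)
        T = 19
        t = np.arange(T)
        flat = np.full(T, 1.5)
        dynamic = 1.0 + 1.0 / (1 + np.exp(-(t - 9)))
        # the dynamic response follows whichever half carries the P2 allele
        if effect_half == "proximal":
            resp = {"par_P2", "chim_AB"}  # chim(left=P1) has P2 proximal half
        else:
            resp = {"par_P2", "chim_BA"}
        effects = {cid: (dynamic if cid in resp else flat) for cid in labels}
        cfg = CreSimulationConfig(
            n_timepoints=T, rna_depth=10_000, dna_depth=10_000, seed=seed
        )
        dna, rna = simulate_cre_counts(manifest, effects, cfg)
        return cre_expression(CreCounts(rna, dna, manifest)), manifest

    def test_proximal_effect_mapped_proximally(self):
        hits = 0
        n = 10
        for rep in range(n):
            expr, manifest = self._chimera_region(seed=500 + rep)
            res = map_chimera(expr, manifest, n_perm=500, seed=rep)
            hits += res.classification == "proximal"
        assert hits >= 0.9 * n

    def test_no_parental_difference_gives_neither(self):
        labels = {
            "par_P1": "P1", "par_P2": "P2",
            "chim_AB": "chimera(left=P1)", "chim_BA": "chimera(left=P2)",
        }
        manifest = make_manifest(labels)
        cfg = CreSimulationConfig(rna_depth=10_000, dna_depth=10_000, seed=3)
        dna, rna = simulate_cre_counts(manifest, {}, cfg)
        expr = cre_expression(CreCounts(rna, dna, manifest))
        res = map_chimera(expr, manifest, n_perm=300, seed=1)
        assert res.classification == "neither"

    def test_effects_in_both_halves_give_both(self):
        labels = {
            "par_P1": "P1", "par_P2": "P2",
            "chim_AB": "chimera(left=P1)", "chim_BA": "chimera(left=P2)",
        }
        manifest = make_manifest(labels)
        T = 19
        t = np.arange(T)
        flat = np.full(T, 2.0)
        half_dyn = 0.5 / (1 + np.exp(-(t - 9)))
        # equal-size effects from each half add: P2 parental gets both
        effects = {
            "par_P1": flat,
            "par_P2": flat + 2 * half_dyn,
            "chim_AB": flat + half_dyn,
            "chim_BA": flat + half_dyn,
        }
        cfg = CreSimulationConfig(
            n_timepoints=T, rna_depth=20_000, dna_depth=20_000, seed=6
        )
        dna, rna = simulate_cre_counts(manifest, effects, cfg)
        expr = cre_expression(CreCounts(rna, dna, manifest))
        res = map_chimera(expr, manifest, n_perm=500, seed=2)
        assert res.classification == "both"


class TestChimeraRange:
    def test_chimera_equal_to_parent_is_inside(self):
        p1 = np.array([1.0, 2.0, 3.0])
        p2 = np.array([2.0, 3.0, 4.0])
        label, d_pp, d_cp, n_out = classify_chimera_range(p1, p2, p1)
        assert label == "inside"
        assert d_cp == pytest.approx(d_pp / 2)
        assert n_out == 0

    def test_hand_euclidean_example(self):
        # parents (0,0) and (2,0); chimera (1,3): mean distance sqrt(10) > 2
        label, d_pp, d_cp, n_out = classify_chimera_range(
            [0, 0], [2, 0], [1, 3]
        )
        assert label == "outside"
        assert d_pp == pytest.approx(2.0)
        assert d_cp == pytest.approx(np.sqrt(10))
        assert n_out == 1

    def test_midpoint_chimera_inside_with_no_outside_timepoints(self):
        p1 = np.array([1.0, 5.0, 2.0, 4.0])
        p2 = np.array([3.0, 1.0, 6.0, 2.0])
        mid = (p1 + p2) / 2
        label, _, _, n_out = classify_chimera_range(p1, p2, mid)
        assert label == "inside" and n_out == 0

    def test_convex_combination_always_inside(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p1 = rng.normal(size=12)
            p2 = rng.normal(size=12)
            lam = rng.random(12)
            chim = lam * p1 + (1 - lam) * p2
            label, _, _, n_out = classify_chimera_range(p1, p2, chim)
            assert label == "inside" and n_out == 0
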