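"""Background-probe specificity: ranking, FDR, Moran's I, NN distances."""

import numpy as np
import pandas as pd
import pytest

import stqc
from stqc.specificity import classify_probe_confidence


def _calls(gene_counts: dict, rng=None, field=100.0) -> stqc.TranscriptTable:
    """Uniform random calls with exact per-gene totals."""
    rng = rng or np.random.default_rng(0)
    genes, xs, ys = [], [], []
    for gene, n in gene_counts.items():
        genes += [gene] * n
        xs.append(rng.uniform(0, field, n))
        ys.append(rng.uniform(0, field, n))
    return stqc.TranscriptTable.from_arrays(
        genes, np.concatenate(xs) if xs else [], np.concatenate(ys) if ys else []
    )


class TestProbeCountRanking:
    def _panel(self):
        return stqc.ProbePanel.from_genes(
            targets=["T1", "T2"], backgrounds=["B1", "B2"]
        )

    def test_threshold_flagging(self):
        tt = _calls({"B1": 50, "B2": 10, "T1": 40, "T2": 60})
        tab = stqc.probe_count_ranking(tt, self._panel()).set_index("gene_id")
        assert tab.at["T1", "within_background_range"] == True
        assert tab.at["T2", "within_background_range"] == False

    def test_all_targets_above_background(self):
        tt = _calls({"B1": 5, "B2": 3, "T1": 50, "T2": 60})
        tab = stqc.probe_count_ranking(tt, self._panel())
        targets = tab[tab["kind"] == "target"]
        assert not targets["within_background_range"].any()

    def test_matches_brute_force_sort(self, rng):
        panel = stqc.ProbePanel.from_genes(
            targets=[f"T{i}" for i in range(5)],
            backgrounds=[f"B{i}" for i in range(3)],
        )
        counts = {g: int(rng.integers(0, 100)) for g in panel.entries["gene_id"]}
        tt = _calls(counts, rng)
        tab = stqc.probe_count_ranking(tt, panel)
        oracle = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        assert tab["gene_id"].tolist() == [g for g, _ in oracle]
        assert tab["rank"].tolist() == list(range(1, 9))

    def test_requires_background(self):
        panel = stqc.ProbePanel.from_genes(targets=["T1"])
        with pytest.raises(ValueError, match="background"):
            stqc.probe_count_ranking(_calls({"T1": 5}), panel)


class TestGlobalFdr:
    def test_hand_example(self):
        # 10 bg calls / 2 bg probes; 1000 target calls / 5 genes -> 2.5%
        panel = stqc.ProbePanel.from_genes(
            targets=[f"T{i}" for i in range(5)], backgrounds=["B1", "B2"]
        )
        tt = _calls({"B1": 6, "B2": 4, **{f"T{i}": 200 for i in range(5)}})
        res = stqc.global_fdr(tt, panel)
        assert res.fdr_percent == pytest.approx(2.5)
        assert res.background_barcode_calls == 10
        assert res.total_target_gene_calls == 1000

    def test_zero_background_calls(self):
        panel = stqc.ProbePanel.from_genes(targets=["T1"], backgrounds=["B1"])
        res = stqc.global_fdr(_calls({"T1": 100}), panel)
        assert res.fdr_percent == 0.0

    def test_equal_rates_give_100_percent(self):
        # equal per-probe mean rates: formula reduces to exactly 100%
        panel = stqc.ProbePanel.from_genes(
            targets=["T1", "T2", "T3"], backgrounds=["B1", "B2"]
        )
        tt = _calls({"T1": 7, "T2": 7, "T3": 7, "B1": 7, "B2": 7})
        assert stqc.global_fdr(tt, panel).fdr_percent == pytest.approx(100.0)

    def test_zero_target_calls_rejected(self):
        panel = stqc.ProbePanel.from_genes(targets=["T1"], backgrounds=["B1"])
        with pytest.raises(ValueError, match="target"):
            stqc.global_fdr(_calls({"B1": 5}), panel)

    def test_invariant_to_record_order(self, rng):
        panel = stqc.ProbePanel.from_genes(targets=["T1", "T2"], backgrounds=["B1"])
        tt = _calls({"T1": 30, "T2": 10, "B1": 4}, rng)
        shuffled = stqc.TranscriptTable(
            tt.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        assert (
            stqc.global_fdr(tt, panel).fdr_percent
            == stqc.global_fdr(shuffled, panel).fdr_percent
        )


def _morans_oracle(values, pts):
    """Textbook O(n²) double sum with w_ij = 1/d_ij."""
    values = np.asarray(values, float)
    pts = np.asarray(pts, float)
    n = len(values)
    xbar = values.mean()
    num = wsum = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.hypot(*(pts[i] - pts[j]))
            w = 1.0 / d
            wsum += w
            num += w * (values[i] - xbar) * (values[j] - xbar)
    return n / wsum * num / ((values - xbar) ** 2).sum()


class TestMoransI:
    def test_n2_closed_form_minus_one(self):
        assert stqc.morans_i([1.0, 99.0], [[0, 0], [5, 5]]) == pytest.approx(-1.0)
        assert stqc.morans_i([2.0, 3.0], [[0, 0], [0.1, 0]]) == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [10, 100, 500])
    def test_matches_direct_double_sum(self, n, rng):
        pts = rng.uniform(0, 50, (n, 2))
        vals = rng.poisson(2.0, n).astype(float)
        while vals.std() == 0:
            vals = rng.poisson(2.0, n).astype(float)
        assert stqc.morans_i(vals, pts) == pytest.approx(
            _morans_oracle(vals, pts), rel=1e-10
        )

    def test_permutation_expectation(self, rng):
        n = 150
        pts = rng.uniform(0, 100, (n, 2))
        vals = rng.poisson(3.0, n).astype(float)
        perms = np.array(
            [stqc.morans_i(rng.permutation(vals), pts) for _ in range(200)]
        )
        se = perms.std(ddof=1) / np.sqrt(200)
        assert abs(perms.mean() - (-1.0 / (n - 1))) <= 3 * se

    def test_clustered_pattern_positive(self, rng):
        # tight cluster of high counts amid distant zeros
        pts = np.vstack([rng.uniform(0, 2, (10, 2)), rng.uniform(50, 100, (30, 2))])
        vals = np.array([10.0] * 10 + [0.0] * 30)
        i = stqc.morans_i(vals, pts)
        assert i > 0
        assert i == pytest.approx(_morans_oracle(vals, pts), rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stqc.morans_i([1.0, 1.0, 1.0], [[0, 0], [1, 0], [2, 0]])

    def test_coincident_centroids_named(self):
        with pytest.raises(ValueError, match="indices 0 and 2"):
            stqc.morans_i([1.0, 2.0, 3.0], [[0, 0], [1, 0], [0, 0]])


class TestScaleMorans:
    def test_affine_map(self):
        out = stqc.scale_morans(np.array([0.0, 0.5, 1.0]))
        assert out.tolist() == [0.0, 0.5, 1.0]

    def test_endpoints(self):
        out = stqc.scale_morans(np.array([-0.3, 0.1, 0.7]))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_order_preserved(self, rng):
        raw = rng.normal(size=20)
        out = stqc.scale_morans(raw)
        assert (np.argsort(out) == np.argsort(raw)).all()

    def test_degenerate(self):
        with pytest.raises(ValueError):
            stqc.scale_morans(np.array([0.5, 0.5]))


class TestMedianNnDistance:
    def test_pair(self):
        assert stqc.median_nn_distance([[0, 0], [3, 4]]) == pytest.approx(5.0)

    def test_square_lattice(self):
        s = 2.0
        xx, yy = np.meshgrid(np.arange(6) * s, np.arange(6) * s)
        pts = np.c_[xx.ravel(), yy.ravel()]
        assert stqc.median_nn_distance(pts) == pytest.approx(s)

    def test_poisson_closed_form(self, rng):
        # lambda = 1/µm²: median NN distance -> sqrt(ln 2 / pi) ~ 0.4697
        n = 5000
        side = np.sqrt(n)
        pts = rng.uniform(0, side, (n, 2))
        from scipy.spatial import cKDTree

        d = cKDTree(pts).query(pts, k=2)[0][:, 1]
        boot = np.array(
            [np.median(rng.choice(d, size=n)) for _ in range(200)]
        )
        se = boot.std(ddof=1)
        expected = np.sqrt(np.log(2) / np.pi)
        assert abs(stqc.median_nn_distance(pts) - expected) <= 3 * max(se, 1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            stqc.median_nn_distance([[0, 0]])


def _spec_table(nn, kinds, scaled=None, in_range=None):
    n = len(nn)
    return pd.DataFrame(
        {
            "gene_id": [f"P{i}" for i in range(n)],
            "kind": kinds,
            "total_count": [10] * n,
            "morans_i_scaled": scaled if scaled is not None else np.linspace(0, 1, n),
            "median_nn_distance": nn,
            "within_background_range": in_range if in_range is not None else [True] * n,
        }
    )


class TestClassifyProbeConfidence:
    def test_identical_nn_distances_no_flags(self):
        tab = _spec_table([5.0] * 8, ["background", "target"] * 4)
        out = classify_probe_confidence(tab, n_strata=2)
        assert not out["low_confidence"].any()

    def test_constructed_fixture_matches_quantile_oracle(self, rng):
        # one diffuse (large-NN) in-range target among clustered targets
        kinds = ["background"] * 8 + ["target"] * 4
        nn = list(rng.uniform(4.0, 5.0, 8)) + [0.5, 0.6, 0.7, 20.0]
        scaled = list(np.linspace(0, 1, 12))
        tab = _spec_table(nn, kinds, scaled=scaled)
        out = classify_probe_confidence(tab, n_strata=1, q=0.95)
        flagged = out.loc[out["low_confidence"], "gene_id"].tolist()
        threshold = np.quantile(nn[:8], 0.95)  # backgrounds only
        oracle = [
            f"P{i}" for i in range(8, 12) if nn[i] > threshold
        ]
        assert flagged == oracle == ["P11"]

    def test_count_gate_blocks_flag(self):
        kinds = ["background"] * 4 + ["target"]
        tab = _spec_table([1.0, 1.0, 1.0, 1.0, 50.0], kinds,
                          in_range=[True] * 4 + [False])
        out = classify_probe_confidence(tab, n_strata=1)
        assert not out["low_confidence"].any()

    def test_flags_monotone_in_q(self, rng):
        kinds = ["background"] * 10 + ["target"] * 10
        nn = list(rng.uniform(1, 10, 20))
        tab = _spec_table(nn, kinds, scaled=list(rng.uniform(0, 1, 20)))
        counts = [
            classify_probe_confidence(tab, n_strata=2, q=q)["low_confidence"].sum()
            for q in (0.05, 0.5, 0.95)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_insufficient_probes(self):
        tab = _spec_table([1.0, 2.0], ["background", "target"])
        with pytest.raises(ValueError, match="at least 4"):
            classify_probe_confidence(tab, n_strata=4)


class TestNuclearFraction:
    def _mask(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:, :5] = 1  # left half nuclear
        return stqc.SegmentationMask(labels, pixel_size=1.0)

    def test_all_inside(self):
        tt = _calls({"A": 20}, field=4.9)
        assert stqc.nuclear_fraction(tt, self._mask()) == 1.0

    def test_all_zero_mask(self):
        mask = stqc.SegmentationMask(np.zeros((10, 10), dtype=np.int32), 1.0)
        tt = _calls({"A": 20}, field=9.9)
        assert stqc.nuclear_fraction(tt, mask) == 0.0

    def test_seven_of_ten(self):
        x = [1.0] * 7 + [8.0] * 3
        tt = stqc.TranscriptTable.from_arrays(["A"] * 10, x, [5.0] * 10)
        assert stqc.nuclear_fraction(tt, self._mask()) == pytest.approx(0.7)

    def test_per_probe_and_empty(self):
        tt = stqc.TranscriptTable.from_arrays(
            ["A", "A", "B"], [1.0, 8.0, 1.0], [1.0, 1.0, 1.0]
        )
        per = stqc.nuclear_fraction(tt, self._mask(), per_probe=True)
        assert per["A"] == pytest.approx(0.5)
        assert per["B"] == pytest.approx(1.0)
        empty = stqc.TranscriptTable.from_arrays([], [], [])
        assert np.isnan(stqc.nuclear_fraction(empty, self._mask()))


class TestZHistogram:
    def _table(self, planes_counts):
        z = np.repeat(np.arange(len(planes_counts)), planes_counts).astype(float)
        n = len(z)
        return stqc.TranscriptTable.from_arrays(["A"] * n, np.zeros(n), np.zeros(n), z=z)

    def test_single_middle_plane_no_flag(self):
        counts, flag = stqc.z_histogram(self._table([0, 0, 0, 50, 0, 0, 0]), planes=7)
        assert counts.tolist() == [0, 0, 0, 50, 0, 0, 0]
        assert not flag

    def test_triangular_no_flag(self):
        counts, flag = stqc.z_histogram(self._table([1, 4, 7, 10, 7, 4, 1]), planes=7)
        assert not flag  # edges are 10% of the mode, below the 0.5 threshold

    def test_truncated_gaussian_flagged(self):
        # edge planes ~80% of the modal plane: the Merscope-style cut-off
        counts, flag = stqc.z_histogram(self._table([80, 90, 100, 95, 85, 82, 80]), planes=7)
        assert flag

    def test_non_integer_z_rejected(self):
        tt = stqc.TranscriptTable.from_arrays(["A"], [0.0], [0.0], z=[1.3])
        with pytest.raises(ValueError, match="plane"):
            stqc.z_histogram(tt, planes=7)


class TestBuildSpecificityTable:
    def test_on_simulated_tissue(self, small_tissue):
        tt, mask, panel, _ = small_tissue
        m, _ = stqc.assign_transcripts(tt, mask, panel, include_background=True)
        table = stqc.build_specificity_table(
            tt, panel, cell_counts=m.counts,
            centroids=m.centroids[["x", "y"]].to_numpy(),
        )
        assert set(table["gene_id"]) == set(panel.entries["gene_id"])
        bg = table[table["kind"] == "background"]
        # background probes: spatially random -> scaled Moran's I near the minimum
        assert bg["morans_i_scaled"].max() < 0.5
        # and NN distances consistent with the Poisson closed form
        area = 400.0 * 400.0
        for row in bg.itertuples(index=False):
            lam = row.total_count / area
            expected = np.sqrt(np.log(2) / (np.pi * lam))
            assert row.median_nn_distance == pytest.approx(expected, rel=0.15)
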