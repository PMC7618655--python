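import numpy as np
import pandas as pd
import pytest

from kneealign import io as kio
from kneealign.evaluation import (
    bland_altman,
    evaluate_run,
    icc_agreement,
    mad_agreement,
    p2c,
    p2p,
    reference_length,
    summarize_localization,
)
from kneealign.geometry import LandmarkSet
from kneealign.phantom import (
    PhantomRanges,
    default_curve_topology,
    generate_dataset,
    write_dataset,
)


def anova_icc21(x):
    """Brute-force ICC(2,1) from the two-way ANOVA decomposition."""
    n, k = x.shape
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * ((rows - grand) ** 2).sum() / (n - 1)
    msc = n * ((cols - grand) ** 2).sum() / (k - 1)
    mse = ((x - rows[:, None] - cols[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestP2P:
    def test_zero_for_identical(self, neutral_phantom):
        lm = neutral_phantom.landmarks
        assert np.all(p2p(lm, lm) == 0.0)

    def test_three_four_five(self, neutral_phantom):
        lm = neutral_phantom.landmarks
        arr = lm.as_array()
        arr[0] += (3.0, 4.0)
        moved = LandmarkSet.from_array(arr, lm.schema)
        d = p2p(moved, lm)
        assert d[0] == pytest.approx(5.0)
        assert np.all(d[1:] == 0.0)

    def test_matches_brute_force(self, neutral_phantom, rng):
        lm = neutral_phantom.landmarks
        jitter = rng.normal(size=(40, 2))
        moved = LandmarkSet.from_array(lm.as_array() + jitter, lm.schema)
        ours = p2p(moved, lm)
        ref = np.array(
            [np.sqrt(dx * dx + dy * dy) for dx, dy in jitter]
        )
        assert np.abs(ours - ref).max() <= 1e-12


class TestP2C:
    def test_zero_on_polyline(self, neutral_phantom):
        lm = neutral_phantom.landmarks
        d = p2c(lm, lm, default_curve_topology())
        assert np.all(d <= 1e-9)

    def test_tangent_slide_gives_zero_p2c_nonzero_p2p(self, neutral_phantom):
        lm = neutral_phantom.landmarks
        topo = default_curve_topology()
        # slide a mid-edge femur landmark along its (straight) boundary
        arr = lm.as_array()
        idx = 4  # interior of the femur left edge polyline
        prev_pt, next_pt = arr[2], arr[6]
        tangent = (next_pt - prev_pt) / np.linalg.norm(next_pt - prev_pt)
        arr[idx] = arr[idx] + 3.0 * tangent
        moved = LandmarkSet.from_array(arr, lm.schema)
        assert p2p(moved, lm)[idx] > 2.9
        assert p2c(moved, lm, topo)[idx] <= 0.05  # edge is straight by construction

    def test_matches_dense_sampling(self, neutral_phantom, rng):
        lm = neutral_phantom.landmarks
        topo = default_curve_topology()
        moved = LandmarkSet.from_array(
            lm.as_array() + rng.normal(scale=2.0, size=(40, 2)), lm.schema
        )
        ours = p2c(moved, lm, topo)
        gt_arr = lm.as_array()
        membership = {}
        for ci, curve in enumerate(topo):
            for i in curve:
                membership.setdefault(i, []).append(ci)
        pred = moved.as_array()
        for i in range(40):
            best = np.inf
            for ci in membership[i]:
                curve = topo[ci]
                for a, b in zip(curve[:-1], curve[1:]):
                    ts = np.linspace(0, 1, 10_000)[:, None]
                    seg = gt_arr[a] + ts * (gt_arr[b] - gt_arr[a])
                    best = min(best, np.linalg.norm(seg - pred[i], axis=1).min())
            assert abs(ours[i] - best) <= 1e-3

    def test_index_off_topology_rejected(self, neutral_phantom):
        lm = neutral_phantom.landmarks
        with pytest.raises(ValueError, match="not on any curve"):
            p2c(lm, lm, [[0, 1, 2]])

    def test_p2c_never_exceeds_p2p(self, neutral_phantom, rng):
        lm = neutral_phantom.landmarks
        topo = default_curve_topology()
        for _ in range(10):
            moved = LandmarkSet.from_array(
                lm.as_array() + rng.normal(scale=3.0, size=(40, 2)), lm.schema
            )
            assert np.all(p2c(moved, lm, topo) <= p2p(moved, lm) + 1e-9)


class TestReferenceLength:
    def test_horizontal_corners(self, neutral_phantom):
        lm = neutral_phantom.landmarks
        arr = lm.as_array()
        arr[lm.schema.index("plateau_corner_left")] = (0.0, 0.0)
        arr[lm.schema.index("plateau_corner_right")] = (30.0, 0.0)
        assert reference_length(LandmarkSet.from_array(arr, lm.schema)) == 30.0

    def test_coincident_corners_rejected(self, neutral_phantom):
        lm = neutral_phantom.landmarks
        arr = lm.as_array()
        left = lm.schema.index("plateau_corner_left")
        arr[left] = arr[lm.schema.index("plateau_corner_right")]
        with pytest.raises(ValueError, match="zero reference"):
            reference_length(LandmarkSet.from_array(arr, lm.schema))


class TestSummarize:
    def test_constant_values(self):
        s = summarize_localization([3.0] * 10)
        assert s == {"mean": 3.0, "median": 3.0, "p95": 3.0}

    def test_one_to_hundred(self):
        s = summarize_localization(np.arange(1.0, 101.0))
        assert s["median"] == pytest.approx(50.5)
        assert s["p95"] == pytest.approx(95.05)

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(0, 10, 50)
        shuffled = rng.permutation(vals)
        assert summarize_localization(vals) == summarize_localization(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_localization([])


class TestICC:
    def test_perfect_agreement(self, rng):
        a = rng.uniform(-10, 10, 20)
        icc, ci, defined = icc_agreement(a, a)
        assert defined
        assert icc == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_penalized(self, rng):
        a = rng.uniform(-10, 10, 200)
        icc, _, _ = icc_agreement(a, a + 3.0)
        assert icc < 1.0

    @pytest.mark.parametrize("n", [6, 10])
    def test_matches_anova_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(-8, 8, n)
        b = a + rng.normal(0, 1.5, n)
        icc, _, _ = icc_agreement(a, b)
        assert icc == pytest.approx(anova_icc21(np.column_stack([a, b])), abs=1e-9)

    @pytest.mark.parametrize("n", [6, 10])
    def test_matches_pingouin(self, n):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(100 + n)
        a = rng.uniform(-8, 8, n)
        b = a + rng.normal(0, 1.5, n)
        icc, ci, _ = icc_agreement(a, b)
        df = pd.DataFrame(
            {
                "target": list(range(n)) * 2,
                "rater": ["a"] * n + ["b"] * n,
                "score": np.concatenate([a, b]),
            }
        )
        ref = pingouin.intraclass_corr(df, "target", "rater", "score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds the CI bounds to two decimals
        assert ci[0] == pytest.approx(row["CI95"][0], abs=0.02)
        assert ci[1] == pytest.approx(row["CI95"][1], abs=0.02)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            icc_agreement([1, 2], [1, 2])

    def test_zero_variance_flagged(self):
        icc, ci, defined = icc_agreement([2.0] * 5, [2.0] * 5)
        assert not defined
        assert np.isnan(icc)


class TestMadAndBlandAltman:
    def test_mad_identical(self):
        mad, sd = mad_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (mad, sd) == (0.0, 0.0)

    def test_mad_plus_minus_one(self):
        mad, sd = mad_agreement([1.0, -1.0], [0.0, 0.0])
        assert mad == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_mad_scale_equivariance(self, rng):
        a = rng.uniform(0, 10, 30)
        b = a + rng.normal(0, 1, 30)
        mad1, sd1 = mad_agreement(a, b)
        mad2, sd2 = mad_agreement(3 * a, 3 * b)
        assert mad2 == pytest.approx(3 * mad1)
        assert sd2 == pytest.approx(3 * sd1)

    def test_mad_matches_direct_formula(self, rng):
        a = rng.uniform(-5, 5, 40)
        b = a + rng.normal(0, 2, 40)
        mad, sd = mad_agreement(a, b)
        diff = np.abs(a - b)
        assert abs(mad - diff.mean()) <= 1e-12
        assert abs(sd - diff.std(ddof=1)) <= 1e-12

    def test_bias_of_identical_series(self):
        bias, sd, loa = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert bias == 0.0 and sd == 0.0

    def test_constant_shift_bias(self, rng):
        a = rng.uniform(0, 10, 25)
        bias, _, _ = bland_altman(a, a - 0.5)
        assert bias == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        a = rng.uniform(-5, 5, 40)
        b = a + rng.normal(0, 2, 40)
        bias, sd, loa = bland_altman(a, b)
        diff = a - b
        assert abs(bias - diff.mean()) <= 1e-12
        assert abs(sd - diff.std(ddof=1)) <= 1e-12
        assert loa == pytest.approx((bias - 1.96 * sd, bias + 1.96 * sd))

    def test_bias_antisymmetry(self, rng):
        a = rng.uniform(0, 10, 15)
        b = rng.uniform(0, 10, 15)
        assert bland_altman(a, b)[0] == -bland_altman(b, a)[0]

    def test_plot_written(self, rng, tmp_path):
        a = rng.uniform(0, 10, 15)
        out = tmp_path / "ba.png"
        bland_altman(a, a + rng.normal(0, 1, 15), plot_path=out)
        assert out.exists() and out.stat().st_size > 0


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    root = tmp_path_factory.mktemp("run")
    samples = generate_dataset(25, PhantomRanges(atfa=(-12, 12)), seed=31)
    manifest_path = write_dataset(samples, root / "gt")
    manifest = kio.Manifest.read(manifest_path)
    return root, samples, manifest


class TestEvaluateRun:
    def test_perfect_predictions(self, small_run):
        root, samples, manifest = small_run
        pred_dir = root / "perfect"
        pred_dir.mkdir()
        for i, s in enumerate(samples):
            kio.write_pts(pred_dir / f"phantom_{i:04d}.pts", s.landmarks)
        loc, agree, scores = evaluate_run(manifest, pred_dir)
        assert loc.loc[loc.metric == "rP2P", "mean"].iloc[0] <= 1e-6
        for _, row in agree.iterrows():
            assert row["icc"] == pytest.approx(1.0, abs=1e-9)
            assert row["mad"] == pytest.approx(0.0, abs=1e-9)
            assert row["baa_bias"] == pytest.approx(0.0, abs=1e-9)

    def test_jittered_predictions_match_expected_rp2p(self, small_run):
        root, samples, manifest = small_run
        pred_dir = root / "jitter"
        pred_dir.mkdir()
        sigma = 1.0
        jrng = np.random.default_rng(77)
        for i, s in enumerate(samples):
            arr = s.landmarks.as_array() + jrng.normal(0, sigma, size=(40, 2))
            kio.write_pts(
                pred_dir / f"phantom_{i:04d}.pts",
                LandmarkSet.from_array(arr, s.landmarks.schema),
            )
        _, _, scores = evaluate_run(manifest, pred_dir)
        expected_p2p = sigma * np.sqrt(np.pi / 2)  # E|N2(0, sigma^2 I)|
        expected_rp2p = 100 * expected_p2p / scores.reference_lengths.mean()
        assert scores.rp2p.mean() == pytest.approx(expected_rp2p, rel=0.1)
        assert np.all(scores.rp2c <= scores.rp2p + 1e-9)

    def test_deterministic_rerun(self, small_run):
        root, samples, manifest = small_run
        pred_dir = root / "perfect"
        t1 = evaluate_run(manifest, pred_dir)[0]
        t2 = evaluate_run(manifest, pred_dir)[0]
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_predictions_skipped(self, small_run, caplog):
        import logging

        root, samples, manifest = small_run
        pred_dir = root / "partial"
        pred_dir.mkdir()
        for i, s in enumerate(samples[:10]):
            kio.write_pts(pred_dir / f"phantom_{i:04d}.pts", s.landmarks)
        with caplog.at_level(logging.WARNING):
            _, agree, scores = evaluate_run(manifest, pred_dir)
        assert len(scores.rp2p) == 10
        assert any("missing" in rec.message for rec in caplog.records)

    def test_output_files_written(self, small_run, tmp_path):
        root, samples, manifest = small_run
        evaluate_run(manifest, root / "perfect", out_dir=tmp_path)
        assert (tmp_path / "localization.csv").exists()
        assert (tmp_path / "agreement.csv").exists()
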