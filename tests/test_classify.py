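"""Linear OvR SVM: training contracts, fold-contained LOOCV, ROC/AUC, maps.

Independent oracles: simulation with well-separated Gaussian clouds,
exhaustive concordant-pair AUC counting, and direct recomputation of
fold-training means for the scaler-containment audit.
"""

import numpy as np
import pytest

from octseg.classify import (
    CLASSES,
    SegmentationMap,
    TrainedModel,
    loocv,
    multiclass_roc,
    render_segmentation,
    segment,
    train,
)
from octseg.features import FeatureBlock
from octseg.io import BScan
from octseg.parametric import compute_maps
from octseg.simulate import ScanLayout, TissueModel, simulate_bscan


def cloud_blocks(rng, centers, n=100, sd=1.0, scan_prefix="s"):
    """Gaussian clouds in (OAC, RSC) space, one scan of blocks per class."""
    blocks = []
    for label, (cx, cy) in centers.items():
        for k in range(n):
            x, y = rng.normal(cx, sd), rng.normal(cy, sd)
            blocks.append(FeatureBlock(f"{scan_prefix}_{label}", k, (20 * k, 20 * k + 20), x, y, label))
    return blocks


def pair_count_auc(scores, positive):
    """Exhaustive concordant-pair AUC with half credit for ties."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    total = concordant = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                concordant += 1
            elif sp == sn:
                concordant += 0.5
    return concordant / total


class TestTrain:
    def test_separated_clouds_reach_high_training_accuracy(self, rng):
        # 4 pooled SDs between means -> Bayes error < 0.003
        blocks = cloud_blocks(rng, {"Normal": (0, 0), "Tumor": (4, 4)})
        model = train(blocks)
        X = np.array([[b.mean_oac, b.mean_rsc] for b in blocks])
        y = [b.label for b in blocks]
        acc = np.mean([p == t for p, t in zip(model.predict(X), y)])
        assert acc >= 0.99

    def test_scaler_standardises_training_features(self, training_blocks):
        model = train(training_blocks)
        X = np.array([[b.mean_oac, b.mean_rsc] for b in training_blocks if b.valid])
        z = (X - model.scaler_mean) / model.scaler_scale
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_duplicating_every_point_keeps_the_boundary(self, rng):
        # duplicating the data doubles the hinge-loss term, so the same
        # objective (and boundary) is recovered at half the box penalty C
        blocks = cloud_blocks(rng, {"Normal": (0, 0), "Tumor": (4, 4)})
        m1 = train(blocks, C=1.0, tol=1e-10)
        m2 = train(blocks + blocks, C=0.5, tol=1e-10)
        np.testing.assert_allclose(m2.coef, m1.coef, atol=1e-6)
        np.testing.assert_allclose(m2.intercept, m1.intercept, atol=1e-6)

    def test_single_class_is_error(self, rng):
        blocks = cloud_blocks(rng, {"Tumor": (0, 0)})
        with pytest.raises(ValueError, match="2 tissue classes"):
            train(blocks)

    def test_zero_variance_feature_is_error_naming_the_feature(self):
        blocks = [
            FeatureBlock("s", k, (0, 20), 1.0, 0.1 * k, "Normal" if k < 5 else "Tumor")
            for k in range(10)
        ]
        with pytest.raises(ValueError, match="mean_oac"):
            train(blocks)

    def test_model_json_roundtrip_and_determinism(self, training_blocks, tmp_path):
        m1 = train(training_blocks)
        m2 = train(training_blocks)
        assert m1.to_json() == m2.to_json()  # bit-identical manifest
        m1.save(tmp_path / "model.json")
        m3 = TrainedModel.load(tmp_path / "model.json")
        np.testing.assert_array_equal(m3.coef, m1.coef)
        np.testing.assert_array_equal(m3.scaler_mean, m1.scaler_mean)


class TestLoocv:
    def test_per_scan_grouping_gives_one_fold_per_scan(self, training_blocks):
        res = loocv(training_blocks)
        assert len(set(res.groups)) == 23
        assert len(res.predicted) == 460
        assert all(p is not None for p in res.predicted)

    def test_per_block_grouping_gives_n_folds(self, rng):
        blocks = cloud_blocks(rng, {"Normal": (0, 0), "Tumor": (4, 4)}, n=10)
        res = loocv(blocks, grouping="per_block")
        assert len(set(res.groups)) == 20

    def test_perfectly_separable_groups_reach_accuracy_one(self, rng):
        blocks = []
        for i, label in enumerate(["Normal", "Tumor", "Normal", "Tumor", "Normal", "Tumor"]):
            c = 0.0 if label == "Normal" else 6.0
            for k in range(5):
                blocks.append(
                    FeatureBlock(f"scan{i}", k, (0, 20), rng.normal(c, 0.3), rng.normal(c, 0.3), label)
                )
        res = loocv(blocks)
        assert res.accuracy == 1.0

    def test_fold_losing_a_class_is_refused(self, rng):
        blocks = []
        for scan_id, label, c in [("a", "Normal", 0.0), ("b", "Normal", 0.0), ("c", "Tumor", 4.0)]:
            for k in range(5):
                blocks.append(
                    FeatureBlock(scan_id, k, (0, 20), rng.normal(c, 0.5), rng.normal(c, 0.5), label)
                )
        # all Tumor blocks live in scan "c" -> its fold has no Tumor remainder
        with pytest.raises(ValueError, match="loses class"):
            loocv(blocks, grouping="per_scan")

    def test_scaler_fold_containment_audit(self, rng):
        """Each fold model's stored scaler means equal that fold's
        training-feature means exactly (recomputed independently)."""
        blocks = cloud_blocks(rng, {"Normal": (0, 0), "Tumor": (4, 4)}, n=6, scan_prefix="a")
        for b in blocks[::2]:
            b.scan_id = b.scan_id + "_even"  # split each class over two scans
        res = loocv(blocks, keep_fold_models=True)
        groups = np.array(res.groups)
        for g, model in zip(dict.fromkeys(res.groups), res.fold_models):
            X_train = np.array(
                [[b.mean_oac, b.mean_rsc] for b, grp in zip(res.blocks, groups) if grp != g]
            )
            np.testing.assert_allclose(model.scaler_mean, X_train.mean(axis=0), rtol=1e-12)

    def test_permuted_labels_fall_to_chance(self, rng):
        blocks = cloud_blocks(rng, {"Normal": (0, 0), "Tumor": (0.1, 0.1)}, n=40)
        labels = [b.label for b in blocks]
        rng.shuffle(labels)
        for b, lab in zip(blocks, labels):
            b.label = lab
        res = loocv(blocks, grouping="per_block")
        majority = max(labels.count("Normal"), labels.count("Tumor")) / len(labels)
        # no-signal null: accuracy within binomial noise of the majority rate
        assert res.accuracy <= majority + 3 * np.sqrt(0.25 / len(blocks))


class TestRoc:
    def test_perfect_ordering_gives_auc_one(self):
        tumor_scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["Normal", "Normal", "Tumor", "Tumor"])
        scores = np.column_stack([-tumor_scores, np.zeros(4), tumor_scores])
        out = multiclass_roc(scores, labels)
        assert out["Tumor"]["auc"] == 1.0
        assert out["tumor_vs_rest"]["auc"] == 1.0

    def test_pair_counting_oracle_on_four_points(self):
        # (0.1-, 0.4+, 0.45-, 0.8+): one discordant pair of four -> 0.75
        labels = np.array(["Normal", "Tumor", "Normal", "Tumor"])
        tumor_scores = np.array([0.1, 0.4, 0.45, 0.8])
        scores = np.column_stack([-tumor_scores, np.zeros(4), tumor_scores])
        out = multiclass_roc(scores, labels)
        assert out["Tumor"]["auc"] == pytest.approx(0.75)
        assert pair_count_auc(tumor_scores, labels == "Tumor") == 0.75
        # (0.1-, 0.4+, 0.35-, 0.8+): all four pairs concordant -> 1.0
        t2 = np.array([0.1, 0.4, 0.35, 0.8])
        out2 = multiclass_roc(np.column_stack([-t2, np.zeros(4), t2]), labels)
        assert out2["Tumor"]["auc"] == 1.0

    def test_sweep_auc_equals_pair_counting_on_random_instances(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 50))
            labels = np.array(["Tumor" if v else "Normal" for v in rng.random(n) < 0.5])
            if len(set(labels)) < 2:
                continue
            # discrete score grid to exercise ties
            tumor_scores = rng.integers(0, 6, n).astype(float)
            scores = np.column_stack([-tumor_scores, np.zeros(n), tumor_scores])
            out = multiclass_roc(scores, labels)
            expected = pair_count_auc(tumor_scores, labels == "Tumor")
            assert out["Tumor"]["auc"] == pytest.approx(expected, abs=1e-12)

    def test_label_independent_scores_hover_near_half(self, rng):
        n = 4000
        labels = np.array(["Tumor" if v else "Normal" for v in rng.random(n) < 0.5])
        scores = rng.random((n, 3))
        out = multiclass_roc(scores, labels)
        assert abs(out["Tumor"]["auc"] - 0.5) < 0.05

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError, match="single class"):
            multiclass_roc(np.zeros((5, 3)), np.array(["Tumor"] * 5))


@pytest.fixture(scope="module")
def model(training_blocks):
    return train(training_blocks)


class TestSegment:
    def test_all_normal_scan_is_all_green(self, model, tissue):
        scan, _ = simulate_bscan(ScanLayout.homogeneous("Normal", 400), tissue, seed=21)
        maps = compute_maps(scan, noise_reference=tissue.noise_level)
        segmap = segment(maps, model)
        assert segmap.n_blocks == 20
        assert all(lab == "Normal" for lab in segmap.labels)

    def test_tumor_insert_blocks_turn_red(self, model, tissue):
        layout = ScanLayout.infiltration(width=400, start=100, length=100)  # blocks 5..9
        scan, _ = simulate_bscan(layout, tissue, seed=22)
        maps = compute_maps(scan, noise_reference=tissue.noise_level)
        segmap = segment(maps, model, truth="Tumor")
        assert segmap.labels[5:10] == ["Tumor"] * 5
        assert all(lab == "Normal" for lab in segmap.labels[:5] + segmap.labels[10:])

    def test_feature_dimension_mismatch_is_error(self, model):
        with pytest.raises(ValueError, match="features"):
            model.decision_function(np.ones((3, 4)))

    def test_render_alternating_blocks_stripe_colors(self):
        labels = ["Normal", "Tumor"] * 5 + [None]
        segmap = SegmentationMap(scan_id="r", labels=labels, block_width=20)
        scan = BScan(intensity=np.ones((64, 220)))
        img = render_segmentation(segmap, scan)
        assert img.shape == (64, 220, 3)
        green = img[32, 10].astype(int)
        red = img[32, 30].astype(int)
        gray = img[32, 210].astype(int)
        assert green[1] > green[0] and green[1] > green[2]
        assert red[0] > red[1] and red[0] > red[2]
        assert abs(int(gray[0]) - int(gray[1])) < 10  # neutral stripe for missing block
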