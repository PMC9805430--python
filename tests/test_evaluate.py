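"""En-face aggregation, Otsu binarization, metrics, cross-validation."""

import math

import numpy as np
import pytest

from octreveng import evaluate as ev
from octreveng.evaluate import (ConfusionCounts, aggregate_enface,
                                compute_metrics, confusion, dice_score,
                                make_folds, otsu_thresholds,
                                select_binarization)


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------

def confusion_loop_oracle(pred, truth):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and truth[i, j]:
                tp += 1
            elif pred[i, j] and not truth[i, j]:
                fp += 1
            elif not pred[i, j] and truth[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def between_class_variance(counts, centers, cuts):
    """Between-class variance of the binned data for cut points ``cuts``
    (bin indices: class c = bins cuts[c-1]..cuts[c]-1)."""
    total = counts.sum()
    bounds = [0, *cuts, len(counts)]
    mu_all = (counts * centers).sum() / total
    v = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        w = counts[lo:hi].sum()
        if w:
            mu = (counts[lo:hi] * centers[lo:hi]).sum() / w
            v += (w / total) * (mu - mu_all) ** 2
    return v


def otsu_brute_force_objective(values, n_classes, nbins):
    """Exhaustive search over all histogram cut points: the maximal
    between-class variance (the multi-Otsu criterion)."""
    counts, edges = np.histogram(values, bins=nbins,
                                 range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best = -1.0
    if n_classes == 2:
        for t in range(1, nbins):
            best = max(best, between_class_variance(counts, centers, (t,)))
    else:
        for t1 in range(1, nbins - 1):
            for t2 in range(t1 + 1, nbins):
                best = max(best,
                           between_class_variance(counts, centers, (t1, t2)))
    return best, counts, centers


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------

class TestAggregateEnface:
    def test_constant_maps(self):
        maps = [np.full((16, 8), 0.3)] * 4
        out = aggregate_enface(maps, out_size=64)
        assert out.shape == (64, 64)
        assert np.allclose(out, 0.3, atol=1e-6)

    def test_single_positive_bscan_forms_band(self):
        maps = [np.zeros((16, 8)) for _ in range(8)]
        maps[3] = np.ones((16, 8))
        out = aggregate_enface(maps, out_size=64)
        band = out[:, 24:32]   # depth index 3 of 8 -> columns 24..31
        assert band.mean() > 0.7      # bilinear ramps soften the edges
        assert out.max() == pytest.approx(band.max())
        assert band.mean() > 3 * np.delete(out, np.s_[16:40], axis=1).mean()

    def test_truth_round_trip_dice(self):
        """Extruded truth pushed through the aggregation + 0.5 threshold
        must recover the registered en-face truth almost exactly (at the
        pipeline's 512 x 128 en-face working grid)."""
        from octreveng.label_transform import (extrude_label,
                                               register_annotation,
                                               resize_nearest)
        from octreveng.phantom import PhantomSpec, generate_phantom
        case = generate_phantom(PhantomSpec(volume_shape=(64, 512, 128),
                                            seed=77))
        reg = register_annotation(case.followup_ga_mask, case.keypoints)
        w, d = case.layers.ilm_row.shape
        stack = extrude_label(resize_nearest(reg, (w, d)),
                              case.layers.boundaries(),
                              case.oct.shape)
        # feed per-B-scan truth masks as probabilities, normalized per
        # column band so a positive column aggregates to 1
        probs = []
        for k in range(d):
            m = stack[:, :, k].astype(float)
            col = m.sum(axis=0, keepdims=True)
            probs.append(np.divide(m * m.shape[0], np.maximum(col, 1)))
        enface = aggregate_enface(probs) > 0.5
        assert dice_score(enface, reg) >= 0.95

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no probability"):
            aggregate_enface([])


class TestOtsu:
    def test_bimodal_threshold_interior(self, rng):
        vals = np.concatenate([np.full(50, 0.1), np.full(50, 0.9)])
        vals += rng.normal(scale=1e-3, size=100)
        (t,) = otsu_thresholds(vals.reshape(10, 10), 2)
        assert 0.1 < t < 0.9

    def test_three_modes(self, rng):
        vals = np.concatenate([np.full(60, 0.1), np.full(60, 0.5),
                               np.full(60, 0.9)])
        vals += rng.normal(scale=1e-3, size=180)
        t1, t2 = otsu_thresholds(vals.reshape(18, 10), 3)
        assert 0.1 < t1 < 0.5 < t2 < 0.9
        assert t1 < t2

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_thresholds(np.full((8, 8), 0.5), 2)

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_matches_brute_force(self, n_classes):
        """The returned thresholds achieve exactly the maximal between-class
        variance found by exhaustive search over all histogram cut points."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            vals = np.concatenate([
                rng.normal(0.2, 0.05, 150),
                rng.normal(0.55, 0.05, 100),
                rng.normal(0.85, 0.04, 80)]).clip(0, 1).reshape(-1)
            got = otsu_thresholds(vals, n_classes, nbins=64)
            best, counts, centers = otsu_brute_force_objective(vals, n_classes,
                                                               nbins=64)
            cuts = tuple(int(np.searchsorted(centers, t, side="right"))
                         for t in got)
            achieved = between_class_variance(counts, centers, cuts)
            assert achieved >= best - 1e-12 * max(1.0, best)


class TestSelectBinarization:
    def test_binary_map_ties_to_two_class(self):
        truth = np.zeros((32, 32), dtype=bool)
        truth[8:16, 8:16] = True
        mask, mode = select_binarization(truth.astype(float), truth)
        assert mode == "otsu2"
        assert np.array_equal(mask, truth)

    def test_never_worse_than_either_candidate(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            emap = np.clip(r.normal(0.2, 0.1, (64, 64)) +
                           0.6 * (r.random((64, 64)) > 0.9), 0, 1)
            truth = r.random((64, 64)) > 0.85
            mask, _ = select_binarization(emap, truth)
            d2 = dice_score(emap > otsu_thresholds(emap, 2)[0], truth)
            d3 = dice_score(emap > otsu_thresholds(emap, 3)[1], truth)
            assert dice_score(mask, truth) >= max(d2, d3) - 1e-12

    def test_empty_truth_dice_convention(self, rng):
        """Empty-vs-empty Dice is 1, any positives against empty truth give
        0, so on empty truths nonempty candidates tie and the 2-class
        threshold is kept."""
        assert dice_score(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0
        some = np.zeros((4, 4), dtype=bool)
        some[0, 0] = True
        assert dice_score(some, np.zeros((4, 4), bool)) == 0.0
        emap = np.clip(rng.normal(0.3, 0.08, (64, 64)), 0, 1)
        truth = np.zeros((64, 64), dtype=bool)
        mask, mode = select_binarization(emap, truth)
        assert mode == "otsu2"
        assert np.array_equal(mask, emap > otsu_thresholds(emap, 2)[0])


class TestConfusionAndMetrics:
    def test_perfect_prediction(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[:3] = True
        c = confusion(truth, truth)
        assert (c.tp, c.fp, c.fn) == (30, 0, 0) and c.tn == 70
        m = compute_metrics(c)
        assert (m.accuracy, m.sensitivity, m.specificity, m.overlap) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_complement_prediction(self):
        truth = np.zeros((4, 4), dtype=bool)
        truth[0] = True
        c = confusion(~truth, truth)
        assert c.tp == 0 and c.tn == 0

    def test_matches_loop_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            pred = rng.random((16, 16)) > rng.uniform(0.2, 0.8)
            truth = rng.random((16, 16)) > rng.uniform(0.2, 0.8)
            c = confusion(pred, truth)
            assert (c.tp, c.fp, c.tn, c.fn) == tuple(
                confusion_loop_oracle(pred, truth)[i] for i in (0, 1, 2, 3))
            assert c.total == 256

    def test_hand_example(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.overlap == pytest.approx(0.6)
        assert m.tp_fraction == pytest.approx(0.3)

    def test_undefined_ratios_are_nan(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert math.isnan(m.sensitivity)
        assert math.isnan(m.overlap)
        assert m.specificity == 1.0

    def test_accuracy_error_identity(self, rng):
        for _ in range(20):
            pred = rng.random((8, 8)) > 0.5
            truth = rng.random((8, 8)) > 0.5
            c = confusion(pred, truth)
            m = compute_metrics(c)
            assert m.accuracy == pytest.approx(1 - (c.fp + c.fn) / c.total)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), bool), np.zeros((2, 3), bool))


class TestFolds:
    def test_partition_properties(self):
        folds = make_folds(22, 8, seed=3)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        flat = sorted(i for f in folds for i in f)
        assert flat == list(range(22))

    def test_too_many_folds(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds(3, 8, seed=0)


@pytest.fixture(scope="module")
def tiny_cases():
    """Four near-identical trivially learnable cases: bright band in a
    fixed region, truth = that region."""
    r = np.random.default_rng(5)
    cases = []
    for i in range(4):
        bscans, masks = [], []
        for _ in range(4):
            b = (r.random((32, 32)) * 0.2).astype(np.float32)
            b[:, 10:20] += 0.7
            m = np.zeros((32, 32), dtype=bool)
            m[:, 10:20] = True
            bscans.append(b)
            masks.append(m)
        # en-face rows correspond to the B-scan width axis
        truth = np.zeros((512, 512), dtype=bool)
        truth[160:320, :] = True
        cases.append(ev.PreparedCase(case_id=f"c{i}", bscans=bscans,
                                     truth_masks=masks, enface_truth=truth))
    return cases


class TestCrossvalidate:
    def test_symmetric_folds_agree(self, tiny_cases):
        from octreveng.segnet import UNetConfig
        cfg = UNetConfig(depth=2, base_channels=8, in_shape=(32, 32),
                         learning_rate=3e-3, epochs=30, batch_size=4, seed=1)
        cv = ev.crossvalidate(tiny_cases, cfg, k=2, seed=0)
        a, b = [fr.report for fr in cv.fold_results]
        assert a.accuracy > 0.9 and b.accuracy > 0.9
        assert abs(a.accuracy - b.accuracy) < 0.05
        # combined equals the mean over per-case rows, recomputed
        rows = cv.per_case_rows
        assert cv.combined.accuracy == pytest.approx(
            np.mean([r["accuracy"] for r in rows]))
        assert cv.combined.overlap == pytest.approx(
            np.mean([r["overlap"] for r in rows]))

    def test_k_larger_than_cases_rejected(self, tiny_cases):
        from octreveng.segnet import UNetConfig
        cfg = UNetConfig(depth=2, base_channels=4, in_shape=(32, 32))
        with pytest.raises(ValueError, match="folds"):
            ev.crossvalidate(tiny_cases, cfg, k=8, seed=0)
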