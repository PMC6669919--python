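"""Segmentation, enrichment ratio, foci counting and categorization,
checked against planted ground truth and brute-force tallies."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbquant import bodies, simgen
from nbquant.bodies import (
    DEFAULT_BINS,
    LabelMap,
    categorize_counts,
    classify_positive_cells,
    count_foci,
    enrichment,
    segment_bodies,
    segment_nuclei,
)
from nbquant.stack import disk_mask


def _match_centroids(found: dict, truth, tol_px=2.0):
    """Greedy one-to-one matching of detected centroids to planted ones."""
    truth_pts = [(b.cx, b.cy) for b in truth]
    used = set()
    tp = 0
    for cx, cy in found.values():
        best, best_d = None, tol_px
        for i, (tx, ty) in enumerate(truth_pts):
            if i in used:
                continue
            d = np.hypot(cx - tx, cy - ty)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            tp += 1
    return tp


class TestSegmentNuclei:
    def test_planted_disjoint_nuclei_all_found(self):
        params = simgen.SimFieldParams(n_nuclei=10, bodies_per_nucleus_mean=0.0, seed=2)
        field = simgen.make_field(params)
        labels = segment_nuclei(field.channels["nuclei"])
        assert labels.n_labels == 10

    def test_blank_image_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="blank"):
            labels = segment_nuclei(np.zeros((64, 64)))
        assert labels.n_labels == 0

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((128, 128))
        img[disk_mask(img.shape, 45.0, 64.0, 22.0)] = 200.0
        img[disk_mask(img.shape, 85.0, 64.0, 22.0)] = 200.0
        labels = segment_nuclei(img, min_distance_px=15)
        assert labels.n_labels == 2


class TestSegmentBodies:
    def test_perfect_recall_precision_on_strong_field(self):
        field = simgen.make_field(simgen.SimFieldParams(seed=4))
        nuclei = segment_nuclei(field.channels["nuclei"])
        found = segment_bodies(field.channels["bodies"], nuclei)
        cents = found.centroids()
        tp = _match_centroids(cents, field.truth.bodies)
        assert tp == len(field.truth.bodies) == len(cents)

    def test_uniform_nucleoplasm_yields_no_bodies(self):
        field = simgen.make_field(
            simgen.SimFieldParams(bodies_per_nucleus_mean=0.0, n_nuclei=4, seed=5)
        )
        nuclei = segment_nuclei(field.channels["nuclei"])
        found = segment_bodies(field.channels["bodies"], nuclei)
        assert found.n_labels == 0

    def test_body_outside_nucleus_discarded(self):
        shape = (96, 96)
        nuc_labels = np.zeros(shape, dtype=np.int32)
        nuc_labels[disk_mask(shape, 30.0, 30.0, 20.0)] = 1
        img = np.full(shape, 100.0)
        img[disk_mask(shape, 30.0, 30.0, 20.0)] = 100.0
        img[disk_mask(shape, 75.0, 75.0, 3.0)] = 800.0  # bright spot outside nucleus
        found = segment_bodies(img, LabelMap(nuc_labels, "nuclei"))
        assert found.n_labels == 0


class TestEnrichment:
    @staticmethod
    def _toy_maps():
        shape = (80, 80)
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[5:75, 5:75] = 1
        bod = np.zeros(shape, dtype=np.int32)
        coords = [(20, 20), (20, 55), (55, 20), (55, 55)]
        for i, (y, x) in enumerate(coords, start=1):
            bod[y : y + 5, x : x + 5] = i
        return LabelMap(nuc, "nuclei"), LabelMap(bod, "bodies", parents={i: 1 for i in range(1, 5)})

    def test_uniform_channel_gives_unit_ratio(self):
        nuclei, bmap = self._toy_maps()
        res = enrichment(bmap, nuclei, np.full((80, 80), 120.0))
        assert all(r.ratio == pytest.approx(1.0) for r in res.records)
        assert res.fraction_enriched == 0.0

    def test_threshold_counting(self):
        nuclei, bmap = self._toy_maps()
        img = np.ones((80, 80))
        for bid, val in zip((1, 2, 3, 4), (1.0, 1.6, 2.0, 1.4)):
            img[bmap.labels == bid] = val
        res = enrichment(bmap, nuclei, img, threshold=1.5)
        ratios = sorted(r.ratio for r in res.records)
        assert ratios == pytest.approx([1.0, 1.4, 1.6, 2.0])
        assert res.fraction_enriched == pytest.approx(0.5)

    def test_planted_enrichment_recovered_noiseless(self):
        params = simgen.SimFieldParams(
            cargo_enrichment=3.0,
            gaussian_read_noise_sd=0.0,
            poisson_scale=np.inf,
            camera_offset=0.0,
            seed=11,
        )
        field = simgen.make_field(params)
        nuclei = segment_nuclei(field.channels["nuclei"])
        bmap = segment_bodies(field.channels["bodies"], nuclei)
        res = enrichment(bmap, nuclei, field.channels["cargo"], camera_offset=0.0)
        ratios = [r.ratio for r in res.records if r.valid]
        assert len(ratios) >= 10
        for r in ratios:
            assert r == pytest.approx(3.0, rel=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(0.0, 500.0))
    def test_ratio_invariant_to_gain_and_offset(self, scale, offset):
        """Multiplying by a gain and shifting by the camera offset leaves
        the ratio unchanged when offset subtraction is enabled."""
        nuclei, bmap = self._toy_maps()
        img = np.ones((80, 80)) * 50.0
        img[bmap.labels > 0] = 150.0
        base = enrichment(bmap, nuclei, img, camera_offset=0.0)
        transformed = enrichment(
            bmap, nuclei, img * scale + offset, camera_offset=offset, subtract_offset=True
        )
        for a, b in zip(base.records, transformed.records):
            assert b.ratio == pytest.approx(a.ratio, rel=1e-9)

    def test_border_body_flagged_and_excluded(self):
        shape = (60, 60)
        nuc = np.ones(shape, dtype=np.int32)  # nucleus fills the image
        bod = np.zeros(shape, dtype=np.int32)
        bod[0:6, 0:6] = 1  # touches the image border
        bod[30:35, 30:35] = 2
        res = enrichment(
            LabelMap(bod, "bodies", parents={1: 1, 2: 1}),
            LabelMap(nuc, "nuclei"),
            np.full(shape, 10.0),
        )
        flags = {r.body_id: r.valid for r in res.records}
        assert flags == {1: False, 2: True}
        assert res.n_excluded == 1


class TestCounting:
    def test_planted_counts_match_truth(self):
        field = simgen.make_field(simgen.SimFieldParams(seed=6))
        nuclei = segment_nuclei(field.channels["nuclei"])
        bmap = segment_bodies(field.channels["bodies"], nuclei)
        counts = count_foci(bmap, nuclei)
        # match segmented nuclei to truth nuclei by centroid
        cents = nuclei.centroids()
        truth_by_count = {}
        for n in field.truth.nuclei:
            lab = min(cents, key=lambda L: np.hypot(cents[L][0] - n.cx, cents[L][1] - n.cy))
            truth_by_count[lab] = n.n_bodies
        assert counts == truth_by_count

    def test_count_conservation(self):
        field = simgen.make_field(simgen.SimFieldParams(seed=7))
        nuclei = segment_nuclei(field.channels["nuclei"])
        bmap = segment_bodies(field.channels["bodies"], nuclei)
        counts = count_foci(bmap, nuclei)
        assert sum(counts.values()) == bmap.n_labels

    def test_split_between_two_nuclei(self):
        shape = (100, 100)
        nuc = np.zeros(shape, dtype=np.int32)
        nuc[10:45, 10:90] = 1
        nuc[55:90, 10:90] = 2
        bod = np.zeros(shape, dtype=np.int32)
        for i, (y, x) in enumerate([(20, 20), (20, 50), (30, 70), (70, 30), (70, 60)], start=1):
            bod[y : y + 4, x : x + 4] = i
        counts = count_foci(LabelMap(bod, "bodies"), LabelMap(nuc, "nuclei"))
        assert counts == {1: 3, 2: 2}


class TestCategorize:
    def test_default_bins_percentages(self):
        labels, pct = categorize_counts([0, 0, 1, 4])
        assert labels == ["0", "0", "1-2", ">=3"]
        assert pct == {"0": 50.0, "1-2": 25.0, ">=3": 25.0}

    def test_all_zero(self):
        _, pct = categorize_counts([0, 0, 0])
        assert pct == {"0": 100.0, "1-2": 0.0, ">=3": 0.0}

    def test_count_three_goes_to_top_bin(self):
        labels, _ = categorize_counts([3])
        assert labels == [">=3"]

    def test_matches_brute_force_tally_on_random_counts(self):
        rng = np.random.default_rng(123)
        counts = rng.poisson(2.0, size=1000)
        labels, pct = categorize_counts(counts)
        tally = collections.Counter(
            "0" if c == 0 else ("1-2" if c <= 2 else ">=3") for c in counts
        )
        for k, v in pct.items():
            assert v == pytest.approx(100.0 * tally.get(k, 0) / 1000, abs=1e-9)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            categorize_counts([1], bins=((0, 1), (1, 2), (3, None)))
        with pytest.raises(ValueError, match="partition"):
            categorize_counts([1], bins=((0, 0), (2, None)))


class TestClassifyPositive:
    @staticmethod
    def _regions():
        shape = (60, 120)
        lab = np.zeros(shape, dtype=np.int32)
        for i in range(8):
            y, x = 10 + 20 * (i // 4), 10 + 28 * (i % 4)
            lab[y : y + 10, x : x + 10] = i + 1
        return LabelMap(lab, "nuclei")

    def test_background_level_regions_are_negative(self):
        regions = self._regions()
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 5.0, regions.labels.shape)
        _, pct, n = classify_positive_cells(img, regions, c=3.0)
        assert pct == 0.0
        assert n == 8

    def test_half_planted_positive(self):
        regions = self._regions()
        rng = np.random.default_rng(1)
        img = rng.normal(100.0, 5.0, regions.labels.shape)
        for i in (1, 3, 5, 7):
            img[regions.labels == i] += 900.0
        calls, pct, _ = classify_positive_cells(img, regions, c=3.0)
        assert pct == 50.0
        assert all(calls[i] for i in (1, 3, 5, 7))

    def test_infinite_cutoff_gives_zero(self):
        regions = self._regions()
        img = np.random.default_rng(2).normal(100.0, 5.0, regions.labels.shape)
        img[regions.labels > 0] += 900.0
        _, pct, _ = classify_positive_cells(img, regions, c=1e9)
        assert pct == 0.0
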