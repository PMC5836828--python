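import numpy as np
import pytest

import cometkit as ck
from cometkit.refine import regional_maxima, trace_boundary
from conftest import disc_mask


# ---------------------------------------------------------------------------
# oracles

def brute_force_edt(binary):
    """All-pairs minimum distance to background (image padded by one
    background ring, so border foreground pixels get distance 1)."""
    binary = np.asarray(binary) > 0
    padded = np.pad(binary, 1, mode="constant", constant_values=False)
    bg = np.argwhere(~padded)
    out = np.zeros(binary.shape, dtype=float)
    for r, c in np.argwhere(binary):
        d = np.sqrt(((bg - [r + 1, c + 1]) ** 2).sum(axis=1))
        out[r, c] = d.min()
    return out


def oracle_regional_maxima(relief, mask):
    """Independent plateau-component regional-maxima labeling."""
    relief = np.asarray(relief, dtype=float)
    mask = np.asarray(mask) > 0
    h, w = relief.shape
    comp = np.full((h, w), -1, dtype=int)
    n = 0
    # connected components of equal value within mask (8-conn)
    for r in range(h):
        for c in range(w):
            if mask[r, c] and comp[r, c] < 0:
                stack = [(r, c)]
                comp[r, c] = n
                while stack:
                    cr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = cr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                                    and comp[nr, nc] < 0 \
                                    and relief[nr, nc] == relief[r, c]:
                                comp[nr, nc] = n
                                stack.append((nr, nc))
                n += 1
    is_max = [True] * n
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                            and relief[nr, nc] > relief[r, c]:
                        is_max[comp[r, c]] = False
    out = np.zeros((h, w), dtype=int)
    relabel = {}
    for r in range(h):
        for c in range(w):
            if mask[r, c] and is_max[comp[r, c]]:
                if comp[r, c] not in relabel:
                    relabel[comp[r, c]] = len(relabel) + 1
                out[r, c] = relabel[comp[r, c]]
    return out


def oracle_watershed(relief, mask):
    """Flooding by decreasing altitude with per-level distance relaxation:
    a pixel takes the smallest label among neighbors one BFS step closer."""
    relief = np.asarray(relief, dtype=float)
    mask = np.asarray(mask) > 0
    labels = oracle_regional_maxima(relief, mask)
    h, w = relief.shape
    for lev in sorted({relief[r, c] for r, c in np.argwhere(mask)}, reverse=True):
        todo = [(r, c) for r, c in np.argwhere(mask & (labels == 0))
                if relief[r, c] == lev]
        dist = {p: np.inf for p in todo}
        lab = {p: 0 for p in todo}
        changed = True
        while changed:
            changed = False
            for (r, c) in todo:
                best_d, best_l = dist[(r, c)], lab[(r, c)]
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if not (0 <= nr < h and 0 <= nc < w and mask[nr, nc]):
                            continue
                        if labels[nr, nc] > 0 and (nr, nc) not in dist:
                            nd, nl = 1, labels[nr, nc]
                        elif (nr, nc) in dist and np.isfinite(dist[(nr, nc)]):
                            nd, nl = dist[(nr, nc)] + 1, lab[(nr, nc)]
                        else:
                            continue
                        if nd < best_d or (nd == best_d and 0 < nl < best_l):
                            best_d, best_l = nd, nl
                if (best_d, best_l) != (dist[(r, c)], lab[(r, c)]):
                    dist[(r, c)], lab[(r, c)] = best_d, best_l
                    changed = True
        for p, l in lab.items():
            if l:
                labels[p] = l
    return labels


def union_find_horizontal_merge(chunks, overlap_min):
    """Pairwise overlap-graph oracle with transitive closure."""
    from scipy import ndimage
    chunks = np.asarray(chunks)
    ids = [int(v) for v in np.unique(chunks) if v > 0]
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    spans = {}
    for i in ids:
        cols = np.flatnonzero((chunks == i).any(axis=0))
        spans[i] = (cols[0], cols[-1])
    for a in ids:
        for b in ids:
            if a >= b:
                continue
            inter = min(spans[a][1], spans[b][1]) - max(spans[a][0], spans[b][0]) + 1
            smaller = min(spans[a][1] - spans[a][0], spans[b][1] - spans[b][0]) + 1
            grown = ndimage.binary_dilation(chunks == a, np.ones((3, 3), bool))
            if inter > 0 and inter / smaller >= overlap_min and (grown & (chunks == b)).any():
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups = {}
    out = np.zeros_like(chunks)
    for i in ids:
        root = find(i)
        groups.setdefault(root, len(groups) + 1)
        out[chunks == i] = groups[root]
    return out


# ---------------------------------------------------------------------------

class TestBorderAndFragments:
    def test_border_component_removed_interior_kept(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[0, 3] = labels[1, 3] = 1   # touches row 0
        labels[4:6, 4:6] = 2              # interior
        out = ck.remove_border_objects(labels)
        assert out.max() == 1
        assert np.all(out[4:6, 4:6] == 1) and out[0, 3] == 0

    def test_matches_border_scan_oracle(self, rng):
        for _ in range(5):
            binary = rng.random((15, 15)) < 0.3
            labels = ck.label_components(binary, 8)
            out = ck.remove_border_objects(labels)
            border_labels = set(np.concatenate([
                labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
            for k in range(1, labels.max() + 1):
                survived = np.any(out[labels == k] > 0)
                assert survived == (k not in border_labels)

    def test_small_fragment_merged_strictly(self):
        labels = np.zeros((100, 100), dtype=int)
        labels[40:60, 40:60] = 1            # 400 px comet
        labels[10, 10:19] = 2               # 9 px < 10 -> merged
        out = ck.merge_small_fragments(labels, 0.001)
        assert out[10, 10] == out[50, 50]

    def test_exactly_at_cutoff_kept(self):
        labels = np.zeros((100, 100), dtype=int)
        labels[40:60, 40:60] = 1
        labels[10, 10:20] = 2               # exactly 10 px: kept
        out = ck.merge_small_fragments(labels, 0.001)
        assert out[10, 10] != out[50, 50]
        assert out.max() == 2

    def test_fragment_joins_nearest_large_component(self):
        labels = np.zeros((100, 100), dtype=int)
        labels[10:30, 10:30] = 1            # comet A
        labels[70:90, 70:90] = 2            # comet B
        labels[60, 60:63] = 3               # 3 px, nearer to B
        out = ck.merge_small_fragments(labels, 0.001)
        # brute-force oracle over all pairwise pixel distances
        frag = np.argwhere(labels == 3)
        best = None
        for big in (1, 2):
            pix = np.argwhere(labels == big)
            d = min(np.sqrt(((frag[:, None, :] - pix[None, :, :]) ** 2)
                            .sum(axis=2)).min() for _ in [0])
            if best is None or d < best[0]:
                best = (d, big)
        assert out[60, 60] == out[80, 80]  # merged into B
        assert best[1] == 2

    def test_no_large_component_deletes_fragments(self):
        labels = np.zeros((100, 100), dtype=int)
        labels[50, 50:53] = 1
        assert ck.merge_small_fragments(labels, 0.001).max() == 0


class TestDistanceTransform:
    def test_isolated_pixel(self):
        binary = np.zeros((5, 5), dtype=int)
        binary[2, 2] = 1
        assert ck.distance_transform(binary)[2, 2] == 1.0

    def test_filled_square_center(self):
        binary = np.zeros((9, 9), dtype=int)
        binary[2:7, 2:7] = 1
        d = ck.distance_transform(binary)
        assert d[4, 4] == brute_force_edt(binary)[4, 4] == 3.0

    def test_matches_brute_force_on_random_blobs(self, rng):
        for _ in range(8):
            binary = rng.random((12, 12)) < 0.5
            assert np.allclose(ck.distance_transform(binary),
                               brute_force_edt(binary))


class TestWaveletSmooth:
    def test_constant_unchanged(self):
        relief = np.full((8, 8), 3.25)
        assert np.allclose(ck.wavelet_smooth(relief, 1), relief)

    def test_level1_haar_is_block_averaging(self, rng):
        relief = rng.uniform(0, 10, (4, 4))
        blocks = relief.reshape(2, 2, 2, 2).mean(axis=(1, 3))
        expected = blocks.repeat(2, axis=0).repeat(2, axis=1)
        assert np.allclose(ck.wavelet_smooth(relief, 1), expected)

    def test_shallow_pit_depth_reduced(self):
        relief = np.full((8, 8), 5.0)
        relief[3, 3] = 3.0
        out = ck.wavelet_smooth(relief, 1)
        before = 5.0 - relief[2:5, 2:5].min()
        after = 5.0 - out[2:5, 2:5].min()
        assert after < before

    def test_odd_shape_preserved(self, rng):
        relief = rng.uniform(0, 5, (7, 9))
        assert ck.wavelet_smooth(relief, 2).shape == (7, 9)

    def test_too_deep_level_rejected(self):
        with pytest.raises(ValueError):
            ck.wavelet_smooth(np.ones((4, 4)), 10)


class TestWatershed:
    def test_single_maximum_single_basin(self):
        mask = disc_mask((12, 12), (6, 6), 4)
        relief = ck.distance_transform(mask.astype(int))
        out = ck.watershed_split(relief, mask)
        assert out.max() == 1
        assert np.array_equal(out > 0, mask)

    def test_two_humps_split_at_saddle(self):
        rr, cc = np.mgrid[0:8, 0:16]
        relief = (5 * np.exp(-((rr - 4) ** 2 + (cc - 4) ** 2) / 6)
                  + 5 * np.exp(-((rr - 4) ** 2 + (cc - 11) ** 2) / 6))
        mask = relief > 0.5
        relief = relief * mask
        out = ck.watershed_split(relief, mask)
        assert out.max() == 2
        assert np.array_equal(out, oracle_watershed(relief, mask))

    def test_disjoint_parents_stay_separate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        relief = ck.distance_transform(mask.astype(int))
        out = ck.watershed_split(relief, mask)
        assert len(np.unique(out[mask])) == 2
        assert not np.any(out[1:4, 1:4] == out[6:9, 6:9])

    def test_matches_flooding_oracle_on_random_reliefs(self, rng):
        for _ in range(8):
            mask = rng.random((12, 12)) < 0.6
            relief = np.round(rng.uniform(0, 4, (12, 12)), 0) * mask
            got = ck.watershed_split(relief, mask)
            want = oracle_watershed(relief, mask)
            assert np.array_equal(got, want)

    def test_regional_maxima_match_oracle(self, rng):
        for _ in range(8):
            mask = rng.random((10, 10)) < 0.7
            relief = np.round(rng.uniform(0, 3, (10, 10)), 0) * mask
            assert np.array_equal(regional_maxima(relief, mask),
                                  oracle_regional_maxima(relief, mask))

    def test_empty_mask(self):
        out = ck.watershed_split(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))
        assert out.sum() == 0


class TestMergeHorizontal:
    def test_stacked_identical_spans_merge(self):
        chunks = np.zeros((6, 10), dtype=int)
        chunks[1:3, 2:8] = 1
        chunks[3:5, 2:8] = 2
        assert ck.merge_horizontal(chunks).max() == 1

    def test_disjoint_spans_unchanged(self):
        chunks = np.zeros((4, 12), dtype=int)
        chunks[1:3, 1:5] = 1
        chunks[1:3, 7:11] = 2
        assert ck.merge_horizontal(chunks).max() == 2

    def test_transitive_chain_collapses(self):
        chunks = np.zeros((9, 12), dtype=int)
        chunks[0:3, 0:8] = 1
        chunks[3:6, 2:10] = 2
        chunks[6:9, 4:12] = 3
        out = ck.merge_horizontal(chunks, 0.5)
        assert out.max() == 1
        assert np.array_equal(out, union_find_horizontal_merge(chunks, 0.5))

    def test_matches_union_find_oracle_random(self, rng):
        for _ in range(5):
            chunks = np.zeros((12, 12), dtype=int)
            for k in range(1, 5):
                r, c = rng.integers(0, 9, 2)
                chunks[r:r + rng.integers(1, 4), c:c + rng.integers(2, 5)] = k
            got = ck.merge_horizontal(chunks, 0.5)
            want = union_find_horizontal_merge(chunks, 0.5)
            # compare partitions (labels may differ)
            for a in np.unique(got[got > 0]):
                sel = got == a
                assert len(np.unique(want[sel])) == 1


class TestContourSpectrum:
    def test_circle_low_frequency_dominates(self):
        mask = disc_mask((50, 50), (25, 25), 20)
        spec = ck.contour_spectrum(mask, 64)
        share = (spec[0] + spec[-1]) / spec.sum()
        assert share > 0.9
        others = np.delete(spec, [0, len(spec) - 1])
        assert others.max() <= 0.05 * spec.sum()

    def test_ellipse_low_frequency_dominates(self):
        rr, cc = np.mgrid[0:40, 0:60]
        mask = ((rr - 20) / 10.0) ** 2 + ((cc - 30) / 20.0) ** 2 <= 1
        spec = ck.contour_spectrum(mask, 64)
        assert (spec[0] + spec[-1]) / spec.sum() > 0.8

    def test_star_less_round_than_circle(self):
        rr, cc = np.mgrid[0:61, 0:61]
        y, x = rr - 30.0, cc - 30.0
        theta = np.arctan2(y, x)
        radius = 10 + 14 * np.cos(4 * theta) ** 2
        star = x ** 2 + y ** 2 <= radius ** 2
        circle = disc_mask((61, 61), (30, 30), 20)
        s_star = ck.contour_spectrum(star, 64)
        s_circ = ck.contour_spectrum(circle, 64)
        ratio = lambda s: (s[0] + s[-1]) / s.sum()  # noqa: E731
        assert ratio(s_star) < ratio(s_circ)

    def test_boundary_traced_clockwise_from_top(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        b = trace_boundary(mask)
        assert tuple(b[0]) == (1, 1)
        assert tuple(b[1]) == (1, 2)  # clockwise: move east along the top
        assert len(b) == 8

    def test_degenerate_contour_rejected(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(ValueError):
            ck.contour_spectrum(mask, 32)


class TestChunkValidity:
    def test_round_half_area_chunk_valid(self):
        initial = np.zeros((40, 60), dtype=bool)
        initial[5:35, 5:55] = True
        chunk = disc_mask((40, 60), (20, 20), 12) & initial
        assert ck.chunk_is_valid(chunk, initial)

    def test_tiny_area_invalid_regardless_of_shape(self):
        initial = np.ones((50, 50), dtype=bool)
        chunk = disc_mask((50, 50), (25, 25), 3)  # ~1.1% of the mask
        assert not ck.chunk_is_valid(chunk, initial)

    def test_low_roundness_invalid(self):
        initial = np.ones((40, 80), dtype=bool)
        rr, cc = np.mgrid[0:40, 0:80]
        y, x = rr - 20.0, cc - 40.0
        theta = np.arctan2(y, x)
        radius = 6 + 12 * np.cos(4 * theta) ** 2
        chunk = x ** 2 + y ** 2 <= radius ** 2
        spec = ck.contour_spectrum(chunk, 64)
        share = (spec[0] + spec[-1]) / spec.sum()
        assert share < 0.70
        assert not ck.chunk_is_valid(chunk, initial)

    def test_empty_initial_mask_rejected(self):
        with pytest.raises(ValueError):
            ck.chunk_is_valid(np.ones((4, 4), bool), np.zeros((4, 4), bool))


class TestCorrectOverlaps:
    def test_isolated_comet_untouched(self):
        import cometkit.synth as synth
        spec = synth.sample_spec(np.random.default_rng(0), "normal", (30.0, 30.0))
        patch, _ = synth.render_comet(spec, seed=1, shape=(64, 64), with_noise=False)
        labels = (patch > 20).astype(np.int32)
        out = ck.correct_overlaps(labels)
        assert out.max() == 1
        assert np.array_equal(out > 0, labels > 0)

    def test_touching_pair_split(self):
        import cometkit.synth as synth
        a = synth.CometSpec("normal", (30.0, 28.0), head_sigma=6, head_peak=200,
                            damage=0.05, tail_length_true=10, tail_decay=20)
        b = synth.CometSpec("normal", (32.0, 58.0), head_sigma=6, head_peak=200,
                            damage=0.05, tail_length_true=10, tail_decay=20)
        from cometkit.synth import _render_clean
        img = _render_clean(a, (64, 100)) + _render_clean(b, (64, 100))
        labels = ck.label_components((img > 15).astype(int), 8)
        assert labels.max() == 1  # genuinely touching
        out = ck.correct_overlaps(labels)
        assert out.max() == 2
        recs = [ck.characterize_comet(img, out, k) for k in (1, 2)]
        cents = [r.centroid for r in recs]
        m = ck.centroid_match(cents, [(30, 28), (32, 58)], 15)
        assert m.tp == 2

    def test_three_comet_chain_split(self):
        import cometkit.synth as synth
        from cometkit.synth import _render_clean
        img = np.zeros((64, 150))
        centers = [(30.0, 28.0), (33.0, 56.0), (30.0, 84.0)]
        for rc in centers:
            spec = synth.CometSpec("normal", rc, head_sigma=6, head_peak=200,
                                   damage=0.05, tail_length_true=10, tail_decay=20)
            img += _render_clean(spec, (64, 150))
        labels = ck.label_components((img > 15).astype(int), 8)
        assert labels.max() == 1
        out = ck.correct_overlaps(labels)
        assert out.max() == 3

    def test_pixel_conservation(self, small_scene):
        img, _ = small_scene
        sm = ck.smooth(img)
        binary, _, _ = ck.threshold_image(sm)
        labels = ck.label_components(binary, 8)
        labels = ck.remove_border_objects(labels)
        labels = ck.merge_small_fragments(labels, 0.001)
        out = ck.correct_overlaps(labels)
        assert not np.any((out > 0) & (labels == 0))
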