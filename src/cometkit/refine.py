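"""Filtering and overlap correction.

Candidate masks from binarization are cleaned in two passes.  First,
components touching the image border are removed (usually truncated
shapes) and components smaller than a fraction of the image (default
0.1%) are merged into the closest large component rather than deleted —
the small satellites are often DNA fragments that belong to a nearby
comet's tail.  Second, overlapping comets are split: the mask's Euclidean
distance relief is smoothed with a Haar wavelet to fill the shallow pits
that cause over-segmentation, a watershed partitions the relief into one
basin per regional maximum, vertically stacked chunks sharing a column
span are merged back (horizontal divisions arise from the ragged contour
of a single cell, not from two cells), and finally each chunk must look
like a cell: the two lowest contour-spectrum frequencies must carry at
least 70% of the total amplitude and the chunk at least 3% of its parent
mask's area.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
import pywt
from scipy import ndimage
from skimage.morphology import reconstruction

from .binarize import relabel_raster_order
from .config import PipelineConfig
from .io import bbox_of

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# candidate filtering

def remove_border_objects(labels: np.ndarray) -> np.ndarray:
    """Delete every component with a pixel on the image border; relabel the
    survivors 1..n in raster order."""
    labels = np.asarray(labels)
    border = np.concatenate([labels[0, :], labels[-1, :],
                             labels[:, 0], labels[:, -1]])
    bad = np.unique(border[border > 0])
    out = labels.copy()
    out[np.isin(out, bad)] = 0
    return relabel_raster_order(out)


def merge_small_fragments(labels: np.ndarray, min_fraction: float = 0.001) -> np.ndarray:
    """Merge components smaller than ``min_fraction`` of the image into the
    nearest large component.

    Distance is the minimum Euclidean distance between any fragment pixel
    and any large-component pixel; ties go to the larger component, then to
    the smaller label.  With no large component present, fragments are
    deleted.
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    total = labels.size
    ids, sizes = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        return labels.astype(np.int32)
    cutoff = min_fraction * total
    small = ids[sizes < cutoff]
    large = ids[sizes >= cutoff]
    out = labels.copy().astype(np.int32)
    if small.size == 0:
        return relabel_raster_order(out)
    if large.size == 0:
        out[np.isin(out, small)] = 0
        return relabel_raster_order(out)

    size_of = dict(zip(ids.tolist(), sizes.tolist()))
    # nearest large component via one EDT per large label (few large comps)
    dist_maps = {}
    for lab in large:
        dist_maps[int(lab)] = ndimage.distance_transform_edt(out != lab)
    for lab in small:
        mask = out == lab
        best: tuple[float, int, int] | None = None  # (dist, -size, label)
        for big, dmap in dist_maps.items():
            d = float(dmap[mask].min())
            key = (d, -size_of[big], big)
            if best is None or key < best:
                best = key
        assert best is not None
        out[mask] = best[2]
    return relabel_raster_order(out)


# ---------------------------------------------------------------------------
# relief construction and smoothing

def distance_transform(binary: np.ndarray) -> np.ndarray:
    """Euclidean distance of each foreground pixel to the nearest background
    pixel; the frame outside the image counts as background (a border
    foreground pixel has distance 1)."""
    binary = np.asarray(binary) > 0
    padded = np.pad(binary, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[1:-1, 1:-1] * binary


def wavelet_smooth(relief: np.ndarray, level: int = 2) -> np.ndarray:
    """Smooth a topographic relief by zeroing the detail coefficients of a
    multi-level Haar decomposition.

    Level-1 smoothing is exactly non-overlapping 2x2 block averaging; odd
    dimensions are symmetric-padded and cropped back.  Output is clipped to
    be non-negative and the same shape as the input.
    """
    relief = np.asarray(relief, dtype=np.float64)
    if level < 1:
        raise ValueError("level must be >= 1")
    max_level = pywt.dwtn_max_level(relief.shape, "haar")
    if level > max_level:
        raise ValueError(f"level {level} too large for shape {relief.shape} "
                         f"(max {max_level})")
    coeffs = pywt.wavedec2(relief, "haar", level=level, mode="symmetric")
    approx = coeffs[0]
    zeroed = [approx] + [tuple(np.zeros_like(d) for d in details)
                         for details in coeffs[1:]]
    rec = pywt.waverec2(zeroed, "haar", mode="symmetric")
    rec = rec[:relief.shape[0], :relief.shape[1]]
    return np.clip(rec, 0.0, None)


# ---------------------------------------------------------------------------
# watershed

def regional_maxima(relief: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Label the 8-connected regional-maximum plateaus of ``relief`` inside
    ``mask``, numbered 1..k in raster order."""
    relief = np.asarray(relief, dtype=np.float64)
    mask = np.asarray(mask) > 0
    h, w = relief.shape
    is_max = np.zeros((h, w), dtype=bool)
    # plateau-aware: a component of equal-valued pixels is a regional max
    # iff no member has a strictly higher neighbor inside the mask
    visited = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or visited[r, c]:
                continue
            val = relief[r, c]
            comp = [(r, c)]
            visited[r, c] = True
            ok = True
            q = deque(comp)
            while q:
                cr, cc = q.popleft()
                for dr, dc in _NEIGHBORS8:
                    nr, nc = cr + dr, cc + dc
                    if not (0 <= nr < h and 0 <= nc < w) or not mask[nr, nc]:
                        continue
                    nv = relief[nr, nc]
                    if nv > val:
                        ok = False
                    elif nv == val and not visited[nr, nc]:
                        visited[nr, nc] = True
                        comp.append((nr, nc))
                        q.append((nr, nc))
            if ok:
                for pr, pc in comp:
                    is_max[pr, pc] = True
    lab = np.zeros((h, w), dtype=np.int32)
    next_lab = 1
    for r in range(h):
        for c in range(w):
            if is_max[r, c] and lab[r, c] == 0:
                q = deque([(r, c)])
                lab[r, c] = next_lab
                while q:
                    cr, cc = q.popleft()
                    for dr, dc in _NEIGHBORS8:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and is_max[nr, nc] \
                                and lab[nr, nc] == 0:
                            lab[nr, nc] = next_lab
                            q.append((nr, nc))
                next_lab += 1
    return lab


def watershed_split(relief: np.ndarray, parent_mask: np.ndarray,
                    seeds: np.ndarray | None = None) -> np.ndarray:
    """Partition ``parent_mask`` into catchment basins of the relief.

    Basins grow from the regional maxima downward, one altitude level at a
    time.  Within a level, each unlabeled pixel takes the label of the
    geodesically nearest already-labeled pixel (8-connected paths through
    the level set); ties go to the smallest label.  A level component with
    no labeled neighbor is itself a regional maximum and has already been
    seeded, so every parent pixel ends up in exactly one basin and the
    number of basins equals the number of regional maxima.
    """
    relief = np.asarray(relief, dtype=np.float64)
    mask = np.asarray(parent_mask) > 0
    if not mask.any():
        return np.zeros_like(relief, dtype=np.int32)
    if np.any(relief[~mask] != 0):
        raise ValueError("relief must be zero outside the parent mask")
    labels = regional_maxima(relief, mask) if seeds is None else \
        np.asarray(seeds, dtype=np.int32).copy()
    h, w = relief.shape
    levels = np.unique(relief[mask])[::-1]
    for lev in levels:
        todo = mask & (relief == lev) & (labels == 0)
        if not todo.any():
            continue
        # multi-source BFS: sources are labeled pixels 8-adjacent to the set
        frontier: deque[tuple[int, int]] = deque()
        claimed = np.zeros((h, w), dtype=np.int32)
        for r, c in zip(*np.nonzero(todo)):
            best = 0
            for dr, dc in _NEIGHBORS8:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and labels[nr, nc] > 0:
                    if best == 0 or labels[nr, nc] < best:
                        best = labels[nr, nc]
            if best:
                claimed[r, c] = best
                frontier.append((r, c))
        # BFS waves; within a wave, smaller label wins contested pixels
        while frontier:
            nxt: dict[tuple[int, int], int] = {}
            for r, c in frontier:
                labels[r, c] = claimed[r, c]
            for r, c in frontier:
                for dr, dc in _NEIGHBORS8:
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and todo[nr, nc] \
                            and labels[nr, nc] == 0:
                        lab = labels[r, c]
                        prev = nxt.get((nr, nc), 0)
                        if prev == 0 or lab < prev:
                            nxt[(nr, nc)] = lab
            frontier = deque()
            for (r, c), lab in nxt.items():
                claimed[r, c] = lab
                frontier.append((r, c))
    return labels * mask


# ---------------------------------------------------------------------------
# chunk post-processing

def _column_range(mask: np.ndarray) -> tuple[int, int]:
    cols = np.flatnonzero(mask.any(axis=0))
    return int(cols[0]), int(cols[-1])


def _adjacent8(a: np.ndarray, b: np.ndarray) -> bool:
    grown = ndimage.binary_dilation(a, structure=np.ones((3, 3), bool))
    return bool((grown & b).any())


def merge_horizontal(chunks: np.ndarray, overlap_min: float = 0.5) -> np.ndarray:
    """Merge 8-adjacent chunks whose column spans overlap by at least
    ``overlap_min`` of the smaller span (transitively, to a fixed point).

    Comets elongate along x, so two genuine neighbors separate along x; a
    pair of fragments stacked along y over the same x-span is one cell whose
    ragged contour was divided horizontally.
    """
    chunks = np.asarray(chunks)
    ids = [int(v) for v in np.unique(chunks) if v > 0]
    if len(ids) <= 1:
        return chunks.astype(np.int32)
    masks = {i: chunks == i for i in ids}
    spans = {i: _column_range(masks[i]) for i in ids}
    parent = {i: i for i in ids}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1:]:
            (a0, a1), (b0, b1) = spans[a], spans[b]
            inter = min(a1, b1) - max(a0, b0) + 1
            if inter <= 0:
                continue
            smaller = min(a1 - a0 + 1, b1 - b0 + 1)
            if inter / smaller < overlap_min:
                continue
            if _adjacent8(masks[a], masks[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    out = chunks.copy().astype(np.int32)
    for i in ids:
        out[masks[i]] = find(i)
    return relabel_raster_order(out)


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a single connected component by Moore-neighbor
    tracing, clockwise, starting at the topmost-then-leftmost pixel.

    Returns an (n, 2) array of (row, col) boundary pixels (closed contour,
    start not repeated).
    """
    mask = np.asarray(mask) > 0
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise ValueError("empty mask")
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))][0])
    # clockwise Moore neighborhood in (row, col) image coordinates
    ring = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

    def inside(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    boundary = [start]
    cur = start
    # start is topmost-then-leftmost, so its west neighbor is background;
    # the backtrack index points from cur toward that background pixel
    backtrack = 6  # index of (0, -1) in ring
    initial_state: tuple[tuple[int, int], int] | None = None
    max_steps = 8 * mask.size + 8
    for _ in range(max_steps):
        move = None
        prev = backtrack
        for k in range(1, 9):
            idx = (backtrack + k) % 8
            nxt = (cur[0] + ring[idx][0], cur[1] + ring[idx][1])
            if inside(nxt):
                move = (idx, nxt, prev)
                break
            prev = idx
        if move is None:  # isolated single pixel
            break
        idx, nxt, prev = move
        state = (cur, idx)
        if initial_state is None:
            initial_state = state
        elif state == initial_state:
            break  # Jacob's criterion: same pixel entered the same way
        boundary.append(nxt)
        # new backtrack: direction from nxt to the background pixel examined
        # just before the move
        bg = (cur[0] + ring[prev][0], cur[1] + ring[prev][1])
        backtrack = ring.index((bg[0] - nxt[0], bg[1] - nxt[1]))
        cur = nxt
    else:
        warnings.warn("boundary tracing did not close; contour truncated")
    # drop the duplicated closing start pixel if present
    if len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    return np.asarray(boundary, dtype=np.int64)


def contour_spectrum(mask: np.ndarray, n_points: int = 64) -> np.ndarray:
    """Fourier shape descriptor of one component's outer contour.

    The boundary is traced, resampled to ``n_points`` equally spaced points
    by arc length, encoded as col + i*row, and transformed by the DFT.  The
    DC term (pure centroid translation) is discarded; the returned
    amplitudes index frequencies 1 .. n_points-1 (so the +/-1 pair sits at
    the two ends).
    """
    boundary = trace_boundary(mask)
    if boundary.shape[0] < 4:
        raise ValueError(f"degenerate contour with {boundary.shape[0]} boundary pixels")
    closed = np.vstack([boundary, boundary[:1]]).astype(np.float64)
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    t = np.linspace(0.0, total, n_points, endpoint=False)
    rows = np.interp(t, arclen, closed[:, 0])
    cols = np.interp(t, arclen, closed[:, 1])
    z = cols + 1j * rows
    spectrum = np.fft.fft(z)
    return np.abs(spectrum[1:])


def chunk_is_valid(chunk: np.ndarray, initial_mask: np.ndarray,
                   spectrum: np.ndarray | None = None,
                   roundness_min: float = 0.70,
                   area_ratio_min: float = 0.03,
                   n_points: int = 64) -> bool:
    """A chunk is a plausible cell when the +/-1 contour frequencies carry
    >= ``roundness_min`` of the total amplitude and its area is >=
    ``area_ratio_min`` of the parent mask's area."""
    chunk = np.asarray(chunk) > 0
    initial = np.asarray(initial_mask) > 0
    area_parent = int(initial.sum())
    if area_parent == 0:
        raise ValueError("empty initial mask")
    if chunk.sum() / area_parent < area_ratio_min:
        return False
    if spectrum is None:
        try:
            spectrum = contour_spectrum(chunk, n_points)
        except ValueError:
            return False
    total = spectrum.sum()
    if total == 0:
        return False
    low = spectrum[0] + spectrum[-1]
    return bool(low / total >= roundness_min)


# ---------------------------------------------------------------------------
# driver

def correct_overlaps(labels: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Split overlapping comets within every candidate component.

    Per component: distance transform -> Haar smoothing -> watershed ->
    horizontal merging -> Fourier/area validity.  Invalid chunks are merged
    into their largest valid 8-adjacent neighbor, or dropped if none.
    Component-level failures degrade to keeping the component whole, with a
    warning, never aborting the image.
    """
    if config is None:
        config = PipelineConfig()
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for comet_id in range(1, int(labels.max()) + 1):
        member = labels == comet_id
        if not member.any():
            continue
        try:
            chunks = _split_component(member, config)
        except Exception as exc:  # noqa: BLE001 - per-component resilience
            warnings.warn(f"overlap correction failed on component {comet_id}: {exc}")
            chunks = member.astype(np.int32)
        for cid in np.unique(chunks[chunks > 0]):
            out[chunks == cid] = next_label
            next_label += 1
    return relabel_raster_order(out)


def _split_component(member: np.ndarray, config: PipelineConfig) -> np.ndarray:
    r0, c0, r1, c1 = bbox_of(member)
    pad = 1
    r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
    r1p, c1p = min(r1 + pad, member.shape[0]), min(c1 + pad, member.shape[1])
    sub = member[r0p:r1p, c0p:c1p]

    relief = distance_transform(sub)
    level = min(config.wavelet_level, pywt.dwtn_max_level(sub.shape, "haar"))
    smoothed = wavelet_smooth(relief, level) if level >= 1 else relief
    smoothed = smoothed * sub  # keep relief zero outside the mask
    # shave maxima shallower than h: ripples surviving the wavelet on the
    # flat ridge of an elongated tail would otherwise seed spurious basins
    if config.seed_prominence_h > 0:
        marker = np.clip(smoothed - config.seed_prominence_h, 0.0, None)
        smoothed = reconstruction(marker, smoothed)
    chunks = watershed_split(smoothed, sub)
    chunks = merge_horizontal(chunks, config.horizontal_overlap_min)

    ids = [int(v) for v in np.unique(chunks) if v > 0]
    # a standalone chunk must also clear the global small-fragment cutoff;
    # otherwise debris merged in earlier could be re-emitted as a "comet"
    min_pixels = config.small_fragment_fraction * member.size
    valid: dict[int, bool] = {}
    for cid in ids:
        cmask = chunks == cid
        valid[cid] = cmask.sum() >= min_pixels and \
            chunk_is_valid(cmask, sub, None,
                           config.fourier_roundness_min,
                           config.area_ratio_min,
                           config.contour_points)
    if not any(valid.values()):
        # nothing passes the cell test: keep the component whole (it was a
        # retained candidate; dropping it entirely would lose a real comet)
        return _embed(sub.astype(np.int32), member.shape, r0p, c0p)
    changed = True
    while changed:
        changed = False
        for cid in list(ids):
            if valid[cid] or not (chunks == cid).any():
                continue
            cmask = chunks == cid
            best, best_area = 0, -1
            for other in ids:
                if other == cid or not valid[other]:
                    continue
                omask = chunks == other
                if _adjacent8(cmask, omask):
                    area = int(omask.sum())
                    if area > best_area:
                        best, best_area = other, area
            if best:
                chunks[cmask] = best
                changed = True
            else:
                chunks[cmask] = 0
                changed = True
            valid.pop(cid, None)
            ids.remove(cid)
    return _embed(relabel_raster_order(chunks), member.shape, r0p, c0p)


def _embed(sub: np.ndarray, shape: tuple[int, int], r0: int, c0: int) -> np.ndarray:
    out = np.zeros(shape, dtype=np.int32)
    out[r0:r0 + sub.shape[0], c0:c0 + sub.shape[1]] = sub
    return out
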