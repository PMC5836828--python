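"""Seeded synthetic comet-assay scenes with full ground truth.

A comet is rendered as an isotropic Gaussian head whose peak dims with
damage, plus a rightward exponential-decay tail carrying the ``damage``
fraction of the comet's total fluorescent mass — the standard qualitative
picture: as DNA damage grows, the head grows dimmer and the tail longer
and brighter.  Three morphology archetypes are provided: *normal* (bright
compact head, negligible tail), *necrosis* (long bright tail, at least
three head-sigmas), and *apoptosis* (dim head — at most 40% of the
necrosis peak — with a long diffuse tail cloud).

Scenes place comets on a dark noisy background, force a chosen fraction of
them into touching/overlapping pairs displaced mainly along +x (comets
elongate along the electrophoresis axis, so real overlap chains run
horizontally), and sprinkle small bright debris below the fragment-filter
cutoff so the filtering stage is exercised.  Every comet's ground-truth
record is computed from its own noiseless render by the same profile
equations the measurement stage uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .characterize import characterize_comet
from .config import PipelineConfig
from .records import CometRecord

#: intensity below which a noiseless render does not count as comet mask
MASK_FLOOR = 5.0
#: background mean intensity of the synthetic camera
BACKGROUND_MEAN = 10.0
#: default additive background noise (s.d., intensity units)
BACKGROUND_NOISE_SD = 3.0
#: signal-dependent jitter scale: s.d. = POISSON_SCALE * sqrt(intensity)
POISSON_SCALE = 0.5

_NECROSIS_PEAK = 180.0

# integral of exp(-u^4/2): 2^(1/4) * Gamma(1/4) / 2
_SUPERGAUSS_NORM = float(2.0 ** 0.25 * 3.6256099082219083 / 2.0)


@dataclass
class CometSpec:
    """Generative parameters of one synthetic comet."""

    class_label: str
    head_center: tuple[float, float]
    head_sigma: float = 6.0
    head_peak: float = 200.0
    damage: float = 0.0
    tail_length_true: float = 12.0
    tail_decay: float = 6.0
    tail_sigma: float | None = None  # vertical half-width; defaults to head_sigma
    tail_offset: float | None = None  # distance from head center to tail start;
    # defaults to one head sigma (the head boundary), where migrated DNA
    # begins

    def __post_init__(self) -> None:
        if not 0.0 <= self.damage <= 1.0:
            raise ValueError("damage must lie in [0, 1]")
        if self.class_label == "normal" and self.damage > 0.1:
            raise ValueError("normal comets have damage <= 0.1")
        if self.class_label == "necrosis" and \
                self.tail_length_true < 3 * self.head_sigma:
            raise ValueError("necrosis tails span >= 3 head sigmas")
        if self.class_label == "apoptosis" and \
                self.head_peak > 0.4 * _NECROSIS_PEAK:
            raise ValueError("apoptosis heads peak at <= 40% of the necrosis default")
        if self.class_label not in ("normal", "necrosis", "apoptosis"):
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.tail_sigma is None:
            self.tail_sigma = self.head_sigma
        if self.tail_offset is None:
            self.tail_offset = self.head_sigma


@dataclass
class SceneGroundTruth:
    """Per-comet truth of a synthetic scene: boolean masks, intensity-
    weighted centroids, the generative specs, and records computed from the
    noiseless renders."""

    masks: list[np.ndarray] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    specs: list[CometSpec] = field(default_factory=list)
    true_records: list[CometRecord] = field(default_factory=list)

    @property
    def n_comets(self) -> int:
        return len(self.specs)


def _render_clean(spec: CometSpec, shape: tuple[int, int]) -> np.ndarray:
    """Noiseless continuous comet model evaluated on a pixel grid."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    r0, c0 = spec.head_center
    s = spec.head_sigma
    head_amp = (1.0 - spec.damage) * spec.head_peak
    head = head_amp * np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * s * s))

    img = head
    if spec.damage > 0 and spec.tail_length_true > 0:
        # tail mass = damage / (1 - damage) of head mass so the tail holds
        # the `damage` fraction of the comet's total mass
        head_mass = 2 * np.pi * s * s * head_amp
        tail_mass = head_mass * spec.damage / max(1.0 - spec.damage, 1e-9)
        lam = spec.tail_decay
        L = spec.tail_length_true
        st = spec.tail_sigma
        # normalization of exp(-dx/lam) on (0, L] x Gaussian in y
        norm_x = lam * (1.0 - np.exp(-L / lam))
        # vertical cross-section is a sharp-edged band (super-Gaussian,
        # power 4): real tails look like a diffuse stripe with fairly crisp
        # edges, not a soft Gaussian halo
        norm_y = _SUPERGAUSS_NORM * st
        amp = tail_mass / (norm_x * norm_y)
        dx = cols - c0 - spec.tail_offset
        u = (rows - r0) / st
        tail = amp * np.exp(-dx / lam) * np.exp(-0.5 * u ** 4)
        tail = np.where((dx > 0) & (dx <= L), tail, 0.0)
        img = img + tail
    return np.clip(img, 0.0, 255.0)


def _apply_noise(clean: np.ndarray, rng: np.random.Generator,
                 background_sd: float = BACKGROUND_NOISE_SD) -> np.ndarray:
    noisy = clean + BACKGROUND_MEAN
    noisy = noisy + rng.normal(0.0, background_sd, clean.shape)
    noisy = noisy + rng.normal(0.0, 1.0, clean.shape) * POISSON_SCALE * np.sqrt(
        np.maximum(clean, 0.0))
    return np.clip(noisy, 0.0, 255.0)


def _truth_record(clean: np.ndarray, comet_id: int = 1,
                  config: PipelineConfig | None = None) -> tuple[CometRecord, np.ndarray]:
    mask = clean > MASK_FLOOR
    labels = mask.astype(np.int32) * comet_id
    rec = characterize_comet(clean, labels, comet_id, config)
    return rec, mask


def render_comet(spec: CometSpec, seed: int = 0,
                 shape: tuple[int, int] | None = None,
                 with_noise: bool = True,
                 config: PipelineConfig | None = None,
                 ) -> tuple[np.ndarray, CometRecord]:
    """Render one comet on its own small canvas.

    Returns the (optionally noisy) patch and the ground-truth record
    computed from the noiseless model with the same profile equations used
    for measurement.  Same spec and seed give a bit-identical patch.
    """
    if shape is None:
        margin = int(np.ceil(4 * max(spec.head_sigma, spec.tail_sigma or 0.0)))
        width = int(np.ceil(spec.head_center[1] + (spec.tail_offset or 0.0)
                            + spec.tail_length_true)) + margin
        height = int(np.ceil(spec.head_center[0])) + margin
        shape = (height, width)
    clean = _render_clean(spec, shape)
    rec, _ = _truth_record(clean, 1, config)
    rec.class_label = spec.class_label
    rng = np.random.default_rng(seed)
    patch = _apply_noise(clean, rng) if with_noise else clean
    return patch, rec


# ---------------------------------------------------------------------------
# scene composition

_CLASS_MIX = (("normal", 0.4), ("necrosis", 0.3), ("apoptosis", 0.3))


def sample_spec(rng: np.random.Generator, class_label: str | None = None,
                head_center: tuple[float, float] = (0.0, 0.0)) -> CometSpec:
    """Draw one comet spec from the archetype distributions."""
    if class_label is None:
        names, probs = zip(*_CLASS_MIX)
        class_label = rng.choice(names, p=probs)
    sigma = float(rng.uniform(5.0, 7.0))
    # tails are rendered as gently decaying bands (decay scale >= 1.5x the
    # tail length): migrated DNA forms a bright stripe with a crisp end, so
    # scene histograms stay bimodal (background peak, sparse mid range,
    # comet-intensity mode) — the premise of first-valley thresholding
    if class_label == "normal":
        L = float(rng.uniform(6.0, 12.0))
        return CometSpec(class_label, head_center, head_sigma=sigma,
                         head_peak=float(rng.uniform(180.0, 220.0)),
                         damage=float(rng.uniform(0.0, 0.08)),
                         tail_length_true=L,
                         tail_decay=float(rng.uniform(1.5, 3.0)) * L)
    if class_label == "necrosis":
        L = float(rng.uniform(3.2 * sigma, 45.0 + 3.2 * sigma))
        return CometSpec(class_label, head_center, head_sigma=sigma,
                         head_peak=float(rng.uniform(160.0, 200.0)),
                         damage=float(rng.uniform(0.35, 0.6)),
                         tail_length_true=L,
                         tail_decay=float(rng.uniform(1.5, 3.0)) * L)
    # apoptosis: the head is nearly gone — most DNA sits in a diffuse cloud,
    # so the comet's mass (and detected centroid) is tail-dominated
    L = float(rng.uniform(25.0, 40.0))
    return CometSpec(class_label, head_center, head_sigma=sigma + 1.0,
                     head_peak=float(rng.uniform(65.0, 0.4 * _NECROSIS_PEAK)),
                     damage=float(rng.uniform(0.7, 0.85)),
                     tail_length_true=L,
                     tail_decay=float(rng.uniform(1.5, 3.0)) * L,
                     tail_sigma=sigma + 1.0)


def damage_sweep_spec(damage: float,
                      head_center: tuple[float, float] = (45.0, 25.0)) -> CometSpec:
    """Fixed-geometry comet whose only free parameter is ``damage``.

    The tail elongates with damage at roughly constant per-pixel
    brightness (as migrated DNA spreads further, not denser), and the
    saturating head stays the profile peak across the whole damage range —
    the regime in which the half-maximum head rule cleanly separates head
    from tail and the measured TDNA tracks the generative damage fraction.
    """
    damage = float(damage)
    label = "normal" if damage <= 0.1 else "necrosis"
    floor_len = 3.0 if label == "normal" else 18.5  # necrosis tails >= 3 sigma
    return CometSpec(label, head_center, head_sigma=6.0,
                     head_peak=420.0, damage=damage,
                     tail_length_true=max(380.0 * damage, floor_len),
                     tail_decay=1200.0, tail_sigma=4.5)


def _extent(spec: CometSpec) -> tuple[float, float, float, float]:
    """Comet footprint around its head center: (up, down, left, right)."""
    rad = 3.2 * max(spec.head_sigma, spec.tail_sigma or spec.head_sigma)
    right = max(3.2 * spec.head_sigma,
                (spec.tail_offset or 0.0) + spec.tail_length_true + 3.0)
    return rad, rad, 3.2 * spec.head_sigma, right


def _render_debris(rng: np.random.Generator, shape: tuple[int, int],
                   n_debris: int) -> np.ndarray:
    out = np.zeros(shape)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    for _ in range(n_debris):
        r = rng.uniform(20, shape[0] - 20)
        c = rng.uniform(20, shape[1] - 20)
        sigma = rng.uniform(0.8, 1.6)
        peak = rng.uniform(80.0, 180.0)
        out += peak * np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * sigma ** 2))
    return out


def compose_scene(n_comets: int = 20, overlap_rate: float = 0.2,
                  n_debris: int = 8, noise_sd: float = BACKGROUND_NOISE_SD,
                  seed: int = 0, size: tuple[int, int] = (512, 512),
                  config: PipelineConfig | None = None,
                  max_tries: int = 2000,
                  ) -> tuple[np.ndarray, SceneGroundTruth]:
    """Compose a full scene and its ground truth.

    ``ceil(overlap_rate * n_comets)`` comet *pairs* are forced to touch
    (second comet displaced 0.45-0.75 of the first's length along +x, with
    small vertical jitter); the rest are placed disjointly, away from the
    image border so the border filter does not remove true comets.
    """
    rng = np.random.default_rng(seed)
    h, w = size
    n_pairs = int(np.ceil(overlap_rate * n_comets)) if overlap_rate > 0 else 0
    if 2 * n_pairs > n_comets:
        raise ValueError("overlap_rate too high for the comet count")

    truth = SceneGroundTruth()
    clean_total = np.zeros(size)
    placed_boxes: list[tuple[float, float, float, float]] = []

    def fits(r: float, c: float, spec: CometSpec, clearance: float = 8.0) -> bool:
        up, down, left, right = _extent(spec)
        if r - up < 2 or r + down > h - 2 or c - left < 2 or c + right > w - 2:
            return False
        box = (r - up - clearance, c - left - clearance,
               r + down + clearance, c + right + clearance)
        for (br0, bc0, br1, bc1) in placed_boxes:
            if box[0] < br1 and br0 < box[2] and box[1] < bc1 and bc0 < box[3]:
                return False
        return True

    def place(spec_class: str | None, partner: CometSpec | None = None) -> CometSpec:
        for _ in range(max_tries):
            probe = sample_spec(rng, spec_class, (0.0, 0.0))
            if partner is None:
                r = rng.uniform(0, h)
                c = rng.uniform(0, w)
            else:
                pr, pc = partner.head_center
                length = 3.2 * partner.head_sigma + partner.tail_length_true
                r = pr + rng.uniform(-0.8, 0.8) * partner.head_sigma
                c = pc + rng.uniform(0.65, 0.95) * length
            probe.head_center = (float(r), float(c))
            if partner is not None:
                up, down, left, right = _extent(probe)
                if r - up < 2 or r + down > h - 2 or c - left < 2 or c + right > w - 2:
                    continue
                return probe
            if fits(r, c, probe):
                return probe
        raise RuntimeError("could not place a comet; reduce n_comets or overlap_rate")

    # overlapping pairs first (each pair shares one clearance box);
    # adjacency of the pair's truth masks is verified, not assumed
    for _ in range(n_pairs):
        for _attempt in range(50):
            a = place(None)
            try:
                b = place(None, partner=a)
            except RuntimeError:
                continue  # e.g. `a` too close to the right border
            mask_a = _render_clean(a, size) > MASK_FLOOR
            mask_b = _render_clean(b, size) > MASK_FLOOR
            if masks_touch(mask_a, mask_b):
                break
        else:
            raise RuntimeError("could not realize a touching comet pair")
        for spec in (a, b):
            up, down, left, right = _extent(spec)
            r, c = spec.head_center
            placed_boxes.append((r - up, c - left, r + down, c + right))
            truth.specs.append(spec)
    # remaining isolated comets
    for _ in range(n_comets - 2 * n_pairs):
        spec = place(None)
        up, down, left, right = _extent(spec)
        r, c = spec.head_center
        placed_boxes.append((r - up, c - left, r + down, c + right))
        truth.specs.append(spec)

    for spec in truth.specs:
        clean = _render_clean(spec, size)
        rec, mask = _truth_record(clean, 1, config)
        rec.class_label = spec.class_label
        total = clean[mask].sum()
        rows, cols = np.nonzero(mask)
        centroid = (float((rows * clean[rows, cols]).sum() / total),
                    float((cols * clean[rows, cols]).sum() / total))
        truth.masks.append(mask)
        truth.centroids.append(centroid)
        truth.true_records.append(rec)
        clean_total += clean

    clean_total += _render_debris(rng, size, n_debris)
    image = _apply_noise(np.clip(clean_total, 0, 255), rng, noise_sd)
    return image, truth


def masks_touch(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two boolean masks overlap or are 8-adjacent."""
    grown = ndimage.binary_dilation(a, structure=np.ones((3, 3), bool))
    return bool((grown & b).any())
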