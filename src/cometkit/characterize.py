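"""Comet characterization: intensity profile, head/tail geometry, DNA
fractions and the three tail moments.

The comet model is one-dimensional in x (the electrophoresis axis): the
per-column integrated intensity profile carries the head peak (CPH), the
head radius r defined by the head threshold HT, and the tail stretching
from the right end of the head to where the intensity reaches zero.
Treating intensity as mass gives

    DNA   = sum_x I(x)                over the whole comet,
    TDNA  = sum_{x in tail} I(x) / DNA,
    extent moment  = TDNA x tail length,
    Olive moment   = TDNA x tail distance (CMT - CPH),
    moment of inertia = sum_{x in tail} I(x) (CPH - x)^2 / DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .io import bbox_of
from .records import CometRecord


class DegenerateCometError(ValueError):
    """Raised for comets with zero integrated intensity."""


@dataclass
class IntensityProfile:
    """Per-column integrated intensity of one comet.

    ``values[k]`` is the sum of the comet's own pixel intensities in
    absolute column ``col_origin + k``.
    """

    values: np.ndarray
    col_origin: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile must be a non-empty 1-D sequence")


def intensity_profile(img: np.ndarray, labels: np.ndarray, comet_id: int) -> IntensityProfile:
    """Column sums of one comet's pixels (other comets and background
    excluded)."""
    member = np.asarray(labels) == comet_id
    if not member.any():
        raise KeyError(f"label {comet_id} not present in mask")
    r0, c0, r1, c1 = bbox_of(member)
    masked = np.where(member, np.asarray(img, dtype=np.float64), 0.0)
    return IntensityProfile(masked[r0:r1, c0:c1].sum(axis=0), c0)


def find_cph(profile: IntensityProfile) -> int:
    """Center position of head: peak of the profile (leftmost on ties)."""
    v = profile.values
    if not np.any(v > 0):
        raise DegenerateCometError("all-zero intensity profile")
    return int(np.argmax(v))


def head_radius(profile: IntensityProfile, cph: int, ht: float) -> int:
    """Distance from the CPH to the first column right of it whose profile
    value drops below HT x peak; the profile end if it never does."""
    if not 0.0 < ht <= 1.0:
        raise ValueError("HT must lie in (0, 1]")
    v = profile.values
    if not 0 <= cph < v.size:
        raise ValueError("cph outside profile")
    cut = ht * v[cph]
    for x in range(cph + 1, v.size):
        if v[x] < cut:
            return x - cph
    return (v.size - 1) - cph


def tail_bounds(profile: IntensityProfile, cph: int, r: int) -> tuple[int, int]:
    """(tail_start, tail_end): the right end of the head and the last
    strictly positive profile column.  Tail columns are the half-open
    interval (tail_start, tail_end]; tail length = tail_end - tail_start,
    floored at 0."""
    v = profile.values
    tail_start = cph + r
    positive = np.flatnonzero(v > 0)
    tail_end = int(positive[-1]) if positive.size else tail_start
    return tail_start, max(tail_end, tail_start)


def tail_columns(tail_start: int, tail_end: int) -> np.ndarray:
    return np.arange(tail_start + 1, tail_end + 1)


def dna_amounts(profile: IntensityProfile, tail: np.ndarray) -> tuple[float, float]:
    """(DNA, TDNA): total summed intensity and the fraction of it in the
    tail columns."""
    v = profile.values
    dna = float(v.sum())
    if dna <= 0:
        raise DegenerateCometError("comet has zero DNA")
    tail = np.asarray(tail, dtype=np.int64)
    tdna = float(v[tail].sum() / dna) if tail.size else 0.0
    return dna, min(max(tdna, 0.0), 1.0)


def tail_moments(tdna: float, tail_length: float, tail_distance: float) -> tuple[float, float]:
    """(extent, Olive) moments: TDNA (as a fraction) times the tail length
    and tail distance in pixels."""
    return tdna * tail_length, tdna * tail_distance


def cmt_and_distance(profile: IntensityProfile, tail: np.ndarray,
                     cph: int) -> tuple[float, float]:
    """Center of mass of the tail along x and the tail distance CMT - CPH.

    With an empty (or massless) tail, the tail distance is 0 and the CMT is
    undefined (returned as NaN).
    """
    v = profile.values
    tail = np.asarray(tail, dtype=np.int64)
    mass = float(v[tail].sum()) if tail.size else 0.0
    if mass <= 0:
        return float("nan"), 0.0
    cmt = float((tail * v[tail]).sum() / mass)
    return cmt, cmt - cph


def moment_of_inertia(profile: IntensityProfile, tail: np.ndarray,
                      cph: int, dna: float) -> float:
    """DNA-normalized intensity-weighted squared distance of tail columns
    from the CPH."""
    if dna <= 0:
        raise DegenerateCometError("comet has zero DNA")
    tail = np.asarray(tail, dtype=np.int64)
    if tail.size == 0:
        return 0.0
    v = profile.values
    return float((v[tail] * (cph - tail) ** 2).sum() / dna)


def characterize_comet(img: np.ndarray, labels: np.ndarray, comet_id: int,
                       config: PipelineConfig | None = None) -> CometRecord:
    """Compose the profile-based measurements into one comet record.

    With ``tail_direction == "-x"`` the comet is mirrored about the vertical
    axis before measurement, so records are identical to the equivalent
    +x acquisition.  Degenerate comets (zero DNA) raise
    :class:`DegenerateCometError`; callers flag rather than drop them.
    """
    if config is None:
        config = PipelineConfig()
    member = np.asarray(labels) == comet_id
    if not member.any():
        raise KeyError(f"label {comet_id} not present in mask")
    img = np.asarray(img, dtype=np.float64)
    bbox = bbox_of(member)

    prof = intensity_profile(img, labels, comet_id)
    flipped = config.tail_direction == "-x"
    values = prof.values[::-1].copy() if flipped else prof.values
    work = IntensityProfile(values, prof.col_origin)

    cph_local = find_cph(work)
    r = head_radius(work, cph_local, config.head_threshold)
    tail_start, tail_end = tail_bounds(work, cph_local, r)
    tail = tail_columns(tail_start, tail_end)
    tail_length = float(tail_end - tail_start)
    dna, tdna = dna_amounts(work, tail)
    cmt, tail_distance = cmt_and_distance(work, tail, cph_local)
    extent, olive = tail_moments(tdna, tail_length, tail_distance)
    inertia = moment_of_inertia(work, tail, cph_local, dna)

    flags = []
    if np.isnan(cmt):
        flags.append("empty-tail")
    if tail_distance < 0:
        flags.append("negative-tail-distance")

    masked = np.where(member, img, 0.0)
    total = masked.sum()
    rows, cols = np.nonzero(member)
    centroid = (float((rows * masked[rows, cols]).sum() / total),
                float((cols * masked[rows, cols]).sum() / total))

    if flipped:
        cph_abs = prof.col_origin + (values.size - 1 - cph_local)
    else:
        cph_abs = prof.col_origin + cph_local

    rec = CometRecord(
        id=int(comet_id), bbox=bbox, centroid=centroid, cph=int(cph_abs),
        head_radius_r=float(r), tail_length=tail_length,
        tail_distance=float(tail_distance), dna=dna, tdna=tdna,
        extent_moment=extent, olive_moment=olive, inertia_moment=inertia,
        flags=";".join(flags),
    )
    rec.validate()
    return rec
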