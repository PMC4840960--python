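"""The assay's core quantification: MBP score, fiber score, and their quotient.

Definitions (per imaged field):

* **MBP score** ("OL differentiation") — threshold-selected MBP area x mean
  MBP intensity within that area, divided by the number of oligodendrocytes
  (Olig2+ nuclei in co-culture mode; DAPI nuclei in the purified-OPC
  differentiation mode).
* **Fiber score** ("myelination") — total amount of *contiguous straight*
  MBP fiber, divided by the number of Olig2+ nuclei.  Each retained fiber
  contributes its skeleton path length, by default weighted by its mean
  intensity along the skeleton.
* **fiber score / MBP score** — the quotient isolating myelination-specific
  signal from differentiation: ~1 means the MBP increase is explained by
  differentiation alone; substantially >1 means specific induction of
  myelination.

Fiber detection is a multiscale ridge (tubeness) filter, binarized within the
MBP mask, skeletonized, decomposed at branch points into simple paths, and
gated on minimum path length and straightness (end-to-end distance / path
length).  A branched, diffuse oligodendrocyte arbor therefore contributes
only its straight sub-segments, which the length gate then removes — matching
the intent of counting only condensed, axon-aligned fibers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import sato, threshold_otsu
from skimage.morphology import skeletonize

from .errors import FormatError, UndefinedScoreError
from .imaging_io import FieldImage
from .segmentation import NucleiSet, SegmentationParams, classify_olig2, detect_nuclei

# ---------------------------------------------------------------------------
# MBP mask and MBP score
# ---------------------------------------------------------------------------


@dataclass
class MBPMask:
    mask: np.ndarray
    threshold_value: float
    area_px: int
    mean_intensity_in_mask: float


def threshold_mbp(mbp: np.ndarray, method: str = "otsu") -> MBPMask:
    """Threshold-select MBP staining.

    ``method`` is ``"otsu"``, ``"fixed:<value>"`` or ``"quantile:<q>"``.
    The mask keeps pixels strictly above the threshold.
    """
    mbp = np.asarray(mbp, dtype=np.float64)
    if mbp.ndim != 2:
        raise FormatError(f"MBP raster must be 2-D, got shape {mbp.shape}")
    if np.any(mbp < 0):
        raise FormatError("MBP raster must be non-negative")
    if method == "otsu":
        if mbp.max() == mbp.min():
            thr = float(mbp.max())
        else:
            thr = float(threshold_otsu(mbp))
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    elif method.startswith("quantile:"):
        q = float(method.split(":", 1)[1])
        if not 0.0 < q < 1.0:
            raise FormatError(f"quantile must be in (0, 1), got {q}")
        thr = float(np.quantile(mbp, q))
    else:
        raise FormatError(f"unknown MBP threshold method {method!r}")
    mask = mbp > thr
    area = int(mask.sum())
    mean = float(mbp[mask].mean()) if area else 0.0
    return MBPMask(mask, thr, area, mean)


def compute_mbp_score(mask: MBPMask, n_cells: int) -> float:
    """MBP score = mask area x mean intensity in mask / number of cells."""
    if n_cells <= 0:
        raise UndefinedScoreError("MBP score undefined: zero cells in denominator")
    return mask.area_px * mask.mean_intensity_in_mask / n_cells


# ---------------------------------------------------------------------------
# Fibers
# ---------------------------------------------------------------------------


@dataclass
class FiberParams:
    """Fiber detector parameters.

    ridge_scales : sigmas (px) of the tubeness filter; spans expected fiber
        widths of ~2-3 px.
    min_ridge_response : binarization cut as a fraction of the maximum ridge
        response within the MBP mask.
    min_fiber_length_px : minimum skeleton path length of a retained fiber.
    min_straightness : minimum end-to-end / path-length ratio; 1 is a
        perfectly straight chain.
    weighting : ``"length_times_mean_intensity"`` (default) or
        ``"length_only"`` — how each fiber contributes to the fiber score.
    """

    ridge_scales: tuple[float, ...] = (1.0, 2.0)
    min_ridge_response: float = 0.15
    min_fiber_length_px: float = 20.0
    min_straightness: float = 0.8
    weighting: str = "length_times_mean_intensity"


@dataclass
class Fiber:
    skeleton: list[tuple[int, int]]
    path_length_px: float
    end_to_end_px: float
    straightness: float
    mean_intensity: float


_SQRT2 = math.sqrt(2.0)


def _chain_length(chain: Sequence[tuple[int, int]]) -> float:
    """Path length of a pixel chain: 1 per orthogonal step, sqrt(2) per diagonal."""
    total = 0.0
    for (r0, c0), (r1, c1) in zip(chain[:-1], chain[1:]):
        total += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return total


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_paths(skeleton: np.ndarray) -> list[list[tuple[int, int]]]:
    """Decompose a binary skeleton into simple paths between endpoints/branch points.

    8-connected skeleton pixels form a graph; pixels of degree != 2 are nodes
    and each node-to-node walk is one simple path.  Isolated cycles are cut at
    an arbitrary pixel and returned as one path.
    """
    coords = {tuple(p) for p in np.argwhere(skeleton)}
    if not coords:
        return []
    neighbors: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for p in coords:
        r, c = p
        neighbors[p] = [q for dr, dc in _OFFSETS if (q := (r + dr, c + dc)) in coords]
    nodes = {p for p, nb in neighbors.items() if len(nb) != 2}
    visited_edges: set[frozenset[tuple[int, int]]] = set()
    paths: list[list[tuple[int, int]]] = []

    def walk(start: tuple[int, int], nxt: tuple[int, int]) -> list[tuple[int, int]]:
        chain = [start, nxt]
        visited_edges.add(frozenset((start, nxt)))
        prev, cur = start, nxt
        while cur not in nodes:
            options = [q for q in neighbors[cur] if q != prev]
            # drop diagonal shortcuts already implied by an orthogonal step
            options = [q for q in options if frozenset((cur, q)) not in visited_edges]
            if not options:
                break
            nxt2 = options[0]
            visited_edges.add(frozenset((cur, nxt2)))
            chain.append(nxt2)
            prev, cur = cur, nxt2
        return chain

    for node in sorted(nodes):
        for nb in sorted(neighbors[node]):
            if frozenset((node, nb)) not in visited_edges:
                paths.append(walk(node, nb))

    # pure cycles: remaining pixels with no incident visited edge
    in_path = {p for path in paths for p in path}
    remaining = sorted(coords - in_path)
    seen: set[tuple[int, int]] = set()
    for start in remaining:
        if start in seen or not neighbors[start]:
            continue
        chain = walk(start, sorted(neighbors[start])[0])
        seen.update(chain)
        paths.append(chain)
    return paths


def detect_fibers(
    mbp: np.ndarray, mask: MBPMask, params: FiberParams | None = None
) -> list[Fiber]:
    """Detect contiguous straight MBP fibers within the thresholded mask.

    Deterministic.  Returns an empty list for an empty mask.
    """
    params = params or FiberParams()
    mbp = np.asarray(mbp, dtype=np.float64)
    if mbp.shape != mask.mask.shape:
        raise FormatError("MBP raster and mask shapes differ")
    if mask.area_px == 0:
        return []
    ridge = sato(mbp, sigmas=params.ridge_scales, black_ridges=False)
    in_mask = ridge[mask.mask]
    top = float(in_mask.max())
    if top <= 0:
        return []
    binary = (ridge >= params.min_ridge_response * top) & mask.mask
    skel = skeletonize(binary)
    fibers: list[Fiber] = []
    for chain in skeleton_paths(skel):
        length = _chain_length(chain)
        if length < params.min_fiber_length_px:
            continue
        (r0, c0), (r1, c1) = chain[0], chain[-1]
        end_to_end = math.hypot(r1 - r0, c1 - c0)
        straightness = end_to_end / length if length > 0 else 1.0
        if straightness < params.min_straightness:
            continue
        rr = np.array([p[0] for p in chain])
        cc = np.array([p[1] for p in chain])
        fibers.append(
            Fiber(
                skeleton=chain,
                path_length_px=length,
                end_to_end_px=end_to_end,
                straightness=straightness,
                mean_intensity=float(mbp[rr, cc].mean()),
            )
        )
    return fibers


def compute_fiber_score(
    fibers: Sequence[Fiber], n_olig2: int, weighting: str = "length_times_mean_intensity"
) -> float:
    """Fiber score = sum of per-fiber weights / number of Olig2+ nuclei."""
    if n_olig2 <= 0:
        raise UndefinedScoreError("fiber score undefined: zero Olig2+ nuclei")
    if weighting == "length_times_mean_intensity":
        total = sum(f.path_length_px * f.mean_intensity for f in fibers)
    elif weighting == "length_only":
        total = sum(f.path_length_px for f in fibers)
    else:
        raise FormatError(f"unknown fiber weighting {weighting!r}")
    return total / n_olig2


# ---------------------------------------------------------------------------
# Per-field scoring
# ---------------------------------------------------------------------------


@dataclass
class FieldScores:
    """Per-field quantification record.

    ``usable`` is False when the field has no Olig2+ nuclei (co-culture
    mode); such fields are excluded from condition aggregation rather than
    scored 0, to avoid deflating condition means.
    """

    n_dapi: int
    n_olig2: int
    mbp_score: float | None
    fiber_score: float | None
    fiber_mbp: float | None
    usable: bool


def score_field(
    image: FieldImage,
    seg_params: SegmentationParams | None = None,
    fiber_params: FiberParams | None = None,
    mbp_threshold: str = "otsu",
) -> FieldScores:
    """Run the full per-field quantification on a 3-channel co-culture field."""
    seg_params = seg_params or SegmentationParams()
    fiber_params = fiber_params or FiberParams()
    nuclei = detect_nuclei(np.asarray(image.channels["DAPI"]), seg_params)
    nuclei = classify_olig2(nuclei, np.asarray(image.channels["Olig2"]), seg_params)
    n_dapi, n_olig2 = nuclei.n_total, nuclei.n_olig2
    if n_olig2 == 0:
        return FieldScores(n_dapi, 0, None, None, None, usable=False)
    mbp = np.asarray(image.channels["MBP"])
    mask = threshold_mbp(mbp, mbp_threshold)
    mbp_score = compute_mbp_score(mask, n_olig2)
    fibers = detect_fibers(mbp, mask, fiber_params)
    fiber_score = compute_fiber_score(fibers, n_olig2, fiber_params.weighting)
    fiber_mbp = fiber_score / mbp_score if mbp_score > 0 else 0.0
    return FieldScores(n_dapi, n_olig2, mbp_score, fiber_score, fiber_mbp, usable=True)


def score_differentiation_field(
    image: FieldImage,
    seg_params: SegmentationParams | None = None,
    mbp_threshold: str = "otsu",
) -> float:
    """Purified-OPC differentiation score: MBP score over *DAPI* nuclei.

    Used in the acute differentiation assay variant, which has no Olig2
    channel and no fiber detection.
    """
    seg_params = seg_params or SegmentationParams()
    nuclei = detect_nuclei(np.asarray(image.channels["DAPI"]), seg_params)
    if nuclei.n_total == 0:
        raise UndefinedScoreError("differentiation score undefined: no DAPI nuclei")
    mask = threshold_mbp(np.asarray(image.channels["MBP"]), mbp_threshold)
    return compute_mbp_score(mask, nuclei.n_total)
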