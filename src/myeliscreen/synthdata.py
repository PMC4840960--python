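"""Synthetic fluorescence fields, plates, and whole screens with exact ground truth.

The generator emulates the assay's imaging phenotypes: DAPI-stained nuclei of
mixed cell types, an Olig2+ subpopulation (default 22 % of nuclei, the
measured OPC/OL share of the co-cultures), and MBP+ oligodendrocytes in two
morphologies — diffuse branched blobs (pre-myelinating OLs) versus condensed
straight aligned fibers (early myelination).  Nuclei are 2-D Gaussians
clipped at 3 sigma, fibers constant-width anti-aliased polylines, diffuse OLs
superposed soft blobs; geometry is therefore analytically known and every
planted quantity (positions, fiber path lengths and intensities, expected
scores) is returned as ground truth.

Screens are simulated at the published design: two concentrations (5 and
1 uM), duplicate wells, 4 fields per well (8 data points per condition),
8 control wells per plate (1 uM DAPT positive / DMSO negative).  Planted hits
scale fiber density by ``effect_size`` x a Hill occupancy term in
concentration; DAPT wells get ``control_effect`` (default 2.0, which together
with an MBP-score coupling of 0.25 reproduces the assay's control behaviour:
raw DAPT fiber-score/MBP-score > 1.5 and a DAPT/DMSO quotient ratio near
1.6).

Screens can be simulated at two fidelities:

* ``render_images=True`` — every field is rendered and must be scored by the
  image pipeline; used for small end-to-end demonstrations.
* ``render_images=False`` — per-field scores are drawn directly from the same
  statistical field model (multipliers + field-to-field noise), which makes
  library-scale screens (727 compounds) fast while preserving the planted
  truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GenerationError
from .fiber_morphometrics import FieldScores
from .imaging_io import FieldImage, PlateLayout, WellInfo
from .plate_analytics import build_score_table

# ---------------------------------------------------------------------------
# Distribution helpers: a parameter may be a scalar (exact) or (lo, hi) uniform
# ---------------------------------------------------------------------------


def _sample(dist, rng: np.random.Generator) -> float:
    if isinstance(dist, (tuple, list)):
        lo, hi = dist
        return float(rng.uniform(lo, hi))
    return float(dist)


def _sample_int(dist, rng: np.random.Generator) -> int:
    if isinstance(dist, (tuple, list)):
        lo, hi = dist
        return int(rng.integers(lo, hi + 1))
    return int(dist)


# ---------------------------------------------------------------------------
# Field-level generation
# ---------------------------------------------------------------------------


@dataclass
class FieldSpec:
    """Parameters of one synthetic field.

    Distribution-valued parameters accept a scalar (used exactly) or a
    ``(lo, hi)`` tuple (sampled uniformly).  Defaults describe a 512x512
    test-scale field of a healthy vehicle-treated co-culture; the full
    acquisition raster (2560x2160) is supported by scaling ``image_shape``
    and the density parameters together.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_nuclei_total: int = 150
    frac_olig2: float = 0.22
    n_ol_diffuse: int = 8
    n_ol_fibrous: int = 6
    fibers_per_ol: int | tuple = 3
    fiber_length_px: float | tuple = (30.0, 90.0)
    fiber_intensity: float | tuple = (800.0, 1200.0)
    fiber_waviness: float = 0.0
    fiber_density_multiplier: float = 1.0
    diffuse_blob_radius_px: float = 12.0
    diffuse_intensity: float | tuple = (400.0, 700.0)
    nucleus_sigma_px: float = 4.0
    nucleus_amplitude: float | tuple = (2000.0, 4000.0)
    olig2_amplitude: float | tuple = (2000.0, 4000.0)
    min_nucleus_distance_px: float = 12.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        n_olig2 = round(self.frac_olig2 * self.n_nuclei_total)
        if self.n_ol_diffuse + self.n_ol_fibrous > n_olig2:
            raise ValueError(
                f"{self.n_ol_diffuse} diffuse + {self.n_ol_fibrous} fibrous OLs exceed "
                f"the {n_olig2} Olig2+ nuclei implied by frac_olig2"
            )
        if not 0.0 <= self.frac_olig2 <= 1.0:
            raise ValueError("frac_olig2 must be in [0, 1]")
        if self.fiber_density_multiplier < 0:
            raise ValueError("fiber_density_multiplier must be >= 0")

    @property
    def n_olig2(self) -> int:
        return round(self.frac_olig2 * self.n_nuclei_total)


@dataclass
class FiberTruth:
    polyline: np.ndarray  # (n, 2) float (row, col)
    path_length_px: float
    mean_intensity: float


@dataclass
class GroundTruth:
    """Planted geometry plus the closed-form expected scores.

    ``expected_fiber_score`` applies the fiber-score definition (sum of path
    length x intensity over Olig2+ nuclei) to the planted polylines;
    ``expected_mbp_score`` applies the MBP-score definition to the noiseless
    MBP footprint (total planted MBP flux over Olig2+ nuclei).  Both are 0
    when the field has no Olig2+ nuclei.
    """

    nuclei: list[dict] = dc_field(default_factory=list)
    fibers: list[FiberTruth] = dc_field(default_factory=list)
    expected_mbp_score: float = 0.0
    expected_fiber_score: float = 0.0
    mbp_footprint_area: int = 0
    noiseless_mbp: np.ndarray | None = None

    @property
    def n_olig2(self) -> int:
        return sum(1 for n in self.nuclei if n["is_olig2"])


def _place_points(
    n: int,
    shape: tuple[int, int],
    min_dist: float,
    rng: np.random.Generator,
    margin: float = 8.0,
) -> np.ndarray:
    """Random positions with a minimum pairwise distance (bounded retries)."""
    points: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max(1000, 300 * n)
    while len(points) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n} nuclei with min distance {min_dist} in {shape} "
                f"after {max_attempts} attempts"
            )
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist**2 for pr, pc in points):
            points.append((r, c))
    return np.array(points).reshape(n, 2)


def _stamp_gaussian(
    img: np.ndarray, center: tuple[float, float], sigma: float, amp: float
) -> None:
    """Add a 2-D Gaussian blob clipped at 3 sigma (in place, max-combined)."""
    r0, c0 = center
    rad = 3.0 * sigma
    rmin, rmax = max(0, int(r0 - rad)), min(img.shape[0], int(r0 + rad) + 1)
    cmin, cmax = max(0, int(c0 - rad)), min(img.shape[1], int(c0 + rad) + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    blob = amp * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > rad**2] = 0.0
    np.maximum(img[rmin:rmax, cmin:cmax], blob, out=img[rmin:rmax, cmin:cmax])


def _stamp_disc(
    img: np.ndarray, center: tuple[float, float], radius: float, amp: float,
    soft_edge: float = 1.5,
) -> None:
    """Max-combine a soft-edged disc: flat plateau with a short linear falloff."""
    r0, c0 = center
    rad = radius + soft_edge
    rmin, rmax = max(0, int(r0 - rad)), min(img.shape[0], int(r0 + rad) + 1)
    cmin, cmax = max(0, int(c0 - rad)), min(img.shape[1], int(c0 + rad) + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    d = np.hypot(rr - r0, cc - c0)
    profile = np.clip(1.0 - (d - radius) / soft_edge, 0.0, 1.0)
    np.maximum(img[rmin:rmax, cmin:cmax], amp * profile, out=img[rmin:rmax, cmin:cmax])


def _fiber_polyline(
    start: tuple[float, float],
    angle: float,
    length: float,
    waviness: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Sample a (possibly wavy) fiber polyline at ~1 px arc steps, clipped to the image."""
    n = int(math.ceil(length)) + 1
    t = np.linspace(0.0, length, n)
    dr, dc = math.sin(angle), math.cos(angle)
    # perpendicular sinusoidal perturbation, one period over the fiber
    offset = waviness * np.sin(2.0 * math.pi * t / max(length, 1e-9))
    rows = start[0] + t * dr - offset * dc
    cols = start[1] + t * dc + offset * dr
    inside = (rows >= 1) & (rows < shape[0] - 1) & (cols >= 1) & (cols < shape[1] - 1)
    if not inside.all():
        stop = int(np.argmin(inside))  # truncate at first exit
        rows, cols = rows[:stop], cols[:stop]
    return np.column_stack([rows, cols])


def _polyline_length(poly: np.ndarray) -> float:
    if len(poly) < 2:
        return 0.0
    return float(np.sum(np.hypot(np.diff(poly[:, 0]), np.diff(poly[:, 1]))))


def _stamp_polyline(
    img: np.ndarray, poly: np.ndarray, intensity: float, core_halfwidth: float = 0.75,
    soft_edge: float = 1.0,
) -> None:
    """Max-combine a constant-width anti-aliased line along a polyline."""
    if len(poly) < 2:
        return
    # dense resample for distance queries
    seg = np.hypot(np.diff(poly[:, 0]), np.diff(poly[:, 1]))
    total = float(seg.sum())
    n_dense = max(2, int(total / 0.35) + 1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    sd = np.linspace(0.0, total, n_dense)
    dense = np.column_stack(
        [np.interp(sd, s, poly[:, 0]), np.interp(sd, s, poly[:, 1])]
    )
    pad = core_halfwidth + soft_edge + 1.0
    rmin = max(0, int(poly[:, 0].min() - pad))
    rmax = min(img.shape[0], int(poly[:, 0].max() + pad) + 1)
    cmin = max(0, int(poly[:, 1].min() - pad))
    cmax = min(img.shape[1], int(poly[:, 1].max() + pad) + 1)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = cKDTree(dense).query(pts, k=1)
    dist = dist.reshape(rr.shape)
    profile = np.clip(1.0 - (dist - core_halfwidth) / soft_edge, 0.0, 1.0)
    np.maximum(
        img[rmin:rmax, cmin:cmax], intensity * profile, out=img[rmin:rmax, cmin:cmax]
    )


def render_field(
    spec: FieldSpec,
    seed: int,
    plate_id: str = "SIM",
    well: str = "A01",
    field_index: int = 1,
) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic 3-channel field; identical seed gives identical output.

    Channels are integer-quantized before background and Gaussian noise are
    added, so the noiseless geometry is exactly reproducible.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.image_shape)
    dapi = np.zeros(shape, dtype=np.float64)
    olig2 = np.zeros(shape, dtype=np.float64)
    mbp = np.zeros(shape, dtype=np.float64)
    truth = GroundTruth()

    n_olig2 = spec.n_olig2
    if spec.n_nuclei_total > 0:
        centers = _place_points(
            spec.n_nuclei_total, shape, spec.min_nucleus_distance_px, rng
        )
        for i, (r, c) in enumerate(centers):
            is_olig2 = i < n_olig2
            _stamp_gaussian(
                dapi, (r, c), spec.nucleus_sigma_px, _sample(spec.nucleus_amplitude, rng)
            )
            if is_olig2:
                _stamp_gaussian(
                    olig2, (r, c), spec.nucleus_sigma_px, _sample(spec.olig2_amplitude, rng)
                )
            truth.nuclei.append({"centroid": (float(r), float(c)), "is_olig2": is_olig2})

        # Olig2+ nuclei: [0:n_ol_diffuse] diffuse OLs, next n_ol_fibrous fibrous OLs
        for i in range(spec.n_ol_diffuse):
            r, c = centers[i]
            radius = spec.diffuse_blob_radius_px
            amp = _sample(spec.diffuse_intensity, rng)
            for _ in range(5):
                off = rng.uniform(-radius, radius, size=2)
                _stamp_disc(mbp, (r + off[0], c + off[1]), radius / 2.0, amp)
        for i in range(spec.n_ol_diffuse, spec.n_ol_diffuse + spec.n_ol_fibrous):
            r, c = centers[i]
            base_count = _sample_int(spec.fibers_per_ol, rng)
            if spec.fiber_density_multiplier == 1.0:
                count = base_count
            else:
                count = int(rng.poisson(base_count * spec.fiber_density_multiplier))
            for _ in range(count):
                # fibers radiate outward from the nucleus edge so that one
                # OL's fibers diverge instead of crossing at the soma
                angle = rng.uniform(0.0, 2.0 * math.pi)
                off = rng.uniform(6.0, 14.0)
                start = (r + off * math.sin(angle), c + off * math.cos(angle))
                length = _sample(spec.fiber_length_px, rng)
                intensity = _sample(spec.fiber_intensity, rng)
                poly = _fiber_polyline(start, angle, length, spec.fiber_waviness, shape)
                plen = _polyline_length(poly)
                if plen < 2.0:
                    continue
                _stamp_polyline(mbp, poly, intensity)
                truth.fibers.append(FiberTruth(poly, plen, intensity))

    # integer-quantized noiseless rendering
    dapi_q, olig2_q, mbp_q = np.round(dapi), np.round(olig2), np.round(mbp)
    truth.noiseless_mbp = mbp_q
    footprint = mbp_q > 0
    truth.mbp_footprint_area = int(footprint.sum())
    if n_olig2 > 0:
        truth.expected_mbp_score = float(mbp_q.sum()) / n_olig2
        truth.expected_fiber_score = (
            sum(f.path_length_px * f.mean_intensity for f in truth.fibers) / n_olig2
        )

    channels: dict[str, np.ndarray] = {}
    for name, clean in (("MBP", mbp_q), ("Olig2", olig2_q), ("DAPI", dapi_q)):
        img = clean + spec.background_level
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    image = FieldImage(plate_id, well, field_index, channels, spec.pixel_size_um)
    return image, truth


def render_single_fiber(
    shape: tuple[int, int] = (200, 200),
    start: tuple[float, float] = (50.0, 50.0),
    angle_deg: float = 0.0,
    length: float = 100.0,
    intensity: float = 1000.0,
    waviness: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one fiber on a blank raster; returns (image, planted polyline).

    Convenience for calibration and robustness checks (e.g. skeleton length
    versus fiber orientation).  Angle 0 runs along +columns, 90 along +rows.
    """
    img = np.zeros(shape, dtype=np.float64)
    poly = _fiber_polyline(start, math.radians(angle_deg), length, waviness, shape)
    _stamp_polyline(img, poly, intensity)
    return img, poly


# ---------------------------------------------------------------------------
# Dose-response simulation
# ---------------------------------------------------------------------------


def simulate_dose_response(
    bottom: float,
    top: float,
    ec50_uM: float,
    hill: float,
    doses: Sequence[float],
    replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a 4PL dose-response table (columns dose_uM, replicate, response)."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if ec50_uM <= 0:
        raise ValueError("ec50_uM must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    log_ec50 = math.log10(ec50_uM)
    for dose in doses:
        mean = bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - math.log10(dose)) * hill))
        for rep in range(1, replicates + 1):
            resp = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"dose_uM": float(dose), "replicate": rep, "response": float(resp)})
    return pd.DataFrame(rows, columns=["dose_uM", "replicate", "response"])


def serial_dilution(top_uM: float = 10.0, fold: float = 3.0, n: int = 8) -> np.ndarray:
    """A standard serial dilution series, highest concentration first."""
    return top_uM / fold ** np.arange(n)


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------


@dataclass
class PlantedHit:
    """A true promoter of myelination planted into a simulated screen."""

    compound_id: str
    effect_size: float = 3.0  # fiber-density multiplier at saturating dose
    ec50_uM: float = 0.55
    hill_slope: float = 1.0

    def multiplier(self, conc_uM: float) -> float:
        occ = 1.0 / (
            1.0 + 10.0 ** ((math.log10(self.ec50_uM) - math.log10(conc_uM)) * self.hill_slope)
        )
        return 1.0 + (self.effect_size - 1.0) * occ


@dataclass
class ScreenSpec:
    """Design + statistical field model of a simulated screen.

    The per-field model: fiber score = ``base_fiber_score`` x the condition's
    fiber-density multiplier x multiplicative noise; MBP score couples to the
    multiplier with strength ``mbp_coupling`` (differentiation rises less than
    myelination); Olig2+/DAPI counts are Poisson.  DAPT wells get
    ``control_effect`` and halve the Olig2+ count (the control's known
    pro-differentiation / anti-proliferation behaviour).
    """

    n_compounds: int = 727
    concentrations: tuple[float, ...] = (5.0, 1.0)
    planted_hits: list[PlantedHit] = dc_field(default_factory=list)
    planted_toxins: dict[str, float] = dc_field(default_factory=dict)  # cid -> olig2 mult
    control_effect: float = 2.0
    control_olig2_multiplier: float = 0.5
    plate_capacity: int = 44  # conditions per plate
    fields_per_well: int = 4
    base_fiber_score: float = 1000.0
    base_mbp_score: float = 950.0
    mbp_coupling: float = 0.25
    base_dapi_count: float = 150.0
    frac_olig2: float = 0.22
    field_cv: float = 0.10

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if self.control_effect <= 0:
            raise ValueError("control_effect must be > 0")
        valid = set(self.compound_ids())
        for hit in self.planted_hits:
            if hit.effect_size <= 0:
                raise ValueError("effect multipliers must be > 0")
            if hit.compound_id not in valid:
                raise ValueError(
                    f"planted hit {hit.compound_id!r} is not among the "
                    f"{self.n_compounds} library compounds"
                )
        for cid in self.planted_toxins:
            if cid not in valid:
                raise ValueError(f"planted toxin {cid!r} is not a library compound")

    def compound_ids(self) -> list[str]:
        return [f"C{i:04d}" for i in range(1, self.n_compounds + 1)]


@dataclass
class PlateData:
    layout: PlateLayout
    field_scores: dict[str, list[FieldScores]]
    images: dict[str, list[FieldImage]] | None = None  # well -> 4 fields


@dataclass
class ScreenResult:
    plates: list[PlateData]
    score_table: "object"  # ScoreTable
    truth: pd.DataFrame

    @property
    def layouts(self) -> list[PlateLayout]:
        return [p.layout for p in self.plates]


_ROWS = "ABCDEFGH"


def _plate_wells_96() -> list[str]:
    return [f"{r}{c:02d}" for r in _ROWS for c in range(1, 13)]


def _control_wells() -> dict[str, str]:
    """Fixed control positions: column 12, rows A-D DAPT, rows E-H DMSO."""
    out = {}
    for r in "ABCD":
        out[f"{r}12"] = "positive_control"
    for r in "EFGH":
        out[f"{r}12"] = "negative_control"
    return out


def _make_layouts(spec: ScreenSpec) -> list[PlateLayout]:
    conditions = [
        (cid, conc) for cid in spec.compound_ids() for conc in spec.concentrations
    ]
    layouts: list[PlateLayout] = []
    cap = spec.plate_capacity
    for p_idx in range(0, len(conditions), cap):
        chunk = conditions[p_idx : p_idx + cap]
        wells: dict[str, WellInfo] = {}
        for well, role in _control_wells().items():
            cid = "DAPT" if role == "positive_control" else "DMSO"
            conc = 1.0 if role == "positive_control" else 0.0
            wells[well] = WellInfo(role, cid, conc)
        test_wells = [w for w in _plate_wells_96() if w not in wells]
        for i, (cid, conc) in enumerate(chunk):
            for dup in range(2):
                wells[test_wells[2 * i + dup]] = WellInfo("test", cid, conc)
        layouts.append(PlateLayout(f"P{p_idx // cap + 1:03d}", wells))
    return layouts


def _condition_multipliers(
    spec: ScreenSpec, info: WellInfo
) -> tuple[float, float]:
    """(fiber-density multiplier, olig2-count multiplier) for a well."""
    if info.role == "positive_control":
        return spec.control_effect, spec.control_olig2_multiplier
    if info.role == "negative_control":
        return 1.0, 1.0
    mult, olig2_mult = 1.0, 1.0
    for hit in spec.planted_hits:
        if hit.compound_id == info.compound_id:
            mult = hit.multiplier(info.concentration_uM)
    if info.compound_id in spec.planted_toxins:
        olig2_mult = spec.planted_toxins[info.compound_id]
    return mult, olig2_mult


def _sample_field_scores(
    spec: ScreenSpec, mult: float, olig2_mult: float, rng: np.random.Generator
) -> FieldScores:
    """Draw one field's scores from the statistical field model."""
    n_dapi = int(rng.poisson(spec.base_dapi_count))
    n_olig2 = int(rng.poisson(spec.base_dapi_count * spec.frac_olig2 * olig2_mult))
    if n_olig2 == 0:
        return FieldScores(n_dapi, 0, None, None, None, usable=False)
    fiber = spec.base_fiber_score * mult * max(0.05, 1.0 + rng.normal(0.0, spec.field_cv))
    mbp = (
        spec.base_mbp_score
        * (1.0 + spec.mbp_coupling * (mult - 1.0))
        * max(0.05, 1.0 + rng.normal(0.0, spec.field_cv))
    )
    return FieldScores(n_dapi, n_olig2, mbp, fiber, fiber / mbp, usable=True)


def _field_seed(seed: int, plate_idx: int, well: str, field_idx: int) -> int:
    """Deterministic per-field sub-seed from (seed, plate, well, field)."""
    ss = np.random.SeedSequence([seed, plate_idx, _ROWS.index(well[0]), int(well[1:]), field_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _image_field_spec(spec: ScreenSpec, base: FieldSpec, mult: float, olig2_mult: float) -> FieldSpec:
    n_olig2_target = round(base.frac_olig2 * base.n_nuclei_total * olig2_mult)
    frac = n_olig2_target / base.n_nuclei_total if base.n_nuclei_total else 0.0
    n_ol = base.n_ol_diffuse + base.n_ol_fibrous
    scale = min(1.0, n_olig2_target / n_ol) if n_ol else 0.0
    return FieldSpec(
        image_shape=base.image_shape,
        n_nuclei_total=base.n_nuclei_total,
        frac_olig2=frac,
        n_ol_diffuse=int(base.n_ol_diffuse * scale),
        n_ol_fibrous=int(base.n_ol_fibrous * scale),
        fibers_per_ol=base.fibers_per_ol,
        fiber_length_px=base.fiber_length_px,
        fiber_intensity=base.fiber_intensity,
        fiber_waviness=base.fiber_waviness,
        fiber_density_multiplier=mult,
        diffuse_blob_radius_px=base.diffuse_blob_radius_px,
        diffuse_intensity=base.diffuse_intensity,
        nucleus_sigma_px=base.nucleus_sigma_px,
        nucleus_amplitude=base.nucleus_amplitude,
        olig2_amplitude=base.olig2_amplitude,
        min_nucleus_distance_px=base.min_nucleus_distance_px,
        background_level=base.background_level,
        noise_sd=base.noise_sd,
        pixel_size_um=base.pixel_size_um,
    )


def simulate_screen(
    spec: ScreenSpec,
    seed: int,
    render_images: bool = False,
    field_spec: FieldSpec | None = None,
    score_fields: bool = True,
) -> ScreenResult:
    """Simulate a whole screen honoring the plate design.

    With ``render_images`` the per-well fields are rendered as images and
    (when ``score_fields``) run through the full image pipeline; otherwise
    per-field scores come from the statistical field model directly.  Either
    way the result carries a normalized :class:`~myeliscreen.ScoreTable` and
    the planted truth table.
    """
    from .fiber_morphometrics import score_field  # local import avoids cycle at module load

    layouts = _make_layouts(spec)
    base = field_spec or FieldSpec()
    plates: list[PlateData] = []
    for p_idx, layout in enumerate(layouts):
        scores: dict[str, list[FieldScores]] = {}
        images: dict[str, list[FieldImage]] | None = {} if render_images else None
        for well in sorted(layout.wells):
            info = layout.wells[well]
            if info.role == "empty":
                continue
            mult, olig2_mult = _condition_multipliers(spec, info)
            well_scores: list[FieldScores] = []
            well_images: list[FieldImage] = []
            for f_idx in range(1, spec.fields_per_well + 1):
                fseed = _field_seed(seed, p_idx, well, f_idx)
                if render_images:
                    fspec = _image_field_spec(spec, base, mult, olig2_mult)
                    img, _ = render_field(fspec, fseed, layout.plate_id, well, f_idx)
                    well_images.append(img)
                    if score_fields:
                        well_scores.append(score_field(img))
                else:
                    rng = np.random.default_rng(fseed)
                    well_scores.append(_sample_field_scores(spec, mult, olig2_mult, rng))
            if well_scores:
                scores[well] = well_scores
            if images is not None:
                images[well] = well_images
        plates.append(PlateData(layout, scores, images))

    table = (
        build_score_table([(p.layout, p.field_scores) for p in plates])
        if (score_fields or not render_images)
        else None
    )

    truth_rows = []
    hit_by_id = {h.compound_id: h for h in spec.planted_hits}
    for cid in spec.compound_ids():
        hit = hit_by_id.get(cid)
        row = {
            "compound_id": cid,
            "is_hit": hit is not None,
            "effect_size": hit.effect_size if hit else 1.0,
            "ec50_uM": hit.ec50_uM if hit else float("nan"),
            "hill_slope": hit.hill_slope if hit else float("nan"),
            "olig2_multiplier": spec.planted_toxins.get(cid, 1.0),
        }
        for conc in spec.concentrations:
            m = hit.multiplier(conc) if hit else 1.0
            row[f"multiplier@{conc:g}"] = m
            row[f"expected_pct_dapt@{conc:g}"] = (
                100.0 * (m - 1.0) / (spec.control_effect - 1.0)
            )
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return ScreenResult(plates, table, truth)


def confirmation_tables(
    spec: ScreenSpec,
    compound_ids: Sequence[str],
    seed: int,
    n_experiments: int = 2,
    doses: Sequence[float] | None = None,
    replicates: int = 4,
    noise_sd: float = 5.0,
) -> dict[str, list[pd.DataFrame]]:
    """Simulate replicate dose-response confirmation experiments (%DAPT scale).

    Planted hits follow their planted 4PL curve (top = the %DAPT implied by
    their saturating effect); inactive compounds produce flat noise.
    """
    doses = np.asarray(doses if doses is not None else serial_dilution(), dtype=float)
    hit_by_id = {h.compound_id: h for h in spec.planted_hits}
    out: dict[str, list[pd.DataFrame]] = {}
    for i, cid in enumerate(compound_ids):
        tables = []
        for rep in range(n_experiments):
            sub_seed = int(
                np.random.SeedSequence([seed, i, rep]).generate_state(1)[0] % (2**31)
            )
            hit = hit_by_id.get(cid)
            if hit is not None:
                top = 100.0 * (hit.effect_size - 1.0) / (spec.control_effect - 1.0)
                tab = simulate_dose_response(
                    0.0, top, hit.ec50_uM, hit.hill_slope, doses, replicates, noise_sd, sub_seed
                )
            else:
                tab = simulate_dose_response(
                    0.0, 0.0, 1.0, 1.0, doses, replicates, noise_sd, sub_seed
                )
            tables.append(tab)
        out[cid] = tables
    return out
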