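"""Synthetic pelvis cohort generator with ground-truth deformations.

The phantom emulates the statistical structure a deformable dose-accumulation
(DDA) study of prostate radiotherapy relies on:

* a reference case per patient — parametric anatomy (ellipsoidal prostate/CTV
  with a thin urethra through it, an ellipsoidal bladder superiorly, a tubular
  rectum dorsally), a PTV from an anisotropic CTV margin (5 mm, 3 mm
  dorsally), and an analytic reference dose tuned to pass every planning
  objective (CTV D50% >= 60 Gy, D98% >= 57 Gy; OAR Dmax <= 61 Gy; rectum
  V56Gy < 13.5 %; bladder V56Gy < 18 %);
* per-fraction anatomy: a rigid prostate shift (systematic drift plus
  Gaussian noise) composed with smooth bladder/rectum filling changes into a
  single invertible displacement field, stored as ground truth;
* three arms of fraction doses: the static reference plan, a conv-IGRT
  simulation (reference dose rigidly translated by the shift an intensity
  registration finds), and an online-adaptive arm whose dose model is re-tuned
  each day on the fraction's own anatomy.

All randomness flows from a single seed; cohorts are bit-reproducible.

The dose model is deliberately analytic rather than optimizer-based: a
conformal plateau around the PTV with a sigmoidal penumbra, a urethra-sparing
dip, and a low-dose bath, with the plateau calibrated so the hottest OAR voxel
sits just under the 61 Gy planning limit — the near-constraint operating point
real optimized plans sit at.  Fraction 1 is generated without anatomical
variation, so the accumulation frame (fraction 1) coincides with the reference
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import registration
from .dvh import check_objectives, compute_dvps
from .grids import GridSpec, ScalarVolume, StructureMask, VectorField, sample_at_world, signed_distance

__all__ = [
    "PhantomParams",
    "PatientCase",
    "FractionRecord",
    "DoseModelParams",
    "PhantomGenerationError",
    "generate_reference_case",
    "sample_fraction_anatomy",
    "generate_fraction_doses",
    "generate_fraction",
    "generate_cohort",
    "evaluate_dose_model",
]


class PhantomGenerationError(RuntimeError):
    """Raised when anatomy or plan generation cannot satisfy its contract."""


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration.

    Volumes are in cm^3, lengths in mm, doses in Gy.  The per-fraction
    variation magnitudes (shift sd, drift, organ volume ranges) are generator
    configuration: they emulate interfraction prostate motion and bladder/
    rectum filling at clinically plausible scales.
    """

    n_patients: int = 10
    n_fractions: int = 20
    dose_per_fraction: float = 3.0
    prescription: float = 60.0
    ctv_margin_mm: float = 5.0
    ctv_margin_dorsal_mm: float = 3.0
    bladder_volume_range: tuple[float, float] = (140.0, 230.0)
    rectum_volume_range: tuple[float, float] = (30.0, 70.0)
    prostate_shift_sd: float = 2.0
    drift_mm_per_fraction: tuple[float, float, float] = (0.0, -0.4, 0.0)
    deformation_smoothness: float = 10.0
    spacing_mm: float = 2.0
    penumbra_mm: float = 2.5
    oar_dmax_headroom: float = 0.15
    urethra_sparing_frac: float = 0.035
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_fractions < 1:
            raise ValueError("n_patients and n_fractions must be >= 1")
        if abs(self.n_fractions * self.dose_per_fraction - self.prescription) > 1e-6:
            raise ValueError("n_fractions * dose_per_fraction must equal the prescription")
        for rng in (self.bladder_volume_range, self.rectum_volume_range):
            if not (0 < rng[0] <= rng[1]):
                raise ValueError("volume ranges must be positive and ordered")
        if self.prostate_shift_sd < 0 or self.spacing_mm <= 0:
            raise ValueError("shift sd must be >= 0 and spacing positive")


@dataclass
class DoseModelParams:
    """Analytic plan parameters produced by the objective tuner."""

    plateau_gy: float
    penumbra_mm: float
    edge_offset_mm: float
    urethra_dip_frac: float
    urethra_dip_sigma_mm: float = 4.0
    bath_frac: float = 0.22
    bath_range_mm: float = 60.0


@dataclass
class FractionRecord:
    """One treatment fraction: daily anatomy, ground truth, and arm doses."""

    index: int
    image: ScalarVolume
    structures: dict[str, StructureMask]
    gt_dvf_ref_to_fx: VectorField
    applied_shift: tuple[float, float, float]
    dose_oa: ScalarVolume | None = None
    dose_conv: ScalarVolume | None = None
    dose_model_oa: DoseModelParams | None = None


@dataclass
class PatientCase:
    """Reference anatomy, reference plan, and all fraction records."""

    patient_id: str
    params: PhantomParams
    ref_image: ScalarVolume
    ref_structures: dict[str, StructureMask]
    ref_dose: ScalarVolume
    dose_model: DoseModelParams
    fractions: list[FractionRecord] = field(default_factory=list)
    geometry: dict = field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return self.ref_image.grid

    def ref_sdt(self, label: str) -> np.ndarray:
        """Cached signed distance transform of a reference structure (mm)."""
        cache = self.__dict__.setdefault("_sdt_cache", {})
        if label not in cache:
            cache[label] = signed_distance(self.ref_structures[label].values, self.grid.spacing)
        return cache[label]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_FOV_LO = (-54.0, -58.0, -58.0)
_FOV_HI = (54.0, 58.0, 82.0)


def _make_grid(spacing: float) -> GridSpec:
    lo = np.asarray(_FOV_LO)
    hi = np.asarray(_FOV_HI)
    shape = tuple(int(np.floor((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(shape=shape, spacing=(spacing,) * 3, origin=tuple(lo))


def _sample_geometry(rng: np.random.Generator) -> dict:
    """Per-patient anatomical parameters (mm), jittered around a template.

    Axes: +x right, +y anterior, +z superior; dorsal is -y.
    """
    j = lambda lo, hi: float(rng.uniform(lo, hi))
    prostate_semi = np.array([21.0, 19.0, 19.0]) * rng.uniform(0.92, 1.08, 3)
    prostate_center = np.array([j(-1.5, 1.5), j(-1.0, 1.0), 0.0])
    rectum_radius = 11.0 * j(0.95, 1.08)
    # slight negative gap: the rectum wall drapes onto the prostate (the CTV is
    # carved out), so the anterior wall abuts the dorsal PTV as in real anatomy
    dorsal_gap = j(-1.5, 0.5)
    rectum_drape = j(2.5, 4.5)  # thickness of the wall sheet lining the prostate
    rectum_axis = np.array(
        [prostate_center[0] + j(-1.5, 1.5),
         prostate_center[1] - prostate_semi[1] - dorsal_gap - rectum_radius]
    )
    bladder_semi = np.array([36.0, 32.0, 26.0]) * rng.uniform(0.95, 1.05, 3)
    bladder_gap = j(-2.5, -0.5)  # bladder base drapes over the prostate apex
    bladder_center = np.array(
        [prostate_center[0] + j(-2.0, 2.0),
         prostate_center[1] + j(8.0, 14.0),
         prostate_center[2] + prostate_semi[2] + bladder_gap + bladder_semi[2]]
    )
    return {
        "prostate_center": prostate_center,
        "prostate_semi": prostate_semi,
        "urethra_radius": 3.0,
        "rectum_axis": rectum_axis,
        "rectum_radius": rectum_radius,
        "rectum_drape": rectum_drape,
        "rectum_z": (-50.0, 38.0),
        "bladder_center": bladder_center,
        "bladder_semi": bladder_semi,
    }


def _ellipsoid(centers: np.ndarray, c, semi) -> np.ndarray:
    d = (centers - np.asarray(c)[None, None, None, :]) / np.asarray(semi)[None, None, None, :]
    return (d**2).sum(axis=-1) <= 1.0


def _build_masks(grid: GridSpec, geo: dict) -> dict[str, StructureMask]:
    centers = grid.voxel_centers_world()
    ctv = _ellipsoid(centers, geo["prostate_center"], geo["prostate_semi"])
    bladder = _ellipsoid(centers, geo["bladder_center"], geo["bladder_semi"])
    ax, ay = geo["rectum_axis"]
    r2 = (centers[..., 0] - ax) ** 2 + (centers[..., 1] - ay) ** 2
    z = centers[..., 2]
    rectum = (r2 <= geo["rectum_radius"] ** 2) & (z >= geo["rectum_z"][0]) & (z <= geo["rectum_z"][1])
    # anterior-wall lip draped along the dorsal prostate surface
    sdt_ctv = signed_distance(ctv, grid.spacing)
    semi = geo["prostate_semi"]
    pc = geo["prostate_center"]
    lip = (
        (sdt_ctv > 0)
        & (sdt_ctv <= geo["rectum_drape"])
        & (centers[..., 1] < pc[1] - 0.45 * semi[1])
        & (np.abs(centers[..., 0] - pc[0]) < 0.85 * semi[0])
        & (np.abs(centers[..., 2] - pc[2]) < 0.8 * semi[2])
    )
    rectum |= lip
    ur2 = (centers[..., 0] - pc[0]) ** 2 + (centers[..., 1] - pc[1]) ** 2
    urethra = (ur2 <= geo["urethra_radius"] ** 2) & ctv
    # enforce pairwise disjointness of CTV vs OARs (CTV wins at the interface)
    bladder &= ~ctv
    rectum &= ~ctv & ~bladder
    masks = {
        "CTV": StructureMask(grid, ctv, "CTV"),
        "bladder": StructureMask(grid, bladder, "bladder"),
        "rectum": StructureMask(grid, rectum, "rectum"),
        "urethra": StructureMask(grid, urethra, "urethra"),
    }
    masks["PTV"] = make_ptv(masks["CTV"])
    return masks


def make_ptv(ctv: StructureMask, margin_mm: float = 5.0, dorsal_margin_mm: float = 3.0) -> StructureMask:
    """CTV dilated anisotropically: ``margin_mm`` everywhere, less dorsally.

    The admissible margin shrinks linearly with the dorsal component of the
    direction from the nearest CTV surface point (dorsal = -y), reaching
    ``dorsal_margin_mm`` for straight-dorsal expansion.
    """
    sp = np.asarray(ctv.grid.spacing)
    dist, idx = ndimage.distance_transform_edt(~ctv.values, sampling=sp, return_indices=True)
    own = np.indices(ctv.values.shape)
    delta = (own - idx) * sp[:, None, None, None]  # vector nearest-CTV -> voxel
    norm = np.sqrt((delta**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        dorsalness = np.where(norm > 0, np.clip(-delta[1] / np.maximum(norm, 1e-9), 0.0, 1.0), 0.0)
    allowed = margin_mm - (margin_mm - dorsal_margin_mm) * dorsalness
    ptv = ctv.values | (dist <= allowed)
    return StructureMask(ctv.grid, ptv, "PTV")


def _build_image(grid: GridSpec, masks: dict[str, StructureMask], rng: np.random.Generator) -> ScalarVolume:
    """T2w-like intensity volume: organ levels, prostate texture, mild noise."""
    img = np.full(grid.shape, 0.25, dtype=np.float32)
    img[masks["rectum"].values] = 0.12
    img[masks["CTV"].values] = 0.55
    img[masks["bladder"].values] = 0.78
    img[masks["urethra"].values] = 0.40
    img = ndimage.gaussian_filter(img, sigma=1.2)
    # seeded intra-prostatic texture (zonal-anatomy surrogate) so intensity
    # registration is well-posed along every axis
    centers = grid.voxel_centers_world()
    ctv_idx = np.argwhere(masks["CTV"].values)
    soft_ctv = ndimage.gaussian_filter(masks["CTV"].values.astype(np.float32), sigma=1.0)
    for _ in range(16):
        c = grid.index_to_world(ctv_idx[rng.integers(ctv_idx.shape[0])])
        amp = rng.uniform(-0.18, 0.18)
        d2 = ((centers - c[None, None, None, :]) ** 2).sum(axis=-1)
        img += amp * np.exp(-d2 / (2 * 4.0**2)).astype(np.float32) * soft_ctv
    img += ndimage.gaussian_filter(
        rng.normal(0.0, 0.05, grid.shape).astype(np.float32), sigma=1.0
    )
    return ScalarVolume(grid, img.astype(np.float32))


# ---------------------------------------------------------------------------
# Analytic dose model and objective tuner
# ---------------------------------------------------------------------------

def evaluate_dose_model(
    model: DoseModelParams,
    sdt_ptv: np.ndarray,
    sdt_urethra: np.ndarray,
) -> np.ndarray:
    """Total dose (Gy) from the analytic model.

    ``sdt_ptv``/``sdt_urethra`` are signed distances (mm, negative inside).
    The conformal term is a logistic penumbra whose 50 % level sits
    ``edge_offset_mm`` outside the PTV; a Gaussian urethra-sparing dip
    multiplies the conformal term; a slowly decaying low-dose bath fills the
    periphery.
    """
    s = np.asarray(sdt_ptv, dtype=np.float32)
    conf = 1.0 / (1.0 + np.exp(np.clip((s - model.edge_offset_mm) / model.penumbra_mm, -40, 40)))
    du = np.maximum(np.asarray(sdt_urethra, dtype=np.float32), 0.0)
    dip = 1.0 - model.urethra_dip_frac * np.exp(-(du**2) / (2 * model.urethra_dip_sigma_mm**2))
    bath = model.bath_frac * np.exp(-np.maximum(s, 0.0) / model.bath_range_mm) * (1.0 - conf)
    return (model.plateau_gy * (conf * dip + bath)).astype(np.float32)


_OAR_LABELS = ("bladder", "rectum", "urethra")


def tune_dose_model(
    grid: GridSpec,
    masks: dict[str, StructureMask],
    prescription: float,
    penumbra_mm: float = 2.5,
    headroom_gy: float = 0.15,
    v56_aim_margin: float = 1.0,
    urethra_sparing_frac: float = 0.035,
    reference_volumes_cm3: dict[str, float] | None = None,
    max_outer_iterations: int = 25,
) -> tuple[ScalarVolume, DoseModelParams]:
    """Calibrate the analytic plan to the planning objectives.

    The plateau is set (the model is linear in it) so the hottest OAR voxel
    lands at ``61 - headroom_gy`` Gy — the near-constraint operating point of
    optimized plans; penumbra width and edge offset are then adjusted until
    every objective passes.  The V56Gy objectives are tuned against an aim
    ``v56_aim_margin`` percentage points below the clinical limit, the usual
    planning-aim practice, so a passing plan keeps a small reserve.  Raises
    :class:`PhantomGenerationError` naming the violated objective if the
    iteration budget is exhausted.
    """
    sp = grid.spacing
    sdt_ptv = signed_distance(masks["PTV"].values, sp)
    sdt_ur = signed_distance(masks["urethra"].values, sp)
    oar_sel = {lab: masks[lab].values for lab in _OAR_LABELS}
    model = DoseModelParams(
        plateau_gy=prescription * 1.01,
        penumbra_mm=penumbra_mm,
        edge_offset_mm=8.0,
        urethra_dip_frac=urethra_sparing_frac,
    )
    dmax_target = 61.0 - headroom_gy

    last_failures: dict = {}
    for _ in range(max_outer_iterations):
        # the model is linear in the plateau, so the plateau placing the
        # hottest OAR voxel exactly at dmax_target is a single division
        unit = evaluate_dose_model(replace(model, plateau_gy=1.0), sdt_ptv, sdt_ur)
        factor = max(float(unit[sel].max()) for sel in oar_sel.values())
        plateau = float(
            np.clip(dmax_target / max(factor, 1e-9), prescription * 0.985, prescription * 1.08)
        )
        model = replace(model, plateau_gy=plateau)
        dose = ScalarVolume(grid, evaluate_dose_model(model, sdt_ptv, sdt_ur))
        dvps = compute_dvps(dose, {k: masks[k] for k in ("CTV", *_OAR_LABELS)})
        checks = check_objectives(dvps)
        # V56 aims are enforced as absolute volumes against the planning-time
        # organ volume (the usual cc-style constraint), so daily distension
        # cannot dilute the percentage and mask a growing high-dose crescent
        v56_tight = {}
        for k, lab in (("rectum_V56", "rectum"), ("bladder_V56", "bladder")):
            vol_now = masks[lab].volume_cm3
            vol_ref = (reference_volumes_cm3 or {}).get(lab, vol_now)
            value_cc = checks[k]["value"] / 100.0 * vol_now
            cap_cc = (checks[k]["limit"] - v56_aim_margin) / 100.0 * vol_ref
            v56_tight[k] = value_cc < cap_cc
        last_failures = {
            k: v for k, v in checks.items() if not v["pass"] and k not in v56_tight
        }
        last_failures.update({k: checks[k] for k, ok in v56_tight.items() if not ok})
        if not last_failures:
            return dose, model
        if not checks["CTV_D98"]["pass"] or not checks["CTV_D50"]["pass"]:
            model = replace(model, penumbra_mm=model.penumbra_mm * 0.88)
        if not all(v56_tight.values()):
            model = replace(model, edge_offset_mm=model.edge_offset_mm - 0.5)
        if not checks["urethra_Dmax"]["pass"]:
            model = replace(model, urethra_dip_frac=model.urethra_dip_frac + 0.01)
    worst = ", ".join(sorted(last_failures))
    raise PhantomGenerationError(f"dose tuner could not satisfy objectives: {worst}")


# ---------------------------------------------------------------------------
# Reference case
# ---------------------------------------------------------------------------

def generate_reference_case(params: PhantomParams, patient_seed: int) -> PatientCase:
    """Build one patient's reference anatomy, image and tuned reference plan.

    Deterministic in ``(params, patient_seed)``; the returned case has no
    fractions yet.  The reference dose is guaranteed to pass
    :func:`ddacc.dvh.check_objectives`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, int(patient_seed), 11]))
    grid = _make_grid(params.spacing_mm)
    geo = _sample_geometry(rng)
    masks = _build_masks(grid, geo)
    for lab in ("CTV", "PTV", "bladder", "rectum", "urethra"):
        if not masks[lab].values.any():
            raise PhantomGenerationError(f"empty structure generated: {lab}")
    image = _build_image(grid, masks, rng)
    dose, model = tune_dose_model(
        grid, masks, params.prescription,
        penumbra_mm=params.penumbra_mm, headroom_gy=params.oar_dmax_headroom,
        urethra_sparing_frac=params.urethra_sparing_frac,
    )
    return PatientCase(
        patient_id=f"P{patient_seed:03d}",
        params=params,
        ref_image=image,
        ref_structures=masks,
        ref_dose=dose,
        dose_model=model,
        geometry=geo,
    )


# ---------------------------------------------------------------------------
# Per-fraction deformation
# ---------------------------------------------------------------------------

def _taper(d: np.ndarray, r0: float, r1: float) -> np.ndarray:
    """1 for d <= r0, smooth cosine ramp to 0 at d >= r1."""
    t = np.clip((np.asarray(d, dtype=np.float32) - r0) / max(r1 - r0, 1e-6), 0.0, 1.0)
    return (0.5 * (1.0 + np.cos(np.pi * t))).astype(np.float32)


def _organ_scale_field(
    centers: np.ndarray,
    sdt_organ: np.ndarray,
    center_pt: np.ndarray,
    scale: float,
    guard: np.ndarray,
    radial_axes: tuple[int, ...],
    reach_mm: float,
    saturation_mm: float = 80.0,
) -> np.ndarray:
    """Pull-back displacement realizing a smooth expansion/contraction.

    ``out(x) = ref(x + u)`` with ``u = (c - x) (1 - 1/a)`` inside the organ:
    sampling closer to the center enlarges the organ for a > 1.  The kernel is
    1 out to the maximal boundary excursion and decays over ``reach_mm``; the
    ``guard`` factor (0 near the CTV) decouples the prostate.
    """
    u = np.zeros((*sdt_organ.shape, 3), dtype=np.float32)
    if abs(scale - 1.0) < 1e-9:
        return u
    r0 = 2.0 + max(0.0, scale - 1.0) * 30.0
    # reach grows with the boundary excursion so the kernel's strain stays
    # well below folding even for large filling changes
    reach = reach_mm + 3.0 * abs(1.0 - 1.0 / scale) * 40.0
    g = _taper(sdt_organ, r0, r0 + reach) * guard
    lever = np.zeros(sdt_organ.shape, dtype=np.float32)
    for ax in radial_axes:
        lever += (center_pt[ax] - centers[..., ax]) ** 2
    np.sqrt(lever, out=lever)
    # saturate the lever arm so the displacement magnitude (and hence the
    # strain against the rigid-prostate guard) stays bounded
    damp = np.minimum(1.0, saturation_mm / np.maximum(lever, 1e-6))
    coeff = (1.0 - 1.0 / scale) * g * damp
    for ax in radial_axes:
        u[..., ax] = coeff * (center_pt[ax] - centers[..., ax])
    return u


def _guard(case: PatientCase) -> np.ndarray:
    """0 inside/near the CTV, 1 beyond 7 mm: decouples organ terms from the prostate."""
    return 1.0 - _taper(case.ref_sdt("CTV"), 0.0, 7.0)


def _organ_term(
    case: PatientCase, centers: np.ndarray, label: str, scale: float, guard: np.ndarray
) -> np.ndarray:
    geo = case.geometry
    if label == "bladder":
        # scaling about the (tethered) bladder base: filling expands the dome
        # superior/anteriorly while the base stays put, as on repeat imaging
        center = np.asarray(geo["bladder_center"], dtype=np.float32).copy()
        center[2] -= 0.8 * float(geo["bladder_semi"][2])
        axes: tuple[int, ...] = (0, 1, 2)
        saturation = 80.0
    else:
        center = np.array([geo["rectum_axis"][0], geo["rectum_axis"][1], 0.0], dtype=np.float32)
        axes = (0, 1)
        saturation = 13.0
    return _organ_scale_field(
        centers, case.ref_sdt(label), center, scale, guard, axes, 12.0, saturation
    )


def _fraction_displacement(
    case: PatientCase,
    shift: np.ndarray,
    bladder_scale: float,
    rectum_scale: float,
    rectum_push_mm: float = 0.0,
) -> np.ndarray:
    grid = case.grid
    centers = grid.voxel_centers_world().astype(np.float32)
    sdt_ctv = case.ref_sdt("CTV")
    guard = _guard(case)

    # rigid prostate shift: weight 1 over the swept CTV volume, smooth decay
    smooth = case.params.deformation_smoothness
    t_mag = float(np.linalg.norm(shift))
    d_union = sdt_ctv.copy()
    if t_mag > 0.25:
        for frac in (0.5, 1.0):
            pts = centers - (frac * shift)[None, None, None, :].astype(np.float32)
            d_union = np.minimum(d_union, sample_at_world(sdt_ctv, grid, pts, order=1, cval=1e3))
        # the min-composition has creases; smooth before tapering so the
        # resulting kernel (and its Jacobian) stays well behaved
        d_union = ndimage.gaussian_filter(d_union, sigma=1.0) - 1.0
    g_p = _taper(d_union, 1.0, 1.0 + smooth + 1.3 * t_mag)
    u_shift = (-shift)[None, None, None, :].astype(np.float32) * g_p[..., None]

    components = [u_shift]
    components.append(_organ_term(case, centers, "bladder", bladder_scale, guard))
    components.append(_organ_term(case, centers, "rectum", rectum_scale, guard))
    if abs(rectum_push_mm) > 1e-9:
        # rectal filling/gas displacing the anterior wall toward (or away
        # from) the prostate: anterior push of the interface zone, vanishing
        # inside the rigid CTV; this is the component a translation-only
        # correction cannot compensate
        w_push = _taper(case.ref_sdt("rectum"), 0.0, 16.0) * (
            1.0 - _taper(sdt_ctv, 0.0, 6.0)
        )
        u_push = np.zeros((*grid.shape, 3), dtype=np.float32)
        u_push[..., 1] = -rectum_push_mm * w_push
        components.append(u_push)

    # compose the component pull-back maps rather than summing them: the
    # composition of individually fold-free maps stays fold-free even where
    # their strain fields overlap (sums do not)
    u: np.ndarray | None = None
    for comp in components:
        if not np.any(comp):
            continue
        if u is None:
            u = comp
            continue
        pts = centers + u
        u = u + np.stack(
            [sample_at_world(comp[..., i], grid, pts, order=1) for i in range(3)],
            axis=-1,
        ).astype(np.float32)
    if u is None:
        u = np.zeros((*grid.shape, 3), dtype=np.float32)
    return u


def _calibrate_scale(case: PatientCase, label: str, target_cm3: float, exponent: float) -> float:
    """Two Newton-like corrections so the warped organ hits its target volume."""
    ref_vol = case.ref_structures[label].volume_cm3
    centers = case.grid.voxel_centers_world().astype(np.float32)
    guard = _guard(case)
    scale = (target_cm3 / ref_vol) ** exponent
    for _ in range(2):
        u = _organ_term(case, centers, label, scale, guard)
        warped = registration.apply_field_to_mask(
            case.ref_structures[label], VectorField(case.grid, u)
        )
        measured = warped.volume_cm3
        if measured <= 0:
            break
        scale *= (target_cm3 / measured) ** exponent
    return scale


def sample_fraction_anatomy(
    case: PatientCase, index: int, params: PhantomParams, seed: int | None = None
) -> FractionRecord:
    """Sample one fraction's anatomy and its ground-truth deformation.

    Fraction 1 carries zero variation (it is the accumulation reference).  The
    prostate shift is ``drift * index + N(0, sd^2)`` per axis; bladder/rectum
    volumes are drawn uniformly from the configured ranges and realized as
    smooth radial scalings decoupled from the (rigid) prostate.  The composed
    field is checked to be fold-free; folding triggers a resample with fresh
    draws, then an error.
    """
    if not 1 <= index <= params.n_fractions:
        raise ValueError(f"fraction index {index} outside 1..{params.n_fractions}")
    grid = case.grid
    if index == 1:
        dvf = VectorField.identity(grid)
        return FractionRecord(
            index=1,
            image=case.ref_image.copy(),
            structures={k: m.copy() for k, m in case.ref_structures.items()},
            gt_dvf_ref_to_fx=dvf,
            applied_shift=(0.0, 0.0, 0.0),
        )
    base_seed = params.seed if seed is None else seed
    for attempt in range(5):
        rng = np.random.default_rng(
            np.random.SeedSequence([base_seed, int(case.patient_id[1:]), index, 7 + attempt])
        )
        drift = np.asarray(params.drift_mm_per_fraction) * index
        shift = drift + rng.normal(0.0, params.prostate_shift_sd, 3)
        shift = np.clip(shift, -10.0, 10.0)
        # targets are drawn from a slightly inset sub-range: the volume
        # calibration is iterative and its ~1-2% residual must not push the
        # realized volume outside the configured interval
        def _draw_inset(lo_hi: tuple[float, float]) -> float:
            lo, hi = lo_hi
            inset = 0.04 * (hi - lo)
            return float(rng.uniform(lo + inset, hi - inset))

        bl_target = _draw_inset(params.bladder_volume_range)
        re_target = _draw_inset(params.rectum_volume_range)
        bl_scale = _calibrate_scale(case, "bladder", bl_target, 1.0 / 3.0)
        re_scale = _calibrate_scale(case, "rectum", re_target, 1.0 / 2.0)
        # filling-correlated anterior push of the rectum-prostate interface;
        # the stochastic part scales with the configured filling variability so
        # a degenerate (zero-variance) configuration deforms nothing
        push_sd = 0.8 * (params.rectum_volume_range[1] - params.rectum_volume_range[0]) / 40.0
        push = float(
            np.clip(
                1.5 * (re_scale - 1.0) * case.geometry["rectum_radius"]
                + rng.normal(0.0, push_sd),
                -2.0,
                2.8,
            )
        )
        u = _fraction_displacement(case, shift, bl_scale, re_scale, rectum_push_mm=push)
        dvf = VectorField(grid, u)
        jac = registration.jacobian_determinant(dvf)
        if jac.min() > 0.05:
            break
    else:
        raise PhantomGenerationError(
            f"fraction {index}: displacement field folds (min |J| = {jac.min():.3f})"
        )
    image = registration.apply_field_to_volume(case.ref_image, dvf, cval=0.2)
    structures = {
        lab: registration.apply_field_to_mask(case.ref_structures[lab], dvf)
        for lab in ("CTV", "bladder", "rectum", "urethra")
    }
    structures["PTV"] = make_ptv(
        structures["CTV"], params.ctv_margin_mm, params.ctv_margin_dorsal_mm
    )
    return FractionRecord(
        index=index,
        image=image,
        structures=structures,
        gt_dvf_ref_to_fx=dvf,
        applied_shift=tuple(float(s) for s in shift),
    )


# ---------------------------------------------------------------------------
# Fraction doses
# ---------------------------------------------------------------------------

def generate_fraction_doses(
    case: PatientCase, fx: FractionRecord, params: PhantomParams
) -> FractionRecord:
    """Fill the OA and conv-IGRT fraction doses of one fraction record.

    OA arm: the analytic dose model is re-tuned on the fraction's own anatomy
    (daily re-plan surrogate) and scaled to one fraction.  conv arm: the
    reference dose is rigidly translated by the shift
    :func:`ddacc.registration.rigid_translate_register` finds between the
    reference and fraction images, then scaled to one fraction.
    """
    grid = case.grid
    n = params.n_fractions
    # daily re-plans aim 2 points under the V56 limits (vs 1 for the static
    # reference plan): adaptive planning hedges the dose it will accumulate
    # across the course, a tighter daily aim being the online equivalent of a
    # plan-robustness margin
    total_oa, model_oa = tune_dose_model(
        grid, fx.structures, params.prescription,
        penumbra_mm=params.penumbra_mm, headroom_gy=params.oar_dmax_headroom,
        v56_aim_margin=2.0,
        urethra_sparing_frac=params.urethra_sparing_frac,
        reference_volumes_cm3={
            lab: case.ref_structures[lab].volume_cm3 for lab in ("rectum", "bladder")
        },
    )
    fx.dose_oa = ScalarVolume(grid, (total_oa.values / n).astype(np.float32))
    fx.dose_model_oa = model_oa

    shift = registration.rigid_translate_register(
        moving=case.ref_image, fixed=fx.image, bbox_mask=case.ref_structures["CTV"]
    )
    tau = np.asarray(shift, dtype=np.float32)
    const_field = VectorField(grid, np.broadcast_to(-tau, (*grid.shape, 3)).copy())
    conv_total = registration.apply_field_to_volume(case.ref_dose, const_field)
    fx.dose_conv = ScalarVolume(grid, (conv_total.values / n).astype(np.float32))
    return fx


def generate_fraction(case: PatientCase, index: int, params: PhantomParams) -> FractionRecord:
    fx = sample_fraction_anatomy(case, index, params)
    return generate_fraction_doses(case, fx, params)


def generate_cohort(params: PhantomParams, progress: bool = False) -> list[PatientCase]:
    """Generate the full cohort: ``n_patients`` cases with complete fractions.

    Per-patient seeds derive deterministically from the master seed; the same
    parameters always produce bit-identical cohorts.
    """
    cases = []
    for p in range(1, params.n_patients + 1):
        case = generate_reference_case(params, p)
        for k in range(1, params.n_fractions + 1):
            case.fractions.append(generate_fraction(case, k, params))
            if progress:
                print(f"{case.patient_id}: fraction {k}/{params.n_fractions}", flush=True)
        cases.append(case)
    return cases
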