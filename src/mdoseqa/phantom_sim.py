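"""Synthetic patient-phantom generator.

Stands in for a clinical VMAT cohort: each case carries a CT volume with a
skin boundary and a bone insert, target/OAR masks, a smooth
prescription-normalized planned dose (RTDose), and a measurement-like dose
(MDose) that deviates from the plan through smoothing, low-frequency
calibration drift, a skin-shell boundary artifact and noise — the deviation
structure a measurement-guided dose-prediction model has to learn.

Everything is a pure function of ``(spec, seed)``: the same inputs reproduce
bitwise-identical cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .core import PatientCase, StructureSet, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "CohortRanges",
    "generate_ct",
    "generate_rtdose",
    "perturb_to_mdose",
    "generate_cohort",
]

HU_AIR = -1000.0
HU_BONE = 700.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and dosimetric parameters of one synthetic phantom.

    All lengths in mm, doses in Gy; tuples are in (z, y, x) order.
    """

    grid_shape: Tuple[int, int, int] = (32, 64, 64)
    spacing: Tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_semiaxes: Tuple[float, float, float] = (40.0, 75.0, 68.0)
    ptv_center: Tuple[float, float, float] = (0.0, 10.0, 12.0)  # offset from body center
    ptv_semiaxes: Tuple[float, float, float] = (16.0, 22.0, 19.0)
    n_oars: int = 2
    prescription_dose: float = 70.0
    dose_falloff_sigma: float = 12.0
    bath_fraction: float = 0.05

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        if not (0.0 <= self.bath_fraction < 1.0):
            raise ValueError("bath_fraction must be in [0, 1)")
        if self.dose_falloff_sigma <= 0:
            raise ValueError("dose_falloff_sigma must be positive")
        # grid must cover the body ellipsoid plus a >= 5 mm margin
        for ax in range(3):
            half_extent = 0.5 * self.grid_shape[ax] * self.spacing[ax]
            if self.body_semiaxes[ax] + 5.0 > half_extent:
                raise ValueError(
                    f"grid too small along axis {ax}: body semiaxis "
                    f"{self.body_semiaxes[ax]} mm + 5 mm margin exceeds half "
                    f"extent {half_extent} mm"
                )
        # PTV ellipsoid strictly inside the body ellipsoid (sampled check)
        theta = np.linspace(0, np.pi, 13)
        phi = np.linspace(0, 2 * np.pi, 25)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        pz = self.ptv_center[0] + self.ptv_semiaxes[0] * np.cos(tt)
        py = self.ptv_center[1] + self.ptv_semiaxes[1] * np.sin(tt) * np.cos(pp)
        px = self.ptv_center[2] + self.ptv_semiaxes[2] * np.sin(tt) * np.sin(pp)
        r2 = (
            (pz / self.body_semiaxes[0]) ** 2
            + (py / self.body_semiaxes[1]) ** 2
            + (px / self.body_semiaxes[2]) ** 2
        )
        if np.any(r2 >= 1.0):
            raise ValueError("PTV ellipsoid is not strictly inside the body ellipsoid")


@dataclass(frozen=True)
class PerturbationSpec:
    """Plan-to-measurement deviation model.

    ``MDose = smooth(RTDose) * (1 + calib_amplitude * G) + boundary_amplitude * S + noise``

    where ``G`` is a seeded smooth random field with unit max amplitude and
    correlation length ``calib_length_scale`` and ``S`` indicates the tissue
    shell within ``boundary_shell`` mm inside the body surface (the region
    where measured doses disagree most with the plan in practice: near the
    skin and immobilization-mask indentations).
    """

    smooth_sigma: float = 3.0          # mm, >= 0
    calib_amplitude: float = 0.02      # fraction, >= 0
    calib_length_scale: float = 30.0   # mm
    boundary_amplitude: float = 3.0    # Gy, >= 0
    boundary_shell: float = 6.0        # mm, >= 0
    noise_sigma: float = 0.5           # Gy, >= 0
    seed: int = 0

    def validate(self) -> None:
        vals = (
            self.smooth_sigma,
            self.calib_amplitude,
            self.calib_length_scale,
            self.boundary_amplitude,
            self.boundary_shell,
            self.noise_sigma,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("perturbation parameters must be finite")
        if min(vals) < 0:
            raise ValueError("perturbation parameters must be non-negative")


def _centered_grid(spec: PhantomSpec):
    """Voxel-center coordinates (mm) relative to the grid center."""
    axes = []
    for ax in range(3):
        n, s = spec.grid_shape[ax], spec.spacing[ax]
        axes.append((np.arange(n) - (n - 1) / 2.0) * s)
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(coords, center, semiaxes) -> np.ndarray:
    r2 = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semiaxes))
    return r2 <= 1.0


def generate_ct(spec: PhantomSpec, seed: int = 0) -> tuple[VolumeGrid, StructureSet]:
    """Build the CT volume (HU) and the structure masks for one phantom.

    HU layout: air (−1000) outside the body ellipsoid; soft tissue in
    [0, 60] inside with a smooth seeded texture; a 2.5 mm skin shell; one
    bone insert (+700) posterior to the target.  Structures: BODY, PTV and
    ``n_oars`` lateral OAR ellipsoids.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    zz, yy, xx = coords = _centered_grid(spec)

    body = _ellipsoid_mask(coords, (0.0, 0.0, 0.0), spec.body_semiaxes)

    # soft-tissue texture: 40 HU baseline with smooth +-12 HU variation
    texture = rng.standard_normal(spec.grid_shape)
    texture = ndimage.gaussian_filter(texture, sigma=[20.0 / s for s in spec.spacing])
    tmax = np.max(np.abs(texture))
    if tmax > 0:
        texture = texture / tmax
    hu = np.full(spec.grid_shape, HU_AIR)
    hu[body] = np.clip(40.0 + 12.0 * texture[body], 0.0, 60.0)

    # skin shell: voxels within 2.5 mm inside the body surface, slightly denser
    inside_depth = ndimage.distance_transform_edt(body, sampling=spec.spacing)
    skin = body & (inside_depth <= 2.5)
    hu[skin] = 55.0

    # bone insert: spine-like cylinder along z, posterior to the target
    bone_center_y = -0.55 * spec.body_semiaxes[1]
    bone = (
        body
        & ((yy - bone_center_y) ** 2 + xx**2 <= 9.0**2)
        & (np.abs(zz) <= 0.7 * spec.body_semiaxes[0])
    )
    hu[bone] = HU_BONE

    ct = VolumeGrid(hu.astype(np.float32), spec.spacing)
    structures = StructureSet(ct)
    structures.add("BODY", body)
    ptv = _ellipsoid_mask(coords, spec.ptv_center, spec.ptv_semiaxes)
    structures.add("PTV", ptv)

    # OARs: small ellipsoids flanking the PTV laterally, clipped to the body
    for k in range(spec.n_oars):
        side = 1 if k % 2 == 0 else -1
        cx = spec.ptv_center[2] + side * (spec.ptv_semiaxes[2] + 14.0)
        center = (spec.ptv_center[0], spec.ptv_center[1] - 4.0, cx)
        oar = _ellipsoid_mask(coords, center, (8.0, 9.0, 9.0)) & body
        structures.add(f"OAR_{k + 1}", oar)
    return ct, structures


def generate_rtdose(spec: PhantomSpec, structures: StructureSet) -> VolumeGrid:
    """Deterministic smooth planned dose.

    Prescription inside the PTV, Gaussian falloff with ``dose_falloff_sigma``
    outside it, plus a ``bath_fraction``-scaled low-dose bath inside BODY;
    zero outside the body.
    """
    spec.validate()
    for name in ("PTV", "BODY"):
        if name not in structures:
            raise ValueError(f"structure set is missing {name!r}")
    ptv = structures["PTV"]
    body = structures["BODY"]
    if not ptv.any():
        raise ValueError("PTV mask is empty")

    dist = ndimage.distance_transform_edt(~ptv, sampling=spec.spacing)
    rx = spec.prescription_dose
    dose = rx * np.exp(-(dist**2) / (2.0 * spec.dose_falloff_sigma**2))
    dose += spec.bath_fraction * rx
    dose[~body] = 0.0
    return structures.grid.copy_with(dose.astype(np.float64))


def _smooth_unit_field(shape, spacing, length_scale, rng) -> np.ndarray:
    """Seeded voxel noise low-pass filtered to ``length_scale`` and max-normalized."""
    g = rng.standard_normal(shape)
    g = ndimage.gaussian_filter(g, sigma=[length_scale / s for s in spacing])
    m = np.max(np.abs(g))
    return g / m if m > 0 else g


def perturb_to_mdose(
    rtdose: VolumeGrid,
    ct: VolumeGrid,
    structures: StructureSet,
    pert: PerturbationSpec,
) -> VolumeGrid:
    """Derive the measurement-like dose from the plan.

    Zero-amplitude parameters reproduce the plan exactly.  Noise is truncated
    at ±3σ and the result is clipped at 0 Gy.
    """
    pert.validate()
    rtdose.require_same_geometry(ct, "RTDose and CT")
    rtdose.require_same_geometry(structures.grid, "RTDose and structures")
    if "BODY" not in structures:
        raise ValueError("structure set is missing 'BODY'")

    if (
        pert.smooth_sigma == 0
        and pert.calib_amplitude == 0
        and pert.boundary_amplitude == 0
        and pert.noise_sigma == 0
    ):
        return rtdose.copy_with(rtdose.data.copy())

    rng = np.random.default_rng(pert.seed)
    spacing = rtdose.spacing
    dose = np.asarray(rtdose.data, dtype=np.float64)

    if pert.smooth_sigma > 0:
        dose = ndimage.gaussian_filter(dose, sigma=[pert.smooth_sigma / s for s in spacing])

    # calibration drift field is drawn even at zero amplitude so that the
    # same seed yields the same field when only amplitudes change
    calib = _smooth_unit_field(dose.shape, spacing, pert.calib_length_scale, rng)
    dose = dose * (1.0 + pert.calib_amplitude * calib)

    if pert.boundary_amplitude > 0:
        body = structures["BODY"]
        depth = ndimage.distance_transform_edt(body, sampling=spacing)
        shell = body & (depth <= pert.boundary_shell)
        dose = dose + pert.boundary_amplitude * shell

    if pert.noise_sigma > 0:
        noise = rng.standard_normal(dose.shape)
        np.clip(noise, -3.0, 3.0, out=noise)
        dose = dose + pert.noise_sigma * noise

    np.clip(dose, 0.0, None, out=dose)
    return rtdose.copy_with(dose)


@dataclass(frozen=True)
class CohortRanges:
    """Per-case geometry jitter applied around a base :class:`PhantomSpec`.

    Fractions are relative half-ranges (e.g. 0.1 → ±10%); offsets absolute mm.
    """

    base: PhantomSpec = field(default_factory=PhantomSpec)
    body_scale: float = 0.08
    ptv_center_offset: float = 5.0
    ptv_scale: float = 0.15
    falloff_scale: float = 0.15

    def draw(self, rng: np.random.Generator) -> PhantomSpec:
        b = self.base
        u = lambda r: rng.uniform(-r, r)
        spec = replace(
            b,
            body_semiaxes=tuple(a * (1 + u(self.body_scale)) for a in b.body_semiaxes),
            ptv_center=tuple(c + u(self.ptv_center_offset) for c in b.ptv_center),
            ptv_semiaxes=tuple(a * (1 + u(self.ptv_scale)) for a in b.ptv_semiaxes),
            dose_falloff_sigma=b.dose_falloff_sigma * (1 + u(self.falloff_scale)),
        )
        return spec


def generate_cohort(
    n: int,
    spec_ranges: CohortRanges | None = None,
    pert: PerturbationSpec | None = None,
    seed: int = 0,
) -> List[PatientCase]:
    """Generate ``n`` reproducible synthetic patient cases.

    Per-case geometry is jittered within ``spec_ranges``; per-case random
    streams are spawned from ``seed`` so cohorts of different sizes share
    their common prefix.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = spec_ranges if spec_ranges is not None else CohortRanges()
    pert = pert if pert is not None else PerturbationSpec()
    children = np.random.SeedSequence(seed).spawn(n)
    cases: List[PatientCase] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        case_seed = int(rng.integers(0, 2**31 - 1))
        # draw a valid jittered geometry (rejection keeps the stream seeded)
        for _ in range(100):
            spec = ranges.draw(rng)
            try:
                spec.validate()
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not draw a valid phantom spec from the given ranges")
        ct, structures = generate_ct(spec, seed=case_seed)
        rtdose = generate_rtdose(spec, structures)
        mdose = perturb_to_mdose(rtdose, ct, structures, replace(pert, seed=case_seed))
        cases.append(
            PatientCase(
                case_id=f"case_{i:04d}",
                ct=ct,
                rtdose=rtdose,
                structures=structures,
                prescription_dose=spec.prescription_dose,
                mdose=mdose,
                meta={"seed": case_seed},
            )
        )
    return cases
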