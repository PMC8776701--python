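"""Synthetic thoracic phantoms and cohorts with known ground truth.

Real 4D-CT ventilation studies rest on patient data that cannot be shipped;
this module generates patients whose every intermediate quantity is known
in closed form, so the whole pipeline is testable end to end:

* two-ellipsoid lung masks, a spherical gross internal tumor volume (GITV)
  and a central-airway exclusion cylinder;
* smooth displacement fields from families with analytic Jacobians
  (linear, radial) plus a sinusoidal family for tolerance testing;
* an inhale/exhale CT pair constructed by inverting the HU ventilation
  metric, so the HU metric recovers the target ventilation exactly;
* a tumor-centred dose plateau with Gaussian falloff in place of a
  treatment-planning-system dose;
* cohorts whose binary pneumonitis labels follow a stated logistic model
  on the computed dose-function features, with the intercept calibrated to
  a target incidence.

The cohort composition frequencies in :data:`REFERENCE_COHORT_COUNTS`
(fractionation mix, delivery technique, toxicity prevalence) are the
published characteristics of an 85-patient non-small-cell lung cancer
cohort that this generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit

from .dosimetry import FractionationScheme, extract_features
from .grids import DisplacementField, GriddedVolume
from .ventilation import (
    apply_exclusion,
    hu_ventilation,
    percentile_normalize,
    resample_inhale,
)

#: Composition of the reference clinical cohort the generator emulates
#: (85 patients; counts per category).
REFERENCE_COHORT_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"male": 65, "female": 20},
    "delivery_technique": {"3D-CRT": 50, "VMAT": 35},
    "rp_classification": {"grade2_or_higher": 21, "below_grade2": 64},
    "smoking_history": {"yes": 70, "no": 15},
    "copd": {"yes": 41, "no": 44},
    "fractionation": {"60Gy/30fr": 56, "66Gy/33fr": 19, "69Gy/23fr": 6, "72Gy/24fr": 4},
    "chemotherapy": {"yes": 39, "no": 46},
    "chemotherapy_regimen": {
        "cisplatin_vinorelbine": 24,
        "carboplatin_paclitaxel": 10,
        "cisplatin_etoposide": 2,
        "cisplatin_pemetrexed": 1,
        "others": 2,
    },
}

#: Fractionation schemes and their sampling weights in the reference cohort.
FRACTIONATION_SCHEMES: tuple[tuple[float, int, int], ...] = (
    (60.0, 30, 56), (66.0, 33, 19), (69.0, 23, 6), (72.0, 24, 4),
)

SOFT_TISSUE_HU = 50.0


def category_percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentages of each category, rounded to ``decimals``."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Phantom specification


@dataclass
class LungGeometry:
    """Two ellipsoidal lung fields, in normalized [0,1]^3 grid coordinates."""

    left_center: tuple[float, float, float] = (0.30, 0.50, 0.50)
    right_center: tuple[float, float, float] = (0.70, 0.50, 0.50)
    semi_axes: tuple[float, float, float] = (0.17, 0.28, 0.38)
    airway_radius_norm: float = 0.05


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic patient."""

    grid_shape: tuple[int, int, int] = (32, 32, 40)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lung_geometry: LungGeometry = dataclass_field(default_factory=LungGeometry)
    tumor_center: tuple[float, float, float] = (0.30, 0.50, 0.40)
    tumor_radius_mm: float = 14.0
    field_family: str = "radial"
    field_coefficients: dict = dataclass_field(default_factory=dict)
    prescription: FractionationScheme = dataclass_field(
        default_factory=lambda: FractionationScheme(60.0, 30)
    )
    dose_falloff_mm: float = 15.0
    function_dose_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape components must be >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if not -1.0 <= self.function_dose_overlap <= 1.0:
            raise ValueError("function_dose_overlap must lie in [-1, 1]")
        if self.field_family not in ("linear", "radial", "sinusoidal"):
            raise ValueError(f"unknown field family {self.field_family!r}")

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)


def _coordinate_grids(spec: PhantomSpec) -> list[np.ndarray]:
    """Physical (mm) coordinate arrays for each axis on the phantom grid."""
    idx = np.indices(spec.grid_shape, dtype=float)
    return [idx[i] * spec.spacing_mm[i] for i in range(3)]


# ---------------------------------------------------------------------------
# Masks


def make_masks(spec: PhantomSpec) -> dict[str, GriddedVolume]:
    """Lung, GITV, exclusion, and evaluation masks for one phantom."""
    xs = _coordinate_grids(spec)
    extent = spec.extent_mm
    geo = spec.lung_geometry
    lung = np.zeros(spec.grid_shape, dtype=bool)
    for center in (geo.left_center, geo.right_center):
        q = sum(
            ((xs[i] - center[i] * extent[i]) / (geo.semi_axes[i] * extent[i])) ** 2
            for i in range(3)
        )
        lung |= q <= 1.0
    tumor_mm = np.asarray(spec.tumor_center) * extent
    coords = np.argwhere(lung)
    lo = coords.min(axis=0) * np.asarray(spec.spacing_mm)
    hi = coords.max(axis=0) * np.asarray(spec.spacing_mm)
    if np.any(tumor_mm - spec.tumor_radius_mm < lo) or np.any(tumor_mm + spec.tumor_radius_mm > hi):
        raise ValueError("tumor is not fully inside the lung bounding box")
    r2 = sum((xs[i] - tumor_mm[i]) ** 2 for i in range(3))
    gitv = r2 <= spec.tumor_radius_mm**2
    # central-airway stand-in: a cylinder along the cranio-caudal axis
    axis_r2 = sum((xs[i] - 0.5 * extent[i]) ** 2 for i in range(2))
    exclusion = lung & (axis_r2 <= (geo.airway_radius_norm * extent[0]) ** 2)
    mk = lambda a: GriddedVolume(a.astype(float), spec.spacing_mm, kind="mask")
    masks = {"lung": mk(lung), "gitv": mk(gitv), "exclusion": mk(exclusion)}
    masks["eval"] = apply_exclusion(masks["lung"], masks["exclusion"], masks["gitv"])
    return masks


# ---------------------------------------------------------------------------
# Displacement fields with analytic Jacobians


def make_displacement_field(spec: PhantomSpec) -> DisplacementField:
    """A smooth displacement field (mm) on the phantom grid.

    Families:

    * ``linear``: u(x) = A x + b; Jacobian det(I+A), constant.  Requires
      det(I+A) > 0.
    * ``radial``: u(x) = a exp(-r^2 / 2 s^2) (x - c); the Jacobian of a
      radial map f(r) r_hat is (1 + f')(1 + f/r)^2, known in closed form.
    * ``sinusoidal``: axis-separable u_i = a_i sin(2 pi x_i / l_i + p_i);
      smooth but with non-constant curvature, used to exercise the
      finite-difference truncation error.

    The family and its coefficients are recorded in ``metadata`` so oracle
    tests can evaluate the analytic Jacobian independently.
    """
    xs = _coordinate_grids(spec)
    c = dict(spec.field_coefficients)
    fam = spec.field_family
    u = np.zeros(spec.grid_shape + (3,))
    if fam == "linear":
        A = np.asarray(c.get("A", np.zeros((3, 3))), dtype=float)
        b = np.asarray(c.get("b", np.zeros(3)), dtype=float)
        if not np.all(np.isfinite(A)) or not np.all(np.isfinite(b)):
            raise ValueError("linear field coefficients must be finite")
        det = float(np.linalg.det(np.eye(3) + A))
        if det <= 0:
            raise ValueError(
                f"linear field is not orientation-preserving: det(I+A) = {det:.6g} <= 0"
            )
        for i in range(3):
            u[..., i] = sum(A[i, j] * xs[j] for j in range(3)) + b[i]
        meta = {"family": fam, "A": A, "b": b, "analytic_det": det}
    elif fam == "radial":
        center = np.asarray(c.get("center_mm", 0.5 * spec.extent_mm), dtype=float)
        a = float(c.get("amplitude", 0.15))
        s = float(c.get("sigma_mm", 50.0))
        if s <= 0:
            raise ValueError("radial sigma must be positive")
        r2 = sum((xs[i] - center[i]) ** 2 for i in range(3))
        g = a * np.exp(-0.5 * r2 / s**2)
        for i in range(3):
            u[..., i] = g * (xs[i] - center[i])
        meta = {"family": fam, "center_mm": center, "amplitude": a, "sigma_mm": s}
    else:  # sinusoidal
        amp = np.broadcast_to(np.asarray(c.get("amplitude_mm", 1.0), dtype=float), (3,))
        lam = np.broadcast_to(np.asarray(c.get("wavelength_mm", 60.0), dtype=float), (3,))
        phase = np.broadcast_to(np.asarray(c.get("phase", 0.0), dtype=float), (3,))
        if np.any(lam <= 0):
            raise ValueError("sinusoidal wavelengths must be positive")
        for i in range(3):
            u[..., i] = amp[i] * np.sin(2.0 * np.pi * xs[i] / lam[i] + phase[i])
        meta = {"family": fam, "amplitude_mm": np.array(amp), "wavelength_mm": np.array(lam),
                "phase": np.array(phase)}
    return DisplacementField(u, spec.spacing_mm, metadata=meta)


def analytic_jacobian_ventilation(spec: PhantomSpec, field: DisplacementField) -> np.ndarray:
    """Closed-form det(I + grad u) - 1 of a generated field, as an array."""
    meta = field.metadata
    fam = meta.get("family")
    xs = _coordinate_grids(spec)
    if fam == "linear":
        return np.full(spec.grid_shape, meta["analytic_det"] - 1.0)
    if fam == "radial":
        a, s = meta["amplitude"], meta["sigma_mm"]
        center = meta["center_mm"]
        r2 = sum((xs[i] - center[i]) ** 2 for i in range(3))
        g = a * np.exp(-0.5 * r2 / s**2)       # = f(r)/r
        fprime = g * (1.0 - r2 / s**2)          # = f'(r)
        return (1.0 + fprime) * (1.0 + g) ** 2 - 1.0
    if fam == "sinusoidal":
        det = np.ones(spec.grid_shape)
        for i in range(3):
            k = 2.0 * np.pi / meta["wavelength_mm"][i]
            det *= 1.0 + meta["amplitude_mm"][i] * k * np.cos(k * xs[i] + meta["phase"][i])
        return det - 1.0
    raise ValueError(f"no analytic Jacobian for family {fam!r}")


# ---------------------------------------------------------------------------
# CT pair, dose


def make_ct_pair(
    spec: PhantomSpec,
    field: DisplacementField,
    target_ventilation: GriddedVolume,
    lung_mask: GriddedVolume | None = None,
) -> tuple[GriddedVolume, GriddedVolume]:
    """Inhale/exhale HU pair whose HU-metric ventilation equals the target.

    An inhale image with smooth parenchymal texture is drawn, pulled onto
    the exhale grid through the field, and the exhale image is set to

        HU_ex = HU_in_reg + V_target * (HU_in_reg + 1000)

    inside the lung, so the HU ventilation metric recovers ``V_target``
    exactly (the identical interpolation path is reused downstream).
    Outside the lung both images are constant soft tissue.
    """
    if lung_mask is None:
        lung_mask = make_masks(spec)["lung"]
    lung = lung_mask.as_bool()
    vt = target_ventilation.values
    if not np.all(np.isfinite(vt[lung])):
        raise ValueError("target ventilation must be finite inside the lung mask")
    rng = np.random.default_rng(spec.seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=2.0)
    noise *= 30.0 / max(noise.std(), 1e-12)
    # parenchymal texture must extend past the lung by the field's reach, so
    # in-lung samples through the field never land on soft tissue
    reach = int(np.ceil(np.abs(field.u).max() / min(spec.spacing_mm))) + 1
    shell = ndimage.binary_dilation(lung, iterations=reach)
    hu_in = np.full(spec.grid_shape, SOFT_TISSUE_HU)
    hu_in[shell] = -870.0 + noise[shell]
    inhale = GriddedVolume(hu_in, spec.spacing_mm, kind="HU")
    registered, _ = resample_inhale(inhale, field)
    reg = registered.values
    if np.any(reg[lung] <= -1000.0):
        raise ValueError("registered inhale HU <= -1000 inside the lung mask")
    vt_shell = np.where(np.isfinite(vt), vt, 0.0)
    hu_ex = np.full(spec.grid_shape, SOFT_TISSUE_HU)
    hu_ex[shell] = reg[shell] + vt_shell[shell] * (reg[shell] + 1000.0)
    if np.any(hu_ex[lung] <= -1000.0) or np.any(hu_ex[lung] >= 200.0):
        raise ValueError(
            "target ventilation pushes exhale HU outside (-1000, 200): unphysical phantom"
        )
    exhale = GriddedVolume(hu_ex, spec.spacing_mm, kind="HU")
    return inhale, exhale


def make_dose(spec: PhantomSpec, gitv_mask: GriddedVolume) -> GriddedVolume:
    """Physical dose (Gy): prescription plateau in the GITV, Gaussian falloff.

    Outside the target the dose decays as Rx * exp(-d^2 / 2 sigma^2) with d
    the Euclidean distance (mm) to the GITV surface and sigma the spec's
    ``dose_falloff_mm``.
    """
    g = gitv_mask.as_bool()
    if not g.any():
        raise ValueError("GITV mask is empty")
    rx = spec.prescription.total_dose_Gy
    dist = ndimage.distance_transform_edt(~g, sampling=spec.spacing_mm)
    sigma = spec.dose_falloff_mm
    if sigma <= 0:
        dose = np.where(g, rx, 0.0)
    else:
        dose = rx * np.exp(-0.5 * (dist / sigma) ** 2)
        dose[g] = rx
    return GriddedVolume(dose, spec.spacing_mm, kind="dose_Gy")


# ---------------------------------------------------------------------------
# Whole patients and cohorts


@dataclass
class PhantomPatient:
    """One generated patient: volumes, clinical scalars, and features."""

    spec: PhantomSpec
    age: float
    brinkman_index: float
    features: dict[str, float]
    volumes: dict[str, GriddedVolume] | None = None
    field: DisplacementField | None = None


def _radial_center_for_overlap(spec: PhantomSpec) -> np.ndarray:
    """Place the high-function centre between the tumor and its mirror point.

    overlap = +1 puts peak function at the tumor (high function irradiated),
    overlap = -1 at the point mirrored through the lung midplane.
    """
    extent = spec.extent_mm
    tumor = np.asarray(spec.tumor_center) * extent
    mirror = tumor.copy()
    mirror[0] = extent[0] - tumor[0]  # reflect left-right
    t = 0.5 * (1.0 + spec.function_dose_overlap)
    return t * tumor + (1.0 - t) * mirror


def make_patient(spec: PhantomSpec, keep_volumes: bool = False) -> PhantomPatient:
    """Generate one self-consistent patient and compute its feature vector."""
    rng = np.random.default_rng(spec.seed)
    masks = make_masks(spec)
    if spec.field_family == "radial" and "center_mm" not in spec.field_coefficients:
        spec.field_coefficients["center_mm"] = _radial_center_for_overlap(spec)
    fld = make_displacement_field(spec)
    target = analytic_jacobian_ventilation(spec, fld)
    smooth_noise = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=3.0)
    target = target + 0.02 * smooth_noise / max(smooth_noise.std(), 1e-12)
    target_vol = GriddedVolume(target, spec.spacing_mm, kind="ventilation")
    inhale, exhale = make_ct_pair(spec, fld, target_vol, masks["lung"])
    registered, _ = resample_inhale(inhale, fld)
    vent = hu_ventilation(exhale, registered, masks["eval"])
    function = percentile_normalize(vent, masks["eval"])
    dose = make_dose(spec, masks["gitv"])
    age = float(np.clip(rng.normal(70.3, 10.9), 40.0, 95.0))
    brinkman = float(np.clip(rng.normal(667.8, 487.7), 0.0, 2500.0))
    features = extract_features(
        dose, spec.prescription, masks["eval"], function,
        masks["gitv"], masks["lung"], age, brinkman,
    )
    volumes = None
    if keep_volumes:
        volumes = {
            "inhale": inhale, "exhale": exhale, "registered_inhale": registered,
            "dose": dose, "target_ventilation": target_vol, "ventilation": vent,
            "function": function, **masks,
        }
    return PhantomPatient(spec, age, brinkman, features,
                          volumes=volumes, field=fld if keep_volumes else None)


@dataclass
class CohortSpec:
    """Parametric description of a synthetic cohort.

    ``label_model`` maps feature names to logistic coefficients applied to
    cohort-standardized feature values; the intercept is calibrated so the
    expected incidence matches ``incidence_target``.
    """

    n_patients: int = 85
    label_model: dict[str, float] = dataclass_field(
        default_factory=lambda: {"fV20": 1.5, "MLD": 0.5}
    )
    incidence_target: float = 0.247
    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 40)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    tumor_radius_range_mm: tuple[float, float] = (8.0, 18.0)
    overlap_range: tuple[float, float] = (-1.0, 1.0)
    amplitude_range: tuple[float, float] = (0.08, 0.25)
    sigma_range_mm: tuple[float, float] = (35.0, 70.0)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if not 0.0 < self.incidence_target < 1.0:
            raise ValueError("incidence_target must lie in (0, 1)")


def _lung_bbox_mm(grid_shape, spacing_mm, geo: LungGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Voxelized lung bounding box (mm) for a given grid and geometry."""
    spec = PhantomSpec(grid_shape=grid_shape, spacing_mm=spacing_mm, lung_geometry=geo,
                       tumor_center=(0.5, 0.5, 0.5), tumor_radius_mm=1e-6)
    xs = _coordinate_grids(spec)
    extent = spec.extent_mm
    lung = np.zeros(grid_shape, dtype=bool)
    for center in (geo.left_center, geo.right_center):
        q = sum(
            ((xs[i] - center[i] * extent[i]) / (geo.semi_axes[i] * extent[i])) ** 2
            for i in range(3)
        )
        lung |= q <= 1.0
    coords = np.argwhere(lung)
    sp = np.asarray(spacing_mm)
    return coords.min(axis=0) * sp, coords.max(axis=0) * sp


def _sample_patient_spec(cohort: CohortSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    geo = LungGeometry()
    extent = (np.asarray(cohort.grid_shape) - 1) * np.asarray(cohort.spacing_mm)
    side = geo.left_center if rng.random() < 0.5 else geo.right_center
    radius = float(rng.uniform(*cohort.tumor_radius_range_mm))
    offs = rng.uniform(-1, 1, size=3) * np.asarray(geo.semi_axes) * 0.55
    center_mm = (np.asarray(side) + offs) * extent
    # the tumor sphere must stay inside the voxelized lung bounding box
    lo, hi = _lung_bbox_mm(cohort.grid_shape, cohort.spacing_mm, geo)
    lo_c, hi_c = lo + radius + 1.0, hi - radius - 1.0
    if np.any(lo_c > hi_c):
        radius = float(0.45 * (hi - lo).min() - 1.0)
        lo_c, hi_c = lo + radius + 1.0, hi - radius - 1.0
    center_mm = np.clip(center_mm, lo_c, hi_c)
    center = tuple(float(c) for c in center_mm / extent)
    weights = np.array([w for *_unused, w in FRACTIONATION_SCHEMES], dtype=float)
    total, nfr, _ = FRACTIONATION_SCHEMES[rng.choice(len(weights), p=weights / weights.sum())]
    return PhantomSpec(
        grid_shape=cohort.grid_shape,
        spacing_mm=cohort.spacing_mm,
        lung_geometry=geo,
        tumor_center=center,
        tumor_radius_mm=radius,
        field_family="radial",
        field_coefficients={
            "amplitude": float(rng.uniform(*cohort.amplitude_range)),
            "sigma_mm": float(rng.uniform(*cohort.sigma_range_mm)),
        },
        prescription=FractionationScheme(total, nfr),
        function_dose_overlap=float(rng.uniform(*cohort.overlap_range)),
        seed=seed,
    )


def calibrate_intercept(logits: np.ndarray, incidence_target: float) -> float:
    """Intercept c with mean(expit(logits + c)) == incidence_target."""
    f = lambda c: float(expit(logits + c).mean() - incidence_target)
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        achieved = float(expit(logits).mean())
        raise RuntimeError(
            f"incidence calibration failed: achieved {achieved:.3f}, "
            f"target {incidence_target:.3f}"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def make_cohort(
    cohort: CohortSpec, keep_volumes: bool = False
) -> tuple[list[PhantomPatient], "pandas.DataFrame"]:
    """Generate a full cohort and its feature table with binary labels.

    Deterministic for a fixed seed.  Labels are Bernoulli draws from the
    logistic model on cohort-standardized features, intercept calibrated to
    the incidence target.  Returns ``(patients, table)`` where ``table`` has
    one row per patient (patient_id, features, label ``rp``).
    """
    import pandas as pd

    ss = np.random.SeedSequence(cohort.seed)
    master = np.random.default_rng(ss)
    patient_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=cohort.n_patients)]
    patients = []
    for i in range(cohort.n_patients):
        spec = _sample_patient_spec(cohort, master, patient_seeds[i])
        patients.append(make_patient(spec, keep_volumes=keep_volumes))
    table = pd.DataFrame([p.features for p in patients])
    table.insert(0, "patient_id", [f"P{i:03d}" for i in range(cohort.n_patients)])

    logits = np.zeros(cohort.n_patients)
    for name, coef in cohort.label_model.items():
        if name == "intercept":
            continue
        if name not in table.columns:
            raise ValueError(f"label model references unknown feature {name!r}")
        col = table[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        logits += coef * z
    if "intercept" in cohort.label_model:
        intercept = float(cohort.label_model["intercept"])
    else:
        intercept = calibrate_intercept(logits, cohort.incidence_target)
    probs = expit(logits + intercept)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    labels = (label_rng.random(cohort.n_patients) < probs).astype(int)
    table["rp"] = labels
    table.attrs["intercept"] = intercept
    table.attrs["achieved_incidence"] = float(labels.mean())
    return patients, table
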