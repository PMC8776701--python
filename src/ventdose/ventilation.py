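"""Voxelwise lung ventilation from a registered inhale/exhale CT pair.

Two standard 4D-CT ventilation metrics are provided.

HU metric: CT intensity is modelled as a linear mixture of air (-1000 HU)
and tissue (~0 HU), so the fractional air-volume change of a voxel between
exhale and registered inhale is

    V_HU = (HU_ex - HU_in_reg) / (HU_in_reg + 1000)

Jacobian metric: the local volume change implied by the deformable
registration displacement field u,

    V_Jac = det(I + grad u) - 1

Both estimate regional ventilation as regional volume change.  Ventilation
values are converted to per-patient rank percentiles before being used as
function weights in dose-function histograms.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .grids import DisplacementField, GriddedVolume

#: Voxels whose registered-inhale HU is within this band of pure air
#: (|HU + 1000| < guard) are excluded from the HU metric: the denominator
#: of V_HU vanishes there and the metric blows up.
AIR_DENOMINATOR_GUARD_HU = 50.0

#: Sentinel written at excluded / out-of-mask voxels of ventilation maps.
EXCLUDED = np.nan


def _check_same_grid(a, b, what: str) -> None:
    if not a.same_grid(b):
        raise ValueError(
            f"{what}: grid mismatch (shape {a.shape} spacing {a.spacing_mm} vs "
            f"shape {b.shape} spacing {b.spacing_mm})"
        )


def resample_inhale(
    inhale: GriddedVolume, field: DisplacementField
) -> tuple[GriddedVolume, GriddedVolume]:
    """Pull the inhale image onto the exhale grid through the displacement field.

    Returns ``(registered, validity)`` where ``registered`` holds
    HU_in(x + u(x)) via trilinear interpolation and ``validity`` is a mask
    flagging sample points that fell inside the inhale volume.  Out-of-volume
    samples take the air padding value -1000 HU.
    """
    if inhale.shape != field.shape or not np.allclose(inhale.spacing_mm, field.spacing_mm):
        raise ValueError(
            f"inhale grid (shape {inhale.shape}, spacing {inhale.spacing_mm}) does not "
            f"match field grid (shape {field.shape}, spacing {field.spacing_mm})"
        )
    idx = np.indices(inhale.shape, dtype=float)
    spacing = np.asarray(inhale.spacing_mm)
    coords = [idx[i] + field.component(i) / spacing[i] for i in range(3)]
    out = ndimage.map_coordinates(
        inhale.values, coords, order=1, mode="constant", cval=-1000.0
    )
    valid = np.ones(inhale.shape, dtype=bool)
    for i in range(3):
        valid &= (coords[i] >= 0.0) & (coords[i] <= inhale.shape[i] - 1)
    registered = inhale.with_values(out, kind="HU")
    validity = GriddedVolume(valid.astype(float), inhale.spacing_mm, inhale.origin_mm, "mask")
    return registered, validity


def hu_ventilation(
    exhale: GriddedVolume,
    registered_inhale: GriddedVolume,
    mask: GriddedVolume,
    guard_hu: float = AIR_DENOMINATOR_GUARD_HU,
) -> GriddedVolume:
    """HU-metric ventilation on the evaluation mask.

    In-mask voxels whose registered-inhale denominator (HU + 1000) has
    magnitude below ``guard_hu`` are excluded (NaN sentinel), as are all
    out-of-mask voxels.
    """
    for vol, name in ((exhale, "exhale"), (registered_inhale, "registered inhale")):
        if vol.kind != "HU":
            raise ValueError(f"{name} volume must be HU kind, got {vol.kind!r}")
    _check_same_grid(exhale, registered_inhale, "hu_ventilation")
    _check_same_grid(exhale, mask, "hu_ventilation")
    m = mask.as_bool()
    denom = registered_inhale.values + 1000.0
    valid = m & (np.abs(denom) >= guard_hu)
    vent = np.full(exhale.shape, EXCLUDED)
    vent[valid] = (exhale.values[valid] - registered_inhale.values[valid]) / denom[valid]
    return exhale.with_values(vent, kind="ventilation")


def jacobian_ventilation(field: DisplacementField, mask: GriddedVolume) -> GriddedVolume:
    """Jacobian-metric ventilation det(I + grad u) - 1 on the evaluation mask.

    Partial derivatives use central finite differences scaled by the voxel
    spacing (one-sided on volume faces), which are exact for affine fields.
    """
    if field.shape != mask.shape:
        raise ValueError(f"field shape {field.shape} does not match mask {mask.shape}")
    m = mask.as_bool()
    spacing = field.spacing_mm
    # grad[i][j] = d u_i / d x_j
    grad = [np.gradient(field.component(i), *spacing) for i in range(3)]
    jac = np.empty(field.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = grad[i][j]
        jac[..., i, i] += 1.0
    det = np.linalg.det(jac)
    if not np.all(np.isfinite(det[m])):
        bad = np.argwhere(m & ~np.isfinite(det))[0]
        raise ValueError(
            f"non-finite Jacobian derivative at voxel {tuple(int(i) for i in bad)}"
        )
    vent = np.full(field.shape, EXCLUDED)
    vent[m] = det[m] - 1.0
    return GriddedVolume(vent, field.spacing_mm, field.origin_mm, "ventilation")


def percentile_normalize(vent: GriddedVolume, mask: GriddedVolume) -> GriddedVolume:
    """Convert ventilation to per-patient rank percentiles in (0, 100].

    Percentile = 100 * rank / N over valid in-mask voxels, ties receiving
    the mean rank of their tie group.  Excluded (NaN) voxels stay excluded;
    out-of-mask voxels are 0.
    """
    _check_same_grid(vent, mask, "percentile_normalize")
    m = mask.as_bool() & np.isfinite(vent.values)
    n = int(m.sum())
    if n == 0:
        raise ValueError("percentile_normalize: no valid in-mask voxel")
    ranks = rankdata(vent.values[m], method="average")
    out = np.zeros(vent.shape)
    out[mask.as_bool() & ~np.isfinite(vent.values)] = EXCLUDED
    out[m] = 100.0 * ranks / n
    return vent.with_values(out, kind="percentile")


def apply_exclusion(
    mask: GriddedVolume,
    exclusion: GriddedVolume | None = None,
    gitv: GriddedVolume | None = None,
) -> GriddedVolume:
    """Evaluation mask = lung AND NOT exclusion AND NOT GITV.

    The exclusion mask stands in for the manual trimming of central airways
    and great vessels; the GITV (gross internal tumor volume) is removed so
    features describe healthy lung only.
    """
    result = mask.as_bool().copy()
    for other in (exclusion, gitv):
        if other is not None:
            _check_same_grid(mask, other, "apply_exclusion")
            result &= ~other.as_bool()
    if not result.any():
        raise ValueError("apply_exclusion: evaluation mask is empty")
    return GriddedVolume(result.astype(float), mask.spacing_mm, mask.origin_mm, "mask")
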