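"""EQD2 conversion and dose-volume / dose-function histogram features.

Physical dose is first converted to the equivalent dose in 2-Gy fractions
(EQD2) under the linear-quadratic model with a lung alpha/beta of 3 Gy:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / n_fractions

so that cohorts mixing fractionation schemes are comparable.  DVH features
(MLD, V5-V50) and their function-weighted DFH counterparts (fMLD, fV5-fV50)
are then extracted over the healthy-lung evaluation mask, with Vx using a
strict "dose exceeding x Gy" rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import GriddedVolume

#: Gy thresholds of the Vx / fVx features.
DOSE_THRESHOLDS_GY = (5, 10, 20, 30, 40, 50)

CLINICAL_FEATURES = (
    "age", "brinkman_index", "gitv_pos_ul", "gitv_pos_ap", "gitv_pos_lr",
    "gitv_volume_cc",
)
DVH_FEATURES = ("MLD", "V5", "V10", "V20", "V30", "V40", "V50")
DFH_FEATURES = ("fMLD", "fV5", "fV10", "fV20", "fV30", "fV40", "fV50")
ALL_FEATURES = CLINICAL_FEATURES + DVH_FEATURES + DFH_FEATURES


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription: total dose, fraction count, and the LQ alpha/beta (Gy)."""

    total_dose_Gy: float
    n_fractions: int
    alpha_beta_Gy: float = 3.0

    def __post_init__(self) -> None:
        if self.total_dose_Gy <= 0:
            raise ValueError("total dose must be positive")
        if self.n_fractions < 1:
            raise ValueError("fraction count must be >= 1")
        if self.alpha_beta_Gy <= 0:
            raise ValueError("alpha/beta must be positive")
        d = self.dose_per_fraction_Gy
        if not 1.8 <= d <= 3.0:
            warnings.warn(
                f"dose per fraction {d:.2f} Gy is outside the conventional "
                "1.8-3.0 Gy/fraction regime", stacklevel=2,
            )

    @property
    def dose_per_fraction_Gy(self) -> float:
        return self.total_dose_Gy / self.n_fractions


def eqd2_convert(dose: GriddedVolume, scheme: FractionationScheme) -> GriddedVolume:
    """Voxelwise EQD2 under the linear-quadratic model.

    The per-voxel fraction dose is d = D_voxel / n_fractions (the fraction
    count is uniform, the fraction dose varies spatially).  Zero maps to
    zero; the conversion is the identity exactly at 2 Gy/fraction.
    """
    if dose.kind != "dose_Gy":
        raise ValueError(f"expected a dose_Gy volume, got kind={dose.kind!r}")
    if np.any(dose.values < 0):
        bad = np.argwhere(dose.values < 0)[0]
        raise ValueError(f"negative dose at voxel {tuple(int(i) for i in bad)}")
    ab = scheme.alpha_beta_Gy
    d = dose.values / scheme.n_fractions
    return dose.with_values(dose.values * (d + ab) / (2.0 + ab), kind="dose_Gy")


def _in_mask(dose: GriddedVolume, eval_mask: GriddedVolume) -> np.ndarray:
    if not dose.same_grid(eval_mask):
        raise ValueError("dose and evaluation mask are on different grids")
    m = eval_mask.as_bool()
    if not m.any():
        raise ValueError("evaluation mask is empty")
    return m


def dvh_features(dose_eqd2: GriddedVolume, eval_mask: GriddedVolume) -> dict[str, float]:
    """MLD (mean lung dose, Gy) and Vx (% of lung volume with dose > x Gy)."""
    m = _in_mask(dose_eqd2, eval_mask)
    d = dose_eqd2.values[m]
    out = {"MLD": float(d.mean())}
    for x in DOSE_THRESHOLDS_GY:
        out[f"V{x}"] = float(100.0 * np.count_nonzero(d > x) / d.size)
    return out


def dfh_features(
    dose_eqd2: GriddedVolume,
    function: GriddedVolume,
    eval_mask: GriddedVolume,
) -> dict[str, float]:
    """fMLD and fVx: DVH quantities weighted by the percentile function map.

    fVx = 100 * sum of function over voxels with dose > x / total function;
    fMLD = function-weighted mean dose.  Voxels excluded from the function
    map (NaN) carry zero weight.
    """
    m = _in_mask(dose_eqd2, eval_mask)
    if not function.same_grid(dose_eqd2):
        raise ValueError("function map and dose are on different grids")
    f = function.values[m]
    d = dose_eqd2.values[m]
    f = np.where(np.isfinite(f), f, 0.0)
    total = f.sum()
    if total <= 0:
        raise ValueError("total function weight is zero on the evaluation mask")
    out = {"fMLD": float((f * d).sum() / total)}
    for x in DOSE_THRESHOLDS_GY:
        out[f"fV{x}"] = float(100.0 * f[d > x].sum() / total)
    return out


def gitv_position(gitv: GriddedVolume, lung: GriddedVolume) -> tuple[float, float, float]:
    """GITV centroid within the lung bounding box, normalized to [0, 1] per axis.

    Returned as (upper-lower, anterior-posterior, left-right); 0 is the
    superior, anterior, and left extreme respectively (grid axis convention
    of :mod:`ventdose.grids`).
    """
    if not gitv.same_grid(lung):
        raise ValueError("GITV and lung masks are on different grids")
    g = gitv.as_bool()
    l = lung.as_bool()
    if not g.any():
        raise ValueError("GITV mask is empty")
    if not l.any():
        raise ValueError("lung mask is empty")
    centroid = np.argwhere(g).mean(axis=0)
    coords = np.argwhere(l)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    pos = []
    # grid axes are (LR, AP, SI); features are reported (UL, AP, LR)
    for axis in (2, 1, 0):
        extent = hi[axis] - lo[axis]
        if extent == 0:
            raise ValueError(f"lung bounding box is degenerate along axis {axis}")
        pos.append(float(np.clip((centroid[axis] - lo[axis]) / extent, 0.0, 1.0)))
    return tuple(pos)


def gitv_volume(gitv: GriddedVolume) -> float:
    """Mask volume in cc (1 cc = 1000 mm^3)."""
    return float(gitv.as_bool().sum() * gitv.voxel_volume_mm3 / 1000.0)


def extract_features(
    dose: GriddedVolume,
    scheme: FractionationScheme,
    eval_mask: GriddedVolume,
    function: GriddedVolume,
    gitv: GriddedVolume,
    lung: GriddedVolume,
    age: float,
    brinkman_index: float,
) -> dict[str, float]:
    """Assemble the full per-patient feature vector (clinical + DVH + DFH)."""
    eqd2 = eqd2_convert(dose, scheme)
    pos_ul, pos_ap, pos_lr = gitv_position(gitv, lung)
    feats = {
        "age": float(age),
        "brinkman_index": float(brinkman_index),
        "gitv_pos_ul": pos_ul,
        "gitv_pos_ap": pos_ap,
        "gitv_pos_lr": pos_lr,
        "gitv_volume_cc": gitv_volume(gitv),
    }
    feats.update(dvh_features(eqd2, eval_mask))
    feats.update(dfh_features(eqd2, function, eval_mask))
    return feats
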