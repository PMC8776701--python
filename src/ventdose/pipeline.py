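"""End-to-end orchestration: simulate -> ventilate -> features -> train -> report.

A :class:`RunConfig` fully determines a run; rerunning with the same config
reproduces the same artifacts (feature CSVs are byte-identical).  Every
written file is listed in a manifest with its SHA-256 content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dosimetry import extract_features
from .grids import save_field, save_volume
from .modeling import (
    FEATURE_SETS,
    LABEL_COLUMN,
    SplitScheme,
    compare_feature_sets,
    correlation_matrix,
    run_experiment,
    univariate_screen,
)
from .phantom import CohortSpec, PhantomPatient, make_cohort
from .ventilation import jacobian_ventilation, percentile_normalize

log = logging.getLogger("ventdose")

METRICS = ("hu", "jacobian")


@dataclass
class RunConfig:
    """Serializable description of one full experiment run."""

    cohort: CohortSpec = dataclass_field(default_factory=CohortSpec)
    scheme: SplitScheme = dataclass_field(default_factory=SplitScheme)
    metric: str = "both"  # {"hu", "jacobian", "both"}
    feature_sets: dict[str, tuple[str, ...]] = dataclass_field(
        default_factory=lambda: dict(FEATURE_SETS)
    )
    write_volumes: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.metric not in METRICS + ("both",):
            raise ValueError(f"unknown metric {self.metric!r}; expected hu, jacobian, or both")

    @property
    def metrics(self) -> tuple[str, ...]:
        return METRICS if self.metric == "both" else (self.metric,)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"cannot serialize {type(o)}")
        return json.dumps(dataclasses.asdict(self), default=default, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)

        def tuplify(d: dict) -> dict:
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        cohort_raw = raw.pop("cohort", {})
        label_model = cohort_raw.pop("label_model", None)
        cohort_kwargs = tuplify(cohort_raw)
        if label_model is not None:
            cohort_kwargs["label_model"] = dict(label_model)
        scheme = SplitScheme(**tuplify(raw.pop("scheme", {})))
        fsets = {k: tuple(v) for k, v in raw.pop("feature_sets", FEATURE_SETS).items()}
        return cls(cohort=CohortSpec(**cohort_kwargs), scheme=scheme,
                   feature_sets=fsets, **raw)


def metric_features(patient: PhantomPatient, metric: str) -> dict[str, float]:
    """Per-patient feature vector under the chosen ventilation metric."""
    if patient.volumes is None:
        raise ValueError("patient was generated without volumes")
    vols = patient.volumes
    if metric == "hu":
        vent = vols["ventilation"]
    elif metric == "jacobian":
        vent = jacobian_ventilation(patient.field, vols["eval"])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    function = percentile_normalize(vent, vols["eval"])
    return extract_features(
        vols["dose"], patient.spec.prescription, vols["eval"], function,
        vols["gitv"], vols["lung"], patient.age, patient.brinkman_index,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the whole study and write all artifacts under ``out_dir``.

    Returns the manifest dict.  Artifacts: per-metric feature tables,
    per-run CSVs, summary tables, pairwise Wilcoxon comparisons, univariate
    screens, Spearman correlation matrices, optional NIfTI volumes, a
    manifest with config hash and content hashes.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    log.info("generating cohort of %d patients (seed %d)",
             config.cohort.n_patients, config.cohort.seed)
    try:
        patients, table = make_cohort(config.cohort, keep_volumes=True)
    except Exception as err:
        raise RuntimeError(f"stage simulate failed: {err}") from err

    if config.write_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for i, p in enumerate(patients):
            pdir = vol_dir / f"P{i:03d}"
            pdir.mkdir(exist_ok=True)
            for name, vol in p.volumes.items():
                path = pdir / f"{name}.nii"
                save_volume(vol, path)
                written.append(path)
            fpath = pdir / "displacement_field.nii"
            save_field(p.field, fpath)
            written.append(fpath)

    results = {}
    for metric in config.metrics:
        log.info("computing %s-metric features", metric)
        try:
            feats = pd.DataFrame([metric_features(p, metric) for p in patients])
        except Exception as err:
            raise RuntimeError(f"stage features ({metric}) failed: {err}") from err
        feats.insert(0, "patient_id", table["patient_id"].to_numpy())
        feats[LABEL_COLUMN] = table[LABEL_COLUMN].to_numpy()
        fpath = out / f"features_{metric}.csv"
        _write_csv(feats, fpath)
        written.append(fpath)

        screen = univariate_screen(feats)
        spath = out / f"univariate_{metric}.csv"
        screen.rename_axis("feature").reset_index().to_csv(spath, index=False)
        written.append(spath)

        corr_cols = [c for c in feats.columns if c not in ("patient_id", LABEL_COLUMN)]
        corr = correlation_matrix(feats, corr_cols)
        cpath = out / f"correlation_{metric}.csv"
        corr.to_csv(cpath)
        written.append(cpath)

        log.info("training %s-metric models (%d repeats x %d sets)",
                 metric, config.scheme.n_repeats, len(config.feature_sets))
        try:
            result = run_experiment(feats, config.feature_sets, config.scheme)
        except Exception as err:
            raise RuntimeError(f"stage train ({metric}) failed: {err}") from err
        results[metric] = result
        rpath = out / f"runs_{metric}.csv"
        _write_csv(result.to_frame(), rpath)
        written.append(rpath)
        mpath = out / f"summary_{metric}.csv"
        _write_csv(result.summary(), mpath)
        written.append(mpath)

        names = list(config.feature_sets)
        comp_rows = [
            {"a": a, "b": b,
             "wilcoxon_p": compare_feature_sets(result.runs[a], result.runs[b])}
            for i, a in enumerate(names) for b in names[i + 1:]
        ]
        ppath = out / f"comparisons_{metric}.csv"
        _write_csv(pd.DataFrame(comp_rows), ppath)
        written.append(ppath)

    config_json = config.to_json()
    cfg_path = out / "config.json"
    cfg_path.write_text(config_json)
    written.append(cfg_path)
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.cohort.seed,
        "achieved_incidence": table.attrs.get("achieved_incidence"),
        "files": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
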