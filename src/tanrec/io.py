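"""File formats and pipeline orchestration.

Everything on disk is delimited text:

* time series — one TSV per subject and scan, ``<subject>_<scan>.tsv``,
  rows = volumes, columns = regions, optional header of region labels;
* FC / tangent matrices — TSV per subject and segment (17 significant
  digits, bit-stable round trip);
* covariates — CSV with the mandated raw column names;
* identifiability and meta-identifiability matrices — labeled TSV;
* reconfiguration vectors — two-column TSV (subject, value);
* model reports — JSON (coefficients, SEs, p values, R^2, additive R^2);
* a YAML manifest tying a cohort together (subjects, files, TR, scheme
  overrides);
* a JSON-lines run log, one line per pipeline stage with wall time and
  output checksums, plus an echoed configuration for exact re-runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import BoldTimeSeries, default_scheme, nominal_scan_volumes
from .regression import PREDICTORS
from .reconfig import DEFAULT_LAMBDA_GRID, FunctionalReconfiguration, TRANSITIONS
from .spd import load_matrix, save_matrix

__all__ = [
    "PipelineConfig",
    "write_time_series",
    "read_time_series",
    "write_cohort",
    "read_manifest",
    "load_time_series",
    "read_covariates",
    "write_vector",
    "read_vector",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    manifest: str
    covariates: str
    output_dir: str
    tr_seconds: float = 1.2
    lam: float = 0.001
    reference_segments: tuple = ("R1.1",)
    include_diagonal: bool = False
    predictor_order: tuple = tuple(PREDICTORS)
    lambda_grid: tuple = tuple(DEFAULT_LAMBDA_GRID)
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("regularization value must be positive")
        self.reference_segments = tuple(self.reference_segments)
        self.predictor_order = tuple(self.predictor_order)
        self.lambda_grid = tuple(float(x) for x in self.lambda_grid)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# time series, covariates, vectors
# ---------------------------------------------------------------------------


def write_time_series(path, ts: BoldTimeSeries, labels=None) -> None:
    save_matrix(path, ts.data, labels=labels)


def read_time_series(path, tr_seconds: float, subject_id="", scan_id="scan1") -> BoldTimeSeries:
    values, _ = load_matrix(path)
    return BoldTimeSeries(
        values, tr_seconds=tr_seconds, subject_id=subject_id, scan_id=scan_id
    )


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject" in df.columns:
        df = df.set_index("subject")
    return df


def write_vector(path, vec) -> None:
    """Two-column TSV: subject, value."""
    with open(path, "w") as fh:
        fh.write("subject\tvalue\n")
        for sid, v in zip(vec.subject_order, vec.values):
            fh.write(f"{sid}\t{v:.17g}\n")


def read_vector(path):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return list(df["subject"]), df["value"].to_numpy()


# ---------------------------------------------------------------------------
# cohort directory and manifest
# ---------------------------------------------------------------------------


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort: manifest, TSVs, covariate CSV, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for (sid, scan_id), ts in cohort.time_series.items():
        name = f"{sid}_{scan_id}.tsv"
        write_time_series(out / name, ts)
        files.setdefault(sid, {})[scan_id] = name
    cohort.covariates.to_csv(out / "covariates.csv")
    manifest = {
        "tr_seconds": cohort.config.tr_seconds,
        "subjects": sorted(files),
        "files": files,
        "covariates": "covariates.csv",
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    gt = cohort.ground_truth
    truth = {
        "config": cohort.config.to_dict(),
        "generating_betas": gt.generating_betas,
        "engage_amplitude": gt.engage_amplitude.tolist(),
        "disengage_fraction": gt.disengage_fraction.tolist(),
        "noise_free_reconfiguration": {
            k: v.tolist() for k, v in gt.noise_free_reconfiguration.items()
        },
        "true_coefficients": {
            k: v.to_dict() for k, v in gt.true_coefficients.items()
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return out


def read_manifest(path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("tr_seconds", "files"):
        if key not in manifest:
            raise ValueError(f"manifest is missing {key!r}")
    return manifest


def load_time_series(manifest_path) -> tuple[dict, float]:
    """Load every subject/scan TSV referenced by a manifest."""
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    tr = float(manifest["tr_seconds"])
    series = {}
    for sid, scans in manifest["files"].items():
        for scan_id, name in scans.items():
            series[(sid, scan_id)] = read_time_series(
                root / name, tr_seconds=tr, subject_id=sid, scan_id=scan_id
            )
    return series, tr


# ---------------------------------------------------------------------------
# full pipeline run
# ---------------------------------------------------------------------------


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def stage(self, name: str, started: float, outputs=()):
        rec = {
            "stage": name,
            "wall_seconds": round(time.perf_counter() - started, 4),
            "outputs": {p.name: _checksum(p) for p in outputs},
        }
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write every intermediate artifact.

    Stages: load -> segment/FC -> reference -> projection ->
    meta-identifiability -> reconfiguration vectors -> models (+ additive
    R^2).  Any stage failure aborts with the stage name in the exception.
    Identical configurations produce byte-identical numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "run_log.jsonl")
    with open(out / "config_echo.json", "w") as fh:
        json.dump(
            {"config": config.to_dict(), "numpy_version": np.__version__},
            fh, indent=1, sort_keys=True,
        )

    stage = "load"
    try:
        t0 = time.perf_counter()
        series, tr = load_time_series(config.manifest)
        covariates = read_covariates(config.covariates)
        log.stage(stage, t0)

        stage = "fc"
        t0 = time.perf_counter()
        scheme = default_scheme(tr, *nominal_scan_volumes(tr))
        model = FunctionalReconfiguration.from_time_series(
            series,
            covariates,
            scheme=scheme,
            tr_seconds=tr,
            lam=config.lam,
            reference_segments=config.reference_segments,
            predictor_order=config.predictor_order,
            include_diagonal=config.include_diagonal,
        )
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        written = []
        for seg, fcs in model.fcs.items():
            for f in fcs:
                p = fc_dir / f"{f.subject_id}_{seg}.tsv"
                save_matrix(p, f.values)
                written.append(p)
        log.stage(stage, t0, written[:1])

        stage = "fit"
        t0 = time.perf_counter()
        results = model.fit()
        ref_path = out / "reference.tsv"
        save_matrix(ref_path, results.reference.values)
        tangent_dir = out / "tangent"
        tangent_dir.mkdir(exist_ok=True)
        for seg, tfcs in results.tangent_fcs.items():
            for t in tfcs:
                save_matrix(tangent_dir / f"{t.label.replace(':', '_')}.tsv", t.values)
        log.stage(stage, t0, [ref_path])

        stage = "identifiability"
        t0 = time.perf_counter()
        meta_path = out / "meta_identifiability.tsv"
        labels = [
            f"{seg}:{sid}"
            for seg in ("R1.1", "R1.2", "SST", "R2.1", "R2.2")
            for sid in results.subject_order
        ]
        save_matrix(meta_path, results.meta.stacked(), labels=labels)
        rates_path = out / "identification_rates.tsv"
        results.identification_rates.to_csv(rates_path, sep="\t")
        log.stage(stage, t0, [meta_path, rates_path])

        stage = "reconfiguration"
        t0 = time.perf_counter()
        vec_paths = []
        for name, vec in results.reconfiguration.items():
            p = out / f"reconfiguration_{name}.tsv"
            write_vector(p, vec)
            vec_paths.append(p)
        log.stage(stage, t0, vec_paths)

        stage = "models"
        t0 = time.perf_counter()
        model_paths = []
        for name, res in results.models.items():
            p = out / f"model_{name}.json"
            with open(p, "w") as fh:
                json.dump(res.to_dict(), fh, indent=1, sort_keys=True)
            resid = out / f"residuals_{name}.tsv"
            with open(resid, "w") as fh:
                fh.write("subject\tresidual\n")
                for sid, r in zip(results.subject_order, res.residuals):
                    fh.write(f"{sid}\t{r:.17g}\n")
            model_paths += [p, resid]
        log.stage(stage, t0, model_paths)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
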