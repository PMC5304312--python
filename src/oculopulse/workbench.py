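"""End-to-end runs: configuration, manifests, extraction and outputs.

Binds the stages — synthetic generation (optional), contour extraction,
feature extraction, pulse-phase binning, the shift scan and the cohort
summary — into a reproducible run.  Every output file carries the hash of the
fully resolved configuration, the seed is recorded everywhere, and a run log
keeps per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contour import decompose_response, extract_contours
from .exceptions import ManifestError, OculopulseError
from .features import (
    applanation_times,
    assemble_feature_vector,
    deformation_profile,
    max_deformation,
    vibration_frequency,
)
from .frames import FrameSequence
from .phasecorr import PhaseCouplingScan
from .pulse import PulseTrace, bin_phase, detect_beats, phase_at
from .records import MeasurementRecord, records_to_dataframe
from .simulate import CohortConfig, generate_cohort

__all__ = ["RunConfig", "read_manifest", "run_pipeline", "write_pulse_csv", "read_pulse_csv"]

logger = logging.getLogger("oculopulse")

MANIFEST_COLUMNS = [
    "subject", "measurement", "eye", "frames_path", "pulse_path",
    "trigger_time_s", "iop_mmHg",
]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    All stage parameters live here with full defaulting so that a run is
    reproducible from the config alone; ``config_hash()`` digests the resolved
    values.
    """

    output_dir: str = "oculopulse_out"
    manifest_path: str | None = None
    # synthetic generation (used when no manifest is given)
    synthetic: bool = True
    n_subjects: int = 10
    n_meas_per_subject: int = 6
    mode: str = "fast"  # "fast" (features directly) or "render" (full imaging)
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # imaging parameters
    canny_low_frac: float = 0.1
    canny_high_frac: float = 0.3
    canny_sigma: float = 1.4
    poly_degree: int = 5
    peripheral_frac: float = 0.1
    central_halfwidth_cols: int = 75
    flatness_threshold_mm: float = 0.005
    smooth_ms: float = 2.5
    # scan parameters
    phi_step_deg: float = 10.0
    outlier_preset: str = "thick"
    feature_std_mode: str = "sample"
    pooled_std_mode: str = "population"
    circular: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("fast", "render"):
            raise ValueError("mode must be 'fast' or 'render'")
        if not 0 < self.canny_low_frac < self.canny_high_frac < 1:
            raise ValueError("need 0 < canny_low_frac < canny_high_frac < 1")
        if not 0 < self.peripheral_frac <= 0.5:
            raise ValueError("peripheral_frac must lie in (0, 0.5]")
        if not 0 < self.phi_step_deg <= 90:
            raise ValueError("phi_step_deg must lie in (0, 90]")
        if self.feature_std_mode not in ("sample", "population"):
            raise ValueError("feature_std_mode must be 'sample' or 'population'")
        if self.pooled_std_mode not in ("sample", "population"):
            raise ValueError("pooled_std_mode must be 'sample' or 'population'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Digest of the analysis-relevant configuration (output_dir excluded,
        so the same analysis written elsewhere hashes identically)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ------------------------------------------------------------- pulse I/O
def write_pulse_csv(trace: PulseTrace, path: str | Path) -> Path:
    """Write a pulse trace as CSV with the trigger in a header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# trigger_time_s={trace.trigger_time_s!r}\n")
        fh.write(f"# sample_rate_hz={trace.sample_rate_hz!r}\n")
        pd.DataFrame(
            {"time_s": trace.times_s, "amplitude_pct": trace.samples}
        ).to_csv(fh, index=False)
    return path


def read_pulse_csv(path: str | Path, trigger_time_s: float | None = None) -> PulseTrace:
    """Read a pulse trace CSV (columns time_s, amplitude_pct)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = float(val)
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "amplitude_pct"} <= set(df.columns):
        raise ManifestError(f"{path}: pulse CSV needs columns time_s, amplitude_pct")
    dt = np.median(np.diff(df["time_s"].to_numpy()))
    rate = header.get("sample_rate_hz", 1.0 / dt)
    trig = trigger_time_s if trigger_time_s is not None else header.get("trigger_time_s")
    if trig is None:
        raise ManifestError(f"{path}: no trigger time in header or manifest")
    return PulseTrace(samples=df["amplitude_pct"].to_numpy(), sample_rate_hz=rate, trigger_time_s=float(trig))


# -------------------------------------------------------------- manifest
def read_manifest(path: str | Path) -> list[dict]:
    """Read and validate a measurement manifest CSV.

    Required columns: subject, measurement, eye, frames_path, pulse_path,
    trigger_time_s, iop_mmHg.  Paths are resolved relative to the manifest.

    Raises
    ------
    ManifestError
        On a missing column, an unreadable referenced path or a duplicate
        (subject, measurement) pair.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ManifestError(f"{path}: manifest contains no measurements")
    dupes = df[df.duplicated(["subject", "measurement"], keep=False)]
    if not dupes.empty:
        pairs = sorted(set(zip(dupes["subject"], dupes["measurement"])))
        raise ManifestError(f"{path}: duplicate (subject, measurement) pairs {pairs}")
    root = path.parent
    descriptors = []
    for _, row in df.iterrows():
        desc = row.to_dict()
        for key in ("frames_path", "pulse_path"):
            p = root / str(desc[key])
            if not p.exists():
                raise ManifestError(f"{path}: unreadable {key} {p}")
            desc[key] = p
        descriptors.append(desc)
    return descriptors


# ------------------------------------------------------------ extraction
def extract_features_from_record(rec: MeasurementRecord, cfg: RunConfig) -> MeasurementRecord:
    """Run imaging + phase extraction for one record carrying raw inputs."""
    contours = extract_contours(
        rec.frames,
        low_frac=cfg.canny_low_frac,
        high_frac=cfg.canny_high_frac,
        sigma=cfg.canny_sigma,
        degree=cfg.poly_degree,
    )
    decomp = decompose_response(contours, peripheral_frac=cfg.peripheral_frac)
    profile = deformation_profile(contours, decomp, central_halfwidth_cols=cfg.central_halfwidth_cols)
    w1, w2 = applanation_times(profile, cfg.flatness_threshold_mm, cfg.smooth_ms)
    w3 = max_deformation(profile, cfg.smooth_ms)
    w4 = vibration_frequency(profile, smooth_ms=cfg.smooth_ms)
    beats = detect_beats(rec.pulse)
    w6 = bin_phase(phase_at(rec.pulse, rec.pulse.trigger_time_s, beats))
    rec.features = assemble_feature_vector(w1, w2, w3, w4, rec.iop_mmHg, w6)
    return rec


def _load_manifest_records(cfg: RunConfig) -> list[MeasurementRecord]:
    records = []
    for desc in read_manifest(cfg.manifest_path):
        records.append(
            MeasurementRecord(
                subject=int(desc["subject"]),
                measurement=int(desc["measurement"]),
                eye=str(desc["eye"]),
                frames=FrameSequence.load(desc["frames_path"]),
                pulse=read_pulse_csv(desc["pulse_path"], float(desc["trigger_time_s"])),
                iop_mmHg=float(desc["iop_mmHg"]),
            )
        )
    return records


# ------------------------------------------------------------------- run
def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline end to end and write all outputs.

    Returns a dict with the fitted results object and the output paths.
    Any stage failure aborts with the stage name and the offending
    (subject, measurement) pair.
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    try:
        logger.info("oculopulse %s  config_hash=%s  seed=%s", __version__, cfg_hash, cfg.seed)
        logger.info("config: %s", json.dumps(cfg.to_dict(), default=str, sort_keys=True))

        if cfg.manifest_path is not None:
            stage = "read_manifest"
            records = _load_manifest_records(cfg)
        elif cfg.synthetic:
            stage = "synthetic_generation"
            records, _ = generate_cohort(
                cfg.n_subjects, cfg.n_meas_per_subject, cfg.cohort, seed=cfg.seed, mode=cfg.mode
            )
        else:
            raise OculopulseError("config error: neither manifest_path nor synthetic mode set")
        counts["input_records"] = len(records)
        logger.info("%s: %d records", stage, len(records))

        stage = "feature_extraction"
        for rec in records:
            if rec.features is None:
                try:
                    extract_features_from_record(rec, cfg)
                except OculopulseError as exc:
                    raise OculopulseError(
                        f"stage {stage} failed for subject {rec.subject} "
                        f"measurement {rec.measurement}: {exc}"
                    ) from exc
        features = records_to_dataframe(records)
        counts["feature_rows"] = len(features)
        logger.info("%s: %d feature rows", stage, len(features))
        if counts["feature_rows"] != counts["input_records"]:
            raise OculopulseError("record count mismatch between stages")
        _write_csv(features, out / "features.csv", cfg_hash, cfg.seed)

        stage = "phase_scan"
        model = PhaseCouplingScan(
            features, phi_step_deg=cfg.phi_step_deg, circular=cfg.circular
        )
        res = model.fit(
            outlier_preset=cfg.outlier_preset,
            feature_std_mode=cfg.feature_std_mode,
            pooled_std_mode=cfg.pooled_std_mode,
        )
        scan_rows = [
            {"subject": subject, "feature": feat, "phi_deg": phi, "r": r}
            for subject, per_feat in sorted(res.scans.items())
            for feat, scan in per_feat.items()
            for phi, r in zip(scan.phi_grid_deg, scan.r_of_phi)
        ]
        _write_csv(pd.DataFrame(scan_rows), out / "scan.csv", cfg_hash, cfg.seed)
        _write_csv(res.feature_table, out / "feature_table.csv", cfg_hash, cfg.seed)
        _write_csv(res.extrema, out / "scan_extrema.csv", cfg_hash, cfg.seed)
        counts["subjects_retained"] = len(res.retained)
        logger.info("%s: retained %d subjects", stage, len(res.retained))

        summary = {
            "config_hash": cfg_hash,
            "seed": cfg.seed,
            "version": __version__,
            "counts": counts,
            "pooled_r_mean": res.pooled_r_mean,
            "pooled_r_std": res.pooled_r_std,
            "pooled_r_std_sample": res.pooled_r_std_sample,
            "mean_optimum_shift_deg": res.mean_optimum_shift_deg,
            "max_iop_std_mmHg": res.max_iop_std,
            "retained_subjects": [int(s) for s in res.retained],
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("done: %s", json.dumps(counts))
        return {"results": res, "summary": summary, "output_dir": out, "features": features}
    finally:
        logger.removeHandler(handler)
        handler.close()
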