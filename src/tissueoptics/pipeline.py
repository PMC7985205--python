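"""End-to-end orchestration: sample -> simulate -> featurize -> train -> evaluate.

A :class:`RunConfig` captures every knob of the workflow in one serializable
document (YAML on disk). ``run_pipeline`` executes the stages, logs per-stage
timings and record counts, and writes a manifest that links every artifact
to the SHA-256 hash of the canonical config, so any output can be
regenerated from its recorded configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
import yaml

from .dataset import ParameterRanges, generate_dataset, split_dataset
from .evaluation import evaluate_model, plot_error_vs_truth, plot_prediction_vs_truth
from .inversion import MomentInversion
from .montecarlo import InvalidParameterError, SimulationConfig, SlabGeometry

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Complete, reproducible description of one pipeline run."""

    n_runs: int = 1000
    n_test: int = 200
    master_seed: int = 0
    out_dir: str = "pipeline_out"
    max_order: int = 5
    include_specular: bool = True
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    geometry: SlabGeometry = field(default_factory=SlabGeometry)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    hidden_size: int = 150
    n_hidden_layers: int = 3
    epochs: int = 5000
    batch_size: int = 256
    learning_rate: float = 1e-3
    signed_log_features: bool = True
    write_plots: bool = True

    def validate(self) -> None:
        """Raise before any simulation work if the config is inconsistent."""
        if self.n_runs < 1:
            raise InvalidParameterError("n_runs must be >= 1")
        if not 0 < self.n_test < self.n_runs:
            raise InvalidParameterError(
                f"n_test must lie in (0, n_runs), got n_test={self.n_test}, n_runs={self.n_runs}"
            )
        if self.epochs < 1 or self.hidden_size < 1:
            raise InvalidParameterError("epochs and hidden_size must be >= 1")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("ranges", ParameterRanges), ("geometry", SlabGeometry), ("sim", SimulationConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON rendering (sorted keys)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return a manifest of artifact paths.

    Artifacts written under ``config.out_dir``: the labeled dataset
    (``dataset.csv``), the serialized model (``model.json``), per-record
    and summary evaluation tables, optional diagnostic plots, the resolved
    config, and ``manifest.json`` keyed by the config hash.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "stages": {}, "artifacts": {}}

    t0 = time.time()
    dataset = generate_dataset(
        n_runs=config.n_runs,
        ranges=config.ranges,
        geometry=config.geometry,
        sim_config=config.sim,
        master_seed=config.master_seed,
        max_order=config.max_order,
        include_specular=config.include_specular,
        progress_every=max(1, config.n_runs // 10),
    )
    dataset = split_dataset(dataset, n_test=config.n_test, seed=config.master_seed)
    dt = time.time() - t0
    logger.info(
        "gen-data: %d records (%d dropped) in %.1f s", len(dataset), dataset.n_dropped, dt
    )
    manifest["stages"]["gen_data"] = {
        "seconds": round(dt, 3),
        "n_records": len(dataset),
        "n_dropped": dataset.n_dropped,
        "n_test": int((dataset.frame["split"] == "test").sum()),
    }
    dataset_path = out / "dataset.csv"
    dataset.to_csv(dataset_path)
    manifest["artifacts"]["dataset"] = str(dataset_path)

    t0 = time.time()
    results = MomentInversion.from_dataset(dataset, split="train").fit(
        hidden_size=config.hidden_size,
        n_hidden_layers=config.n_hidden_layers,
        epochs=config.epochs,
        seed=config.master_seed,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        signed_log_features=config.signed_log_features,
    )
    dt = time.time() - t0
    logger.info("train: [%s] for %d epochs in %.1f s, final loss %.3g",
                ", ".join(map(str, results.layer_sizes)), config.epochs, dt, results.final_loss)
    manifest["stages"]["train"] = {
        "seconds": round(dt, 3),
        "layer_sizes": results.layer_sizes,
        "final_loss": results.final_loss,
    }
    model_path = out / "model.json"
    results.save(model_path)
    manifest["artifacts"]["model"] = str(model_path)

    t0 = time.time()
    report = evaluate_model(results, dataset, split="test")
    dt = time.time() - t0
    logger.info("evaluate: %d test records in %.1f s\n%s", report.n_test, dt, report)
    manifest["stages"]["evaluate"] = {
        "seconds": round(dt, 3),
        "n_test": report.n_test,
        "summary": json.loads(report.summary.to_json()),
    }
    report_path = out / "report.csv"
    records_path = out / "report_records.csv"
    report.summary_to_csv(report_path)
    report.to_csv(records_path)
    manifest["artifacts"]["report_summary"] = str(report_path)
    manifest["artifacts"]["report_records"] = str(records_path)

    if config.write_plots:
        pvt = out / "prediction_vs_truth.png"
        evt = out / "error_vs_truth.png"
        plot_prediction_vs_truth(report, pvt)
        plot_error_vs_truth(report, evt)
        manifest["artifacts"]["prediction_vs_truth"] = str(pvt)
        manifest["artifacts"]["error_vs_truth"] = str(evt)

    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    manifest["artifacts"]["config"] = str(config_path)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest
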