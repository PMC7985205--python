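"""Training-set construction: parameter sampling and labeled feature tables.

Optical properties are drawn independently per run: refractive index and
anisotropy uniform on their biological ranges, scattering and absorption
coefficients log-uniform (they span several decades, so linear-uniform
sampling would starve the low end). Each draw is simulated, the reflected
exit log is compressed to moments, and the (truth, features) pair becomes
one dataset record.

Defaults cover the span reported for human tissue: 1.3 <= n <= 1.6,
0.5 <= g <= 0.95, 0.1 <= mu_s <= 100 mm^-1, 0.01 <= mu_a <= 10 mm^-1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .featurize import compute_moments, moment_labels
from .montecarlo import (
    InvalidParameterError,
    OpticalProperties,
    SimulationConfig,
    SlabGeometry,
    run_simulation,
)

__all__ = [
    "ParameterRanges",
    "Dataset",
    "sample_parameters",
    "generate_dataset",
    "split_dataset",
    "TRUTH_COLUMNS",
]

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["n", "g", "mu_s", "mu_a", "mu_s_prime"]
_META_COLUMNS = ["run_id", "seed", "split"]


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling bounds for the four optical parameters."""

    n_min: float = 1.3
    n_max: float = 1.6
    g_min: float = 0.5
    g_max: float = 0.95
    mu_s_min: float = 0.1
    mu_s_max: float = 100.0
    mu_a_min: float = 0.01
    mu_a_max: float = 10.0

    def __post_init__(self) -> None:
        pairs = [
            ("n", self.n_min, self.n_max),
            ("g", self.g_min, self.g_max),
            ("mu_s", self.mu_s_min, self.mu_s_max),
            ("mu_a", self.mu_a_min, self.mu_a_max),
        ]
        for name, lo, hi in pairs:
            if not lo < hi:
                raise InvalidParameterError(f"{name} range requires min < max, got [{lo}, {hi}]")
        if self.mu_s_min <= 0.0 or self.mu_a_min <= 0.0:
            raise InvalidParameterError("log-uniform sampling requires positive lower bounds")


def sample_parameters(
    ranges: ParameterRanges, u1: float, u2: float, u3: float, u4: float
) -> OpticalProperties:
    """Map four uniform deviates in [0, 1] to one parameter realization.

    n and g are linear-uniform; mu_s and mu_a are log-uniform (uniform in
    log10 between the bounds; the log base is immaterial to the induced
    distribution).
    """
    for u in (u1, u2, u3, u4):
        if not 0.0 <= u <= 1.0:
            raise InvalidParameterError(f"uniform deviates must lie in [0, 1], got {u}")
    n = (ranges.n_max - ranges.n_min) * u1 + ranges.n_min
    g = (ranges.g_max - ranges.g_min) * u2 + ranges.g_min
    log_mu_s = (np.log10(ranges.mu_s_max) - np.log10(ranges.mu_s_min)) * u3 + np.log10(
        ranges.mu_s_min
    )
    log_mu_a = (np.log10(ranges.mu_a_max) - np.log10(ranges.mu_a_min)) * u4 + np.log10(
        ranges.mu_a_min
    )
    return OpticalProperties(n=n, g=g, mu_s=float(10.0**log_mu_s), mu_a=float(10.0**log_mu_a))


@dataclass
class Dataset:
    """Labeled feature table: one row per simulated slab realization.

    ``frame`` columns: run_id, seed, split ('train'|'test'), the five truth
    columns (n, g, mu_s, mu_a, mu_s_prime) and the moment features in
    canonical order.
    """

    frame: pd.DataFrame
    ranges: ParameterRanges
    geometry: SlabGeometry
    sim_config: SimulationConfig
    max_order: int = 5
    master_seed: int = 0
    n_dropped: int = 0

    @property
    def feature_columns(self) -> List[str]:
        return moment_labels(self.max_order)

    def __len__(self) -> int:
        return len(self.frame)

    def _subset(self, split: Optional[str]) -> pd.DataFrame:
        if split is None:
            return self.frame
        if split not in ("train", "test"):
            raise InvalidParameterError(f"split must be train|test|None, got {split!r}")
        return self.frame[self.frame["split"] == split]

    def features(self, split: Optional[str] = None) -> np.ndarray:
        """Moment features as an (n_records, n_features) array."""
        return self._subset(split)[self.feature_columns].to_numpy(dtype=float)

    def targets(self, split: Optional[str] = None) -> np.ndarray:
        """Inversion targets (n, mu_s_prime, mu_a) as an (n_records, 3) array."""
        return self._subset(split)[["n", "mu_s_prime", "mu_a"]].to_numpy(dtype=float)

    def truths(self, split: Optional[str] = None) -> pd.DataFrame:
        return self._subset(split)[TRUTH_COLUMNS]

    # -- persistence --------------------------------------------------------

    def _metadata(self) -> dict:
        return {
            "ranges": asdict(self.ranges),
            "geometry": asdict(self.geometry),
            "sim_config": asdict(self.sim_config),
            "max_order": self.max_order,
            "master_seed": self.master_seed,
            "n_dropped": self.n_dropped,
        }

    def to_csv(self, path) -> None:
        """Write a single CSV: one '#'-prefixed JSON metadata line + rows."""
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self._metadata()) + "\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path} is missing the metadata header line")
            meta = json.loads(header.lstrip("#").strip())
            frame = pd.read_csv(fh, float_precision="round_trip")
        return cls(
            frame=frame,
            ranges=ParameterRanges(**meta["ranges"]),
            geometry=SlabGeometry(**meta["geometry"]),
            sim_config=SimulationConfig(**meta["sim_config"]),
            max_order=meta["max_order"],
            master_seed=meta["master_seed"],
            n_dropped=meta["n_dropped"],
        )

    def to_parquet(self, path) -> None:
        """Binary columnar container for large runs (metadata in the schema)."""
        import pyarrow as pa
        import pyarrow.parquet as pq

        table = pa.Table.from_pandas(self.frame, preserve_index=False)
        table = table.replace_schema_metadata(
            {b"tissueoptics": json.dumps(self._metadata()).encode()}
        )
        pq.write_table(table, path)

    @classmethod
    def from_parquet(cls, path) -> "Dataset":
        import pyarrow.parquet as pq

        table = pq.read_table(path)
        meta = json.loads(table.schema.metadata[b"tissueoptics"].decode())
        return cls(
            frame=table.to_pandas(),
            ranges=ParameterRanges(**meta["ranges"]),
            geometry=SlabGeometry(**meta["geometry"]),
            sim_config=SimulationConfig(**meta["sim_config"]),
            max_order=meta["max_order"],
            master_seed=meta["master_seed"],
            n_dropped=meta["n_dropped"],
        )


def _run_seed(master_seed: int, run_id: int) -> int:
    """Deterministic per-run simulation seed (independent of batching)."""
    return int(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(1, run_id)).generate_state(1)[0]
    )


def generate_dataset(
    n_runs: int,
    ranges: Optional[ParameterRanges] = None,
    geometry: Optional[SlabGeometry] = None,
    sim_config: Optional[SimulationConfig] = None,
    master_seed: int = 0,
    max_order: int = 5,
    include_specular: bool = True,
    progress_every: int = 0,
) -> Dataset:
    """Sample, simulate and featurize ``n_runs`` slab realizations.

    Each record's parameter draw and simulation seed derive deterministically
    from ``master_seed`` and the run id, so any record can be regenerated
    bit-identically in isolation. Records whose reflection detector caught
    zero weight are dropped (counted in ``n_dropped``), never imputed.
    """
    if n_runs < 1:
        raise InvalidParameterError("n_runs must be >= 1")
    ranges = ranges or ParameterRanges()
    geometry = geometry or SlabGeometry()
    sim_config = sim_config or SimulationConfig()

    param_rng = np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(0,)))
    deviates = param_rng.random((n_runs, 4))

    labels = moment_labels(max_order)
    rows = []
    n_dropped = 0
    for run_id in range(n_runs):
        u1, u2, u3, u4 = deviates[run_id]
        props = sample_parameters(ranges, u1, u2, u3, u4)
        seed = _run_seed(master_seed, run_id)
        result = run_simulation(props, geometry, replace(sim_config, seed=seed))
        fv = compute_moments(result, max_order=max_order, include_specular=include_specular)
        if not fv.valid:
            n_dropped += 1
            continue
        row = {
            "run_id": run_id,
            "seed": seed,
            "split": "train",
            "n": props.n,
            "g": props.g,
            "mu_s": props.mu_s,
            "mu_a": props.mu_a,
            "mu_s_prime": props.mu_s_prime,
        }
        row.update(dict(zip(labels, fv.values)))
        rows.append(row)
        if progress_every and (run_id + 1) % progress_every == 0:
            logger.info("generated %d/%d runs (%d dropped)", run_id + 1, n_runs, n_dropped)
    if not rows:
        raise RuntimeError("every generated record had an empty reflection detector")
    if n_dropped:
        logger.info("dropped %d/%d records with empty reflection detectors", n_dropped, n_runs)
    frame = pd.DataFrame(rows, columns=_META_COLUMNS + TRUTH_COLUMNS[:4] + ["mu_s_prime"] + labels)
    return Dataset(
        frame=frame,
        ranges=ranges,
        geometry=geometry,
        sim_config=sim_config,
        max_order=max_order,
        master_seed=master_seed,
        n_dropped=n_dropped,
    )


def split_dataset(dataset: Dataset, n_test: int, seed: int = 0) -> Dataset:
    """Label a uniformly random, seed-reproducible test subset.

    Returns a new Dataset; the input is not modified. ``n_test = 0`` marks
    everything as training data.
    """
    n_records = len(dataset)
    if n_test < 0 or n_test >= n_records:
        raise InvalidParameterError(
            f"n_test must lie in [0, n_records), got {n_test} of {n_records}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    test_idx = rng.choice(n_records, size=n_test, replace=False)
    split = np.full(n_records, "train", dtype=object)
    split[test_idx] = "test"
    frame = dataset.frame.copy()
    frame["split"] = split
    return replace(dataset, frame=frame)
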