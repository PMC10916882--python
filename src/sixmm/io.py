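"""File formats, configuration, model artifacts, manifests and fixtures.

Trajectory files are plain CSV with header
``t_ms,left_P,left_M,left_A,right_P,right_M,right_A`` (deflections in mm,
left negative).  Datasets go to HDF5 (or NPZ as fallback) with datasets
``/trajectories`` (float32, N x 6 x n), ``/q`` (N x 14),
``/rest_positions`` (N x 6) and generation metadata as attributes.  Model
artifacts bundle the network weights with its architecture config and a
config hash that the loader validates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import sys
import warnings
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .model import PhysicalConfig, RestPositionGrid, ScalingVector, TrajectorySet
from .sampling import (
    DEFAULT_MARGINALS,
    DEFAULT_RHO,
    TABLE_MARGINALS_CM,
    CopulaSpec,
    GammaMarginal,
    LabeledDataset,
    LogUniformBounds,
    build_dataset,
    sample_rest_positions,
)
from .surrogate import CRNN, SurrogateConfig

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "save_dataset",
    "load_dataset",
    "save_physical_config",
    "load_physical_config",
    "save_model",
    "load_model",
    "write_manifest",
    "make_fixtures",
    "load_marginals",
]

TRAJECTORY_COLUMNS = [
    "t_ms",
    "left_P",
    "left_M",
    "left_A",
    "right_P",
    "right_M",
    "right_A",
]


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------

def read_trajectories(path) -> TrajectorySet:
    """Read a trajectory CSV; dt is inferred from the time column.

    The documented sign convention (left <= 0, right >= 0) is checked and
    violations produce a warning, not an error — recorded data may carry
    segmentation noise across the midline.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} is missing columns: {missing}")
    if len(df) < 2:
        raise ValueError("trajectory file needs at least 2 rows")
    values = df[TRAJECTORY_COLUMNS[1:]].to_numpy(dtype=float).T
    if not np.all(np.isfinite(values)):
        raise ValueError("trajectory file contains non-numeric or non-finite cells")
    t = df["t_ms"].to_numpy(dtype=float)
    dt = float(np.mean(np.diff(t)))
    if dt <= 0:
        raise ValueError("time column must be strictly increasing")
    if values[:3].max() > 0 or values[3:].min() < 0:
        warnings.warn(
            f"{path}: sign convention violated (left should be <= 0, right >= 0); "
            "data preserved as read",
            stacklevel=2,
        )
    return TrajectorySet(values=values, dt=dt)


def write_trajectories(path, T: TrajectorySet) -> None:
    data = {"t_ms": T.times_ms}
    for name, row in zip(TRAJECTORY_COLUMNS[1:], T.values):
        data[name] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def save_dataset(path, ds: LabeledDataset) -> None:
    path = Path(path)
    meta = dict(
        seed=ds.seed,
        q_min=ds.bounds.q_min,
        q_max=ds.bounds.q_max,
        dt=ds.dt,
        survival_fraction=ds.survival_fraction,
        n_requested=ds.n_requested,
        n_excluded=ds.n_excluded,
        n_unstable=ds.n_unstable,
    )
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("trajectories", data=ds.trajectories.astype(np.float32))
            f.create_dataset("q", data=ds.q)
            f.create_dataset("rest_positions", data=ds.rest_positions)
            for k, v in meta.items():
                f.attrs[k] = v
    else:
        np.savez_compressed(
            path,
            trajectories=ds.trajectories.astype(np.float32),
            q=ds.q,
            rest_positions=ds.rest_positions,
            **{k: np.asarray(v) for k, v in meta.items()},
        )


def load_dataset(path) -> LabeledDataset:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            arrays = {k: f[k][()] for k in ("trajectories", "q", "rest_positions")}
            meta = {k: f.attrs[k] for k in f.attrs}
    else:
        with np.load(path) as z:
            arrays = {k: z[k] for k in ("trajectories", "q", "rest_positions")}
            meta = {k: z[k][()] for k in z.files if k not in arrays}
    return LabeledDataset(
        trajectories=arrays["trajectories"],
        q=arrays["q"],
        rest_positions=arrays["rest_positions"],
        dt=float(meta["dt"]),
        seed=int(meta["seed"]),
        bounds=LogUniformBounds(float(meta["q_min"]), float(meta["q_max"])),
        survival_fraction=float(meta["survival_fraction"]),
        n_requested=int(meta["n_requested"]),
        n_excluded=int(meta["n_excluded"]),
        n_unstable=int(meta.get("n_unstable", 0)),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def save_physical_config(path, cfg: PhysicalConfig) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(cfg), f, sort_keys=False)


def load_physical_config(path) -> PhysicalConfig:
    with open(path) as f:
        doc = yaml.safe_load(f)
    return PhysicalConfig(**doc)


# ---------------------------------------------------------------------------
# Model artifacts
# ---------------------------------------------------------------------------

def _config_hash(cfg: SurrogateConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def save_model(path, model: CRNN) -> None:
    cfg_json = json.dumps(dataclasses.asdict(model.config), sort_keys=True)
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(
        path,
        __config__=np.bytes_(cfg_json.encode()),
        __config_hash__=np.bytes_(_config_hash(model.config).encode()),
        __seed__=np.asarray(model.seed),
        **arrays,
    )


def load_model(path) -> CRNN:
    with np.load(path) as z:
        cfg_doc = json.loads(bytes(z["__config__"]).decode())
        stored_hash = bytes(z["__config_hash__"]).decode()
        cfg = SurrogateConfig(**cfg_doc)
        if _config_hash(cfg) != stored_hash:
            raise ValueError("model artifact config hash mismatch")
        state = {
            k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")
        }
        seed = int(z["__seed__"])
    model = CRNN(cfg, seed=seed)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(path, command: str, seeds: dict, inputs: dict, outputs: dict,
                   config: dict | None = None) -> None:
    """One JSON manifest per CLI run: enough to re-run bit-compatibly."""
    doc = {
        "command": command,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seeds": seeds,
        "inputs": inputs,
        "outputs": outputs,
        "config": config or {},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=2, default=str)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixtures(outdir, seed: int = 0) -> dict[str, Path]:
    """Write the deterministic micro-fixture bundle used by the tests.

    Contents: a 32-sample simulated dataset (NPZ), one default-parameter
    trajectory CSV, the default correlation matrix (CSV), and the
    published gamma marginals (YAML, stated in their original cm unit).
    No download is ever needed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cfg = PhysicalConfig()
    ds = build_dataset(32, seed=seed, cfg=cfg)
    paths["dataset"] = outdir / "micro_dataset.npz"
    save_dataset(paths["dataset"], ds)

    rng = np.random.default_rng(seed)
    rest = sample_rest_positions(DEFAULT_MARGINALS, CopulaSpec(), 1, rng)[0]
    from .model import extract_trajectories, simulate

    history = simulate(ScalingVector.identity(), RestPositionGrid(rest), cfg)
    T = extract_trajectories(history, cfg)
    paths["trajectory"] = outdir / "default_trajectory.csv"
    write_trajectories(paths["trajectory"], T)

    paths["rho"] = outdir / "default_rho.csv"
    labels = ["left_P", "left_M", "left_A", "right_P", "right_M", "right_A"]
    pd.DataFrame(DEFAULT_RHO, index=labels, columns=labels).to_csv(paths["rho"])

    paths["marginals"] = outdir / "marginals.yaml"
    doc = {
        "units": "cm",
        "marginals": {
            name: {"alpha": m.alpha, "beta": m.beta, "c": m.c}
            for name, m in TABLE_MARGINALS_CM.items()
        },
    }
    with open(paths["marginals"], "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)
    return paths


def load_marginals(path) -> dict[str, GammaMarginal]:
    """Load a marginals YAML; cm-unit files are converted to mm."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    scale = 10.0 if doc.get("units", "mm") == "cm" else 1.0
    return {
        name: GammaMarginal(m["alpha"], m["beta"] * scale, m["c"] * scale)
        for name, m in doc["marginals"].items()
    }
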