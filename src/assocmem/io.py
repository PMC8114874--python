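"""Serialization: weight matrices, configs, run manifests.

Weight matrices are written as dense CSV or sparse MatrixMarket (MTX) with
a JSON side-car holding the network spec, seeds and solver diagnostics, so
that every artifact is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .loading import WeightMatrix
from .params import NetworkSpec, NeuronParams

__all__ = [
    "save_weights",
    "load_weights",
    "spec_to_dict",
    "spec_from_dict",
    "load_config",
    "echo_config",
    "write_manifest",
]


def spec_to_dict(spec: NetworkSpec) -> dict:
    return dict(
        n=spec.n,
        n_inh=spec.n_inh,
        seed=spec.seed,
        neurons=[asdict(p) for p in spec.neurons],
    )


def spec_from_dict(d: dict) -> NetworkSpec:
    return NetworkSpec(
        n=d["n"],
        n_inh=d["n_inh"],
        seed=d.get("seed", 0),
        neurons=tuple(NeuronParams(**p) for p in d["neurons"]),
    )


def save_weights(
    W: WeightMatrix, path: str | Path, sparse: bool | None = None, meta: dict | None = None
) -> None:
    """Write the scaled weight matrix as MTX (``.mtx``) or CSV plus a JSON
    side-car with the spec and per-neuron feasibility."""
    path = Path(path)
    if sparse is None:
        sparse = path.suffix == ".mtx"
    if sparse:
        sio.mmwrite(str(path), sp.csr_matrix(W.J_tilde))
    else:
        np.savetxt(path, W.J_tilde, delimiter=",", fmt="%.17g")
    sidecar = dict(feasible=W.feasible.astype(int).tolist())
    if W.spec is not None:
        sidecar["spec"] = spec_to_dict(W.spec)
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_weights(path: str | Path) -> WeightMatrix:
    path = Path(path)
    if path.suffix == ".mtx":
        J = np.asarray(sio.mmread(str(path)).todense())
    else:
        J = np.loadtxt(path, delimiter=",", ndmin=2)
    side = path.with_suffix(path.suffix + ".json")
    feasible = np.ones(J.shape[0], dtype=bool)
    spec = None
    if side.exists():
        d = json.loads(side.read_text())
        feasible = np.asarray(d.get("feasible", feasible), dtype=bool)
        if "spec" in d:
            spec = spec_from_dict(d["spec"])
    return WeightMatrix(J_tilde=J, feasible=feasible, spec=spec)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def echo_config(cfg: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def write_manifest(outdir: str | Path, **entries) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(entries, indent=2, default=str))
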