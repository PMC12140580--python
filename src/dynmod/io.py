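"""Delimited-text readers and writers for every pipeline artifact.

- timeseries panel: first header line ``# tr=<seconds>``, then N rows ×
  T tab-separated columns; region metadata in a sidecar table;
- trial table: TSV with columns day, trial, bin, target_deg, error_deg;
- matrices (coherence layers, allegiance P/T, factor H): TSV;
- partitions: L rows × N columns of integer labels;
- manifests and ground truth: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import TimeSeriesPanel, WindowSpec, MultilayerNetwork
from .modularity import Partition, PartitionEnsemble

__all__ = [
    "write_panel", "read_panel", "write_trials", "read_trials",
    "write_matrix", "read_matrix", "write_multilayer", "read_multilayer",
    "write_ensemble", "read_ensemble", "write_json", "read_json",
    "write_regions", "read_regions",
]

TRIAL_COLUMNS = ["day", "trial", "bin", "target_deg", "error_deg"]


def write_panel(path, panel: TimeSeriesPanel) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tr={panel.tr}\n")
        np.savetxt(fh, panel.data, fmt="%.17g", delimiter="\t")


def read_panel(path, subject: str = "", region_ids: list[str] | None = None) -> TimeSeriesPanel:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# tr="):
            raise ValueError(f"{path}: missing '# tr=<seconds>' header")
        tr = float(header.split("=", 1)[1])
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return TimeSeriesPanel(data=data, tr=tr, subject=subject, region_ids=region_ids or [])


def write_trials(path, trials: pd.DataFrame) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"{path}: missing trial columns {sorted(missing)}")
    return t


def write_regions(path, region_ids: list[str], names: list[str], network_labels) -> None:
    pd.DataFrame(
        {"region_id": region_ids, "name": names, "task_network": network_labels}
    ).to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(path, matrix: np.ndarray, region_ids: list[str] | None = None) -> None:
    if region_ids:
        pd.DataFrame(matrix, columns=region_ids).to_csv(path, sep="\t", index=False)
    else:
        np.savetxt(path, matrix, fmt="%.17g", delimiter="\t")


def read_matrix(path, has_header: bool = False) -> np.ndarray:
    if has_header:
        return pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_multilayer(dirpath, net: MultilayerNetwork) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for l in range(net.n_layers):
        write_matrix(d / f"layer{l:03d}.tsv", net.layers[l])
    write_json(d / "manifest.json", {
        "n_layers": net.n_layers,
        "n_regions": net.n_regions,
        "band_hz": list(net.band),
        "threshold": net.threshold,
        "sparsity": net.sparsity,
        "window": {"length": net.window.length, "step": net.window.step},
        "subject": net.subject,
    })


def read_multilayer(dirpath) -> MultilayerNetwork:
    d = Path(dirpath)
    man = read_json(d / "manifest.json")
    layers = np.stack(
        [read_matrix(d / f"layer{l:03d}.tsv") for l in range(man["n_layers"])]
    )
    return MultilayerNetwork(
        layers=layers,
        window=WindowSpec(**man["window"]),
        band=tuple(man["band_hz"]),
        threshold=man["threshold"],
        subject=man.get("subject", ""),
    )


def write_ensemble(dirpath, ensemble: PartitionEnsemble) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for r, part in enumerate(ensemble.partitions):
        np.savetxt(d / f"partition{r:03d}.tsv", part.labels, fmt="%d", delimiter="\t")
    write_json(d / "manifest.json", {
        "n_partitions": ensemble.n_partitions,
        "quality": [p.quality for p in ensemble.partitions],
        "mean_quality": ensemble.mean_quality,
    })


def read_ensemble(dirpath) -> PartitionEnsemble:
    d = Path(dirpath)
    man = read_json(d / "manifest.json")
    parts = []
    for r in range(man["n_partitions"]):
        labels = np.loadtxt(d / f"partition{r:03d}.tsv", dtype=int, delimiter="\t", ndmin=2)
        parts.append(Partition(labels=labels, quality=man["quality"][r]))
    return PartitionEnsemble(partitions=parts)


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
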