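"""Plain-text readers and writers.

Everything the pipeline emits is diffable text: signal matrices as
tab-separated tables (header row = channel names, one row per sample, with
the sampling rate in a leading comment line), montages as name-x-y-z lines,
truth labels as one symbol per line, and all tables (subjects, metrics,
statistics, models) as TSV.  EDF/BDF recordings can be *read* through MNE
when it is installed; there is no EDF writer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Recording
from .model import MicrostateModel
from .synthetic import TemplateSet

__all__ = [
    "write_recording", "read_recording", "read_edf",
    "write_montage", "read_montage",
    "write_labels", "read_labels",
    "write_subject_table", "read_subject_table",
    "write_model", "read_model",
    "write_table", "read_table",
]

_RATE_PREFIX = "# sampling_rate_hz:"


def write_recording(path, rec: Recording) -> None:
    """Signal matrix as TSV: comment line with the rate, channel-name
    header, then one row per sample."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_RATE_PREFIX} {rec.sampling_rate_hz:g}\n")
        fh.write("\t".join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter="\t")


def read_recording(path, sampling_rate_hz: Optional[float] = None,
                   positions: Optional[np.ndarray] = None) -> Recording:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if first.startswith(_RATE_PREFIX):
            rate = float(first[len(_RATE_PREFIX):])
            header = fh.readline().strip()
        else:
            rate = None
            header = first
        names = header.split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if sampling_rate_hz is not None:
        rate = sampling_rate_hz
    if rate is None:
        raise ValueError(
            f"{path} has no sampling-rate comment; pass sampling_rate_hz"
        )
    return Recording(data=data.T, sampling_rate_hz=rate, channel_names=names,
                     channel_positions=positions)


def read_edf(path) -> Recording:
    """Read an EDF/BDF recording via MNE (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF/BDF requires the 'mne' package (install extra "
            "'mstates[edf]')"
        ) from exc
    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data=data, sampling_rate_hz=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names))


def write_montage(path, channel_names: Sequence[str],
                  positions: np.ndarray) -> None:
    with Path(path).open("w") as fh:
        for name, (x, y, z) in zip(channel_names, positions):
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_montage(path) -> tuple[list[str], np.ndarray]:
    names, rows = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    return names, np.asarray(rows)


def write_labels(path, labels: np.ndarray,
                 class_labels: Sequence[str]) -> None:
    """Per-sample truth/segmentation labels, one symbol per line
    ('.' = unassigned)."""
    symbols = ["." if lab < 0 else class_labels[lab] for lab in labels]
    Path(path).write_text("\n".join(symbols) + "\n")


def read_labels(path, class_labels: Sequence[str]) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(class_labels)}
    lookup["."] = -1
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(lookup[line])
    return np.asarray(out, dtype=int)


def write_subject_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_model(path, model: MicrostateModel) -> None:
    """Model maps as TSV (row per class) plus a YAML metadata sidecar."""
    path = Path(path)
    names = model.channel_names or [
        f"ch{i + 1}" for i in range(model.maps.shape[1])
    ]
    df = pd.DataFrame(model.maps, columns=names)
    df.insert(0, "class", model.class_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    meta = {
        "k": int(model.n_classes),
        "gev": float(model.gev),
        "level": model.level,
    }
    path.with_suffix(path.suffix + ".meta.yaml").write_text(
        yaml.safe_dump(meta)
    )


def read_model(path) -> MicrostateModel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    labels = df["class"].astype(str).tolist()
    maps = df.drop(columns=["class"]).to_numpy(dtype=float)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = (
        yaml.safe_load(meta_path.read_text()) if meta_path.exists()
        else {"gev": 0.0, "level": "subject"}
    )
    return MicrostateModel(
        maps=maps,
        class_labels=labels,
        gev=float(meta.get("gev", 0.0)),
        level=meta.get("level", "subject"),
        channel_names=[c for c in df.columns if c != "class"],
    )


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def templates_to_model(templates: TemplateSet) -> MicrostateModel:
    """View a (truth or canonical) template set as a labeled model, e.g. to
    backfit with known maps."""
    return MicrostateModel(
        maps=templates.maps.copy(),
        class_labels=list(templates.class_labels),
        gev=1.0,
        level="group",
        channel_names=list(templates.channel_names),
    )
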