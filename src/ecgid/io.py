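"""Reading and writing ECG recordings, segment containers and GAF datasets.

Formats
-------
* Single recording, CSV: one sample per row in a column named ``amplitude``;
  the sampling rate (and optional labels) ride in ``# key=value`` header
  comments, e.g. ``# fs=128``.
* Segment container / GAF dataset: a compressed ``.npz`` holding the array
  payload (``segments`` or ``images``), a ``labels`` vector and a JSON
  ``meta`` record.  Arrays round-trip bit-identically.
* WFDB-dialect records (public ECG archives): optional adapter that activates
  only when the ``wfdb`` package is importable; never required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputFormatError, ValidationError
from .gaf import GAFImage
from .records import ECGRecording, Segment

__all__ = [
    "GAFDataset",
    "read_recording",
    "write_recording",
    "write_segments",
    "read_segments",
    "write_gaf_dataset",
    "read_gaf_dataset",
    "read_wfdb_recording",
]


@dataclass
class GAFDataset:
    """A labelled stack of same-sized GAF images (the classifier's dataset)."""

    images: np.ndarray  # (count, n, n)
    labels: np.ndarray  # (count,) subject ids
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=str)
        if images.size == 0:
            images = images.reshape(0, 0, 0)
        if images.ndim != 3 or (images.size and images.shape[1] != images.shape[2]):
            raise ValidationError("images must form a (count, n, n) stack")
        if labels.shape[0] != images.shape[0]:
            raise ValidationError(
                f"label count {labels.shape[0]} != image count {images.shape[0]}"
            )
        self.images = images
        self.labels = labels

    def __len__(self) -> int:
        return int(self.images.shape[0])

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique subject labels."""
        return np.unique(self.labels)

    @classmethod
    def from_images(cls, images: list[GAFImage], meta: dict | None = None) -> "GAFDataset":
        """Stack per-window images; all must share dimensions and have labels."""
        if not images:
            return cls(np.zeros((0, 0, 0)), np.zeros((0,), dtype=str), meta or {})
        sizes = {im.paa_size for im in images}
        if len(sizes) > 1:
            raise ValidationError(f"images have mismatched dimensions: {sorted(sizes)}")
        stack = np.stack([im.matrix for im in images])
        labels = np.asarray([im.subject_id or "unknown" for im in images])
        return cls(stack, labels, meta or {})

    def subset(self, indices: np.ndarray) -> "GAFDataset":
        return GAFDataset(self.images[indices], self.labels[indices], dict(self.meta))


def _parse_header_comments(path: Path) -> dict:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                out[key.strip()] = val.strip()
    return out


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    sampling_rate: float | None = None,
) -> ECGRecording:
    """Read one recording from CSV or a compressed array file.

    CSV needs a column named ``amplitude`` and the sampling rate either as a
    ``# fs=<Hz>`` header comment or via the ``sampling_rate`` argument.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    if fmt is None:
        fmt = "npz" if path.suffix == ".npz" else "csv"
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            if "samples" not in z or "fs" not in z:
                raise InputFormatError(f"{path}: missing 'samples' or 'fs' field")
            meta = json.loads(str(z["meta"])) if "meta" in z else {}
            return ECGRecording(
                samples=z["samples"],
                sampling_rate=float(z["fs"]),
                subject_id=meta.get("subject_id", "unknown"),
                activity=meta.get("activity", "unknown"),
                lead=meta.get("lead", "II-modified"),
            )
    header = _parse_header_comments(path)
    fs = sampling_rate if sampling_rate is not None else header.get("fs")
    if fs is None:
        raise InputFormatError(
            f"{path}: sampling rate missing — provide a '# fs=<Hz>' header "
            "comment or the sampling_rate argument"
        )
    try:
        fs = float(fs)
    except ValueError as exc:
        raise InputFormatError(f"{path}: sampling rate field not numeric: {fs!r}") from exc
    import pandas as pd

    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "amplitude" not in frame.columns:
        raise InputFormatError(
            f"{path}: no 'amplitude' column (found {list(frame.columns)})"
        )
    samples = frame["amplitude"].to_numpy(dtype=np.float64)
    return ECGRecording(
        samples=samples,
        sampling_rate=fs,
        subject_id=header.get("subject_id", "unknown"),
        activity=header.get("activity", "unknown"),
        lead=header.get("lead", "II-modified"),
    )


def write_recording(recording: ECGRecording, path: str | Path) -> Path:
    """Write one recording as a commented CSV (see :func:`read_recording`)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.sampling_rate}\n")
        fh.write(f"# subject_id={recording.subject_id}\n")
        fh.write(f"# activity={recording.activity}\n")
        fh.write(f"# lead={recording.lead}\n")
        fh.write("amplitude\n")
        np.savetxt(fh, recording.samples, fmt="%.17g")
    return path


def write_segments(segments: list[Segment], path: str | Path) -> Path:
    """Write same-length segments as a compressed container."""
    path = Path(path)
    if not segments:
        raise ValidationError("cannot write an empty segment list")
    lengths = {s.samples.size for s in segments}
    if len(lengths) > 1:
        raise ValidationError(f"segments have mismatched lengths: {sorted(lengths)}")
    meta = {
        "sampling_rate": segments[0].sampling_rate,
        "activities": [s.activity for s in segments],
        "indices": [s.index for s in segments],
    }
    np.savez_compressed(
        path,
        segments=np.stack([s.samples for s in segments]),
        labels=np.asarray([s.subject_id for s in segments]),
        meta=json.dumps(meta),
    )
    return path


def read_segments(path: str | Path) -> list[Segment]:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    with np.load(path, allow_pickle=False) as z:
        if "segments" not in z or "labels" not in z:
            raise InputFormatError(f"{path}: missing 'segments' or 'labels' field")
        meta = json.loads(str(z["meta"])) if "meta" in z else {}
        arr = z["segments"]
        labels = z["labels"]
        fs = float(meta.get("sampling_rate", 1.0))
        acts = meta.get("activities", ["unknown"] * arr.shape[0])
        idxs = meta.get("indices", list(range(arr.shape[0])))
        return [
            Segment(arr[i], fs, subject_id=str(labels[i]), activity=acts[i], index=idxs[i])
            for i in range(arr.shape[0])
        ]


def write_gaf_dataset(dataset: GAFDataset, path: str | Path) -> Path:
    """Write a GAF dataset; the write->read round trip is bit-identical."""
    path = Path(path)
    np.savez_compressed(
        path,
        images=dataset.images,
        labels=dataset.labels,
        meta=json.dumps(dataset.meta),
    )
    return path


def read_gaf_dataset(path: str | Path) -> GAFDataset:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    with np.load(path, allow_pickle=False) as z:
        for key in ("images", "labels"):
            if key not in z:
                raise InputFormatError(f"{path}: missing {key!r} field")
        meta = json.loads(str(z["meta"])) if "meta" in z else {}
        return GAFDataset(z["images"], z["labels"], meta)


def read_wfdb_recording(record_path: str, channel: int = 0) -> ECGRecording:
    """Optional adapter for WFDB-dialect archive records.

    Requires the third-party ``wfdb`` package; raises ImportError with a
    clear message when it is not installed.  Never used by the core pipeline
    or the test suite.
    """
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - capability check
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package"
        ) from exc
    rec = wfdb.rdrecord(record_path)  # pragma: no cover
    return ECGRecording(  # pragma: no cover
        samples=np.asarray(rec.p_signal)[:, channel],
        sampling_rate=float(rec.fs),
        subject_id=str(rec.record_name),
        lead=str(rec.sig_name[channel]) if rec.sig_name else "II-modified",
    )
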