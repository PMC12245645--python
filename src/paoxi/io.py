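"""HDF5 container for study datasets, plus validation and content hashing.

Layout: one group per subject under ``/subjects``, one float32 dataset per
sample (``stack``, shape 21 x H x W) with the annotation stored as attributes
(``fio2``, ``o2satss_gt``, ``sss_x``, ``sss_y``).  Datasets are written with
``track_times=False`` so that identical content yields byte-identical files,
which makes seeded simulation runs hashable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .core import SampleRecord, SpectralImage, StudyDataset

SCHEMA_VERSION = 1


class SchemaVersionError(RuntimeError):
    """Raised when a container was written with an incompatible schema."""


def save_dataset(ds: StudyDataset, path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subjects"] = [str(s) for s in ds.subjects]
        root = f.create_group("subjects", track_order=True)
        per_subject: dict[str, int] = {}
        for order, sample in enumerate(ds.samples):
            sid = str(sample.subject_id)
            grp = root.require_group(sid)
            idx = per_subject.get(sid, 0)
            per_subject[sid] = idx + 1
            dset = grp.create_dataset(
                f"sample_{idx:04d}",
                data=np.asarray(sample.image.pixels, dtype=np.float32),
                track_times=False,
            )
            dset.attrs["fio2"] = float(sample.fio2)
            dset.attrs["o2satss_gt"] = float(sample.o2satss_gt)
            dset.attrs["sss_x"] = int(sample.sss_xy[0])
            dset.attrs["sss_y"] = int(sample.sss_xy[1])
            dset.attrs["pixel_spacing_mm"] = float(sample.image.pixel_spacing_mm)
            dset.attrs["order"] = order  # flat study order, for order-preserving reload


def load_dataset(path) -> StudyDataset:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"container schema {version} incompatible with reader schema {SCHEMA_VERSION}"
            )
        subjects = [str(s) for s in f.attrs["subjects"]]
        records: list[tuple[int, SampleRecord]] = []
        for sid in f["subjects"]:
            grp = f["subjects"][sid]
            for name in grp:
                dset = grp[name]
                img = SpectralImage(
                    dset[()], pixel_spacing_mm=float(dset.attrs["pixel_spacing_mm"])
                )
                rec = SampleRecord(
                    image=img,
                    subject_id=str(sid),
                    fio2=float(dset.attrs["fio2"]),
                    o2satss_gt=float(dset.attrs["o2satss_gt"]),
                    sss_xy=(int(dset.attrs["sss_x"]), int(dset.attrs["sss_y"])),
                )
                records.append((int(dset.attrs["order"]), rec))
    records.sort(key=lambda t: t[0])
    return StudyDataset(samples=[r for _, r in records], subjects=subjects)


def export_annotations(ds: StudyDataset, path) -> pd.DataFrame:
    """Write the annotation sidecar CSV (one row per sample, study order)."""
    per_subject: dict[str, int] = {}
    rows = []
    for sample in ds.samples:
        idx = per_subject.get(sample.subject_id, 0)
        per_subject[sample.subject_id] = idx + 1
        rows.append(
            {
                "subject_id": sample.subject_id,
                "sample_idx": idx,
                "sss_x": sample.sss_xy[0],
                "sss_y": sample.sss_xy[1],
                "o2satss_gt": sample.o2satss_gt,
                "fio2": sample.fio2,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)


def validate_dataset(ds: StudyDataset, n_channels: int | None = None) -> ValidationReport:
    """Report-only invariant check: bounds, finiteness, channel counts, subjects."""
    report = ValidationReport()
    known = set(ds.subjects)
    for i, s in enumerate(ds.samples):
        tag = f"sample {i} (subject {s.subject_id})"
        if s.subject_id not in known:
            report.add(f"{tag}: subject not listed in dataset subjects")
        px = s.image.pixels
        if not np.all(np.isfinite(px)):
            report.add(f"{tag}: non-finite intensities")
        if np.any(px < 0):
            report.add(f"{tag}: negative intensities")
        if n_channels is not None and s.image.n_channels != n_channels:
            report.add(
                f"{tag}: {s.image.n_channels} channels, expected {n_channels}"
            )
        h, w = s.image.shape_yx
        x, y = s.sss_xy
        if not (0 <= x < w and 0 <= y < h):
            report.add(f"{tag}: sss_xy {s.sss_xy} outside image bounds ({w}x{h})")
        if not (0.0 <= s.o2satss_gt <= 100.0):
            report.add(f"{tag}: o2satss_gt {s.o2satss_gt} outside [0, 100]")
    return report


def content_hash(ds: StudyDataset) -> str:
    """SHA-256 over arrays and metadata, invariant to container byte layout."""
    h = hashlib.sha256()
    h.update(",".join(ds.subjects).encode())
    for s in ds.samples:
        h.update(s.subject_id.encode())
        h.update(np.float64(s.fio2).tobytes())
        h.update(np.float64(s.o2satss_gt).tobytes())
        h.update(np.int64(s.sss_xy[0]).tobytes())
        h.update(np.int64(s.sss_xy[1]).tobytes())
        h.update(np.ascontiguousarray(s.image.pixels, dtype=np.float32).tobytes())
    return h.hexdigest()


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
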