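"""Native bundle format: per-condition FID CSVs with JSON sidecars.

A *session bundle* is a directory with one ``<condition>.csv`` of
``index,real,imag`` rows per scan and a matching ``<condition>.json``
sidecar carrying the acquisition parameters, condition, τ, subject and
session.  A cohort bundle nests ``<subject>/<session>/`` bundles plus a
cohort-level ``ground_truth.csv`` when generated synthetically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from mtmrs.synthetic_data import (
    AcquisitionConfig,
    Cohort,
    Condition,
    FidSeries,
)

__all__ = [
    "write_session_bundle",
    "read_session_bundle",
    "write_cohort_bundle",
    "read_cohort_bundle",
]

_FLOAT_FMT = "%.17g"


def write_session_bundle(fids: list[FidSeries], directory) -> Path:
    """Write one session's FIDs; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fid in fids:
        stem = fid.condition.id
        rows = np.column_stack(
            [np.arange(len(fid.samples)), fid.samples.real, fid.samples.imag]
        )
        np.savetxt(
            directory / f"{stem}.csv",
            rows,
            delimiter=",",
            header="index,real,imag",
            comments="",
            fmt=("%d", _FLOAT_FMT, _FLOAT_FMT),
        )
        sidecar = {
            "condition": asdict(fid.condition),
            "tau": fid.tau,
            "subject_id": fid.subject_id,
            "session_label": fid.session_label,
            "acquisition": asdict(fid.acquisition),
        }
        (directory / f"{stem}.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )
    return directory


def _read_fid_csv(path: Path, n_points: int) -> np.ndarray:
    samples = np.empty(n_points, dtype=complex)
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "index,real,imag":
            raise ValueError(f"{path}: unexpected header {header.strip()!r}")
        count = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split(",")
            try:
                idx = int(parts[0])
                samples[idx] = float(parts[1]) + 1j * float(parts[2])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: corrupted row ({exc})") from exc
            count += 1
    if count != n_points:
        raise ValueError(f"{path}: expected {n_points} samples, found {count}")
    return samples


def read_session_bundle(directory) -> list[FidSeries]:
    directory = Path(directory)
    sidecars = sorted(directory.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no condition sidecars in {directory}")
    fids = []
    for sidecar_path in sidecars:
        meta = json.loads(sidecar_path.read_text())
        acq_dict = dict(meta["acquisition"])
        acq_dict["pulse_counts"] = tuple(acq_dict["pulse_counts"])
        acq = AcquisitionConfig(**acq_dict)
        condition = Condition(**meta["condition"])
        csv_path = sidecar_path.with_suffix(".csv")
        if not csv_path.exists():
            raise FileNotFoundError(f"missing FID data for {sidecar_path.name}")
        samples = _read_fid_csv(csv_path, acq.n_points)
        fids.append(
            FidSeries(
                samples=samples,
                condition=condition,
                tau=meta["tau"],
                acquisition=acq,
                subject_id=meta["subject_id"],
                session_label=meta["session_label"],
            )
        )
    return fids


def write_cohort_bundle(cohort: Cohort, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for subject in cohort.subjects:
        for label, fids in subject.sessions.items():
            write_session_bundle(fids, directory / subject.subject_id / label)
    table = cohort.ground_truth_table()
    table.to_csv(directory / "ground_truth.csv", index=False, float_format=_FLOAT_FMT)
    (directory / "cohort.json").write_text(
        json.dumps({"seed": cohort.seed, "n_subjects": len(cohort.subjects)},
                   indent=1, sort_keys=True)
    )
    return directory


def read_cohort_bundle(directory) -> dict:
    """Read a cohort bundle as {subject_id: {session: [FidSeries]}}."""
    directory = Path(directory)
    out: dict = {}
    for subject_dir in sorted(p for p in directory.iterdir() if p.is_dir()):
        sessions = {}
        for session_dir in sorted(p for p in subject_dir.iterdir() if p.is_dir()):
            sessions[session_dir.name] = read_session_bundle(session_dir)
        if sessions:
            out[subject_dir.name] = sessions
    if not out:
        raise FileNotFoundError(f"no subject bundles in {directory}")
    return out
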