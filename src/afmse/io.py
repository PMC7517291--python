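"""Plain-text persistence: CSV records, JSON ground truth, cohort manifests.

Records are stored as two-column CSV (sample index, mV) with a JSON
metadata sidecar; ground truth goes to a JSON sidecar holding the additive
components and beat annotations; a cohort is a directory of records plus a
``manifest.csv`` (record id, group label, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import BeatSet, EcgRecord, GroundTruth

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_cohort",
    "read_cohort",
    "write_beats_csv",
]


def write_record_csv(record: EcgRecord, path) -> None:
    path = Path(path)
    df = pd.DataFrame({"sample": np.arange(record.n_samples), "mv": record.samples})
    df.to_csv(path, index=False)
    meta = {
        "fs": record.fs,
        "lead_name": record.lead_name,
        "provenance": record.provenance,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_record_csv(path) -> EcgRecord:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return EcgRecord(
        samples=df["mv"].to_numpy(float),
        fs=float(meta["fs"]),
        lead_name=meta.get("lead_name", "V1"),
        provenance=meta.get("provenance", "raw"),
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "atrial": gt.atrial.tolist(),
        "ventricular": gt.ventricular.tolist(),
        "noise": gt.noise.tolist(),
        "beat_indices": gt.beat_indices.tolist(),
        "ectopic_flags": gt.ectopic_flags.tolist(),
        "group_label": gt.group_label,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        atrial=np.asarray(payload["atrial"], float),
        ventricular=np.asarray(payload["ventricular"], float),
        noise=np.asarray(payload["noise"], float),
        beat_indices=np.asarray(payload["beat_indices"], np.int64),
        ectopic_flags=np.asarray(payload["ectopic_flags"], bool),
        group_label=payload.get("group_label", ""),
    )


def write_beats_csv(beats: BeatSet, path) -> None:
    """Beat annotations as CSV: sample index, time in s, label."""
    df = pd.DataFrame(
        {
            "sample": beats.r_peaks,
            "time_s": beats.r_peaks / beats.fs,
            "label": beats.labels,
        }
    )
    df.to_csv(path, index=False)


def write_cohort(
    cohort: Sequence[Tuple[EcgRecord, GroundTruth]],
    directory,
    seeds: Optional[Sequence[int]] = None,
    with_ground_truth: bool = True,
) -> List[str]:
    """Write a cohort to a directory; returns the record ids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    ids = []
    for i, (record, gt) in enumerate(cohort):
        rid = f"rec{i:03d}"
        ids.append(rid)
        write_record_csv(record, directory / f"{rid}.csv")
        if with_ground_truth:
            write_ground_truth(gt, directory / f"{rid}.truth.json")
        rows.append(
            {
                "record_id": rid,
                "group": gt.group_label,
                "seed": seeds[i] if seeds is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return ids


def read_cohort(directory) -> List[Tuple[EcgRecord, GroundTruth]]:
    """Read a cohort directory written by :func:`write_cohort`.

    Records without a ground-truth sidecar get an empty GroundTruth
    carrying only the group label from the manifest.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    out: List[Tuple[EcgRecord, GroundTruth]] = []
    for _, row in manifest.iterrows():
        rid = row["record_id"]
        record = read_record_csv(directory / f"{rid}.csv")
        truth_path = directory / f"{rid}.truth.json"
        if truth_path.exists():
            gt = read_ground_truth(truth_path)
            if not gt.group_label:
                gt.group_label = str(row["group"])
        else:
            zeros = np.zeros(record.n_samples)
            gt = GroundTruth(
                atrial=zeros,
                ventricular=zeros,
                noise=zeros,
                beat_indices=np.array([], np.int64),
                ectopic_flags=np.array([], bool),
                group_label=str(row["group"]),
            )
        out.append((record, gt))
    return out
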