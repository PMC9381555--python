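"""Scan-stream serialization: newline-delimited JSON, one scan per line."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .simulate import Ms2ScanRecord

__all__ = ["scan_to_dict", "scan_from_dict", "write_ndjson", "read_ndjson"]


def scan_to_dict(scan: Ms2ScanRecord) -> dict:
    return {
        "run_id": scan.run_id,
        "scan_index": scan.scan_index,
        "rt_seconds": round(scan.rt_seconds, 6),
        "target_id": scan.target_id,
        "channel": scan.channel,
        "isolation_center_mz": round(scan.isolation_center_mz, 6),
        "isolation_width": scan.isolation_width,
        "compensation_voltage": scan.compensation_voltage,
        "injection_time_ms": round(scan.injection_time_ms, 6),
        "total_ion_count": scan.total_ion_count,
        "mz": [round(float(x), 6) for x in scan.mz],
        "intensity": [round(float(x), 6) for x in scan.intensity],
    }


def scan_from_dict(d: dict) -> Ms2ScanRecord:
    return Ms2ScanRecord(
        run_id=d["run_id"],
        scan_index=int(d["scan_index"]),
        rt_seconds=float(d["rt_seconds"]),
        target_id=d["target_id"],
        channel=d["channel"],
        isolation_center_mz=float(d["isolation_center_mz"]),
        isolation_width=float(d["isolation_width"]),
        compensation_voltage=(
            None if d["compensation_voltage"] is None else float(d["compensation_voltage"])
        ),
        injection_time_ms=float(d["injection_time_ms"]),
        total_ion_count=int(d["total_ion_count"]),
        mz=np.asarray(d["mz"], dtype=float),
        intensity=np.asarray(d["intensity"], dtype=float),
    )


def _opener(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_ndjson(scans: Iterable[Ms2ScanRecord], path) -> None:
    path = Path(path)
    with _opener(path, "w") as fh:
        for scan in scans:
            fh.write(json.dumps(scan_to_dict(scan), separators=(",", ":")))
            fh.write("\n")


def read_ndjson(path) -> list[Ms2ScanRecord]:
    path = Path(path)
    out = []
    with _opener(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(scan_from_dict(json.loads(line)))
    return out
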