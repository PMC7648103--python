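"""File formats: the native scan-JSON dialect, mzML import, tables and sidecars.

The native run format is deliberately a human-diffable JSON document::

    {"scans": [{"time": 0.0, "polarity": "-", "mz": [...], "intensity": [...]}]}

mzML is supported for import only (centroided spectra; profile-mode files are
rejected), via pyteomics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pulses import ScanSpectrum, RepresentativeSpectrum
from .features import FeatureTable

__all__ = [
    "read_run",
    "write_run",
    "read_mzml",
    "write_spectrum",
    "read_spectrum",
    "write_table",
    "read_table",
]


def write_run(run: list[ScanSpectrum], path) -> None:
    """Write a run in the native scan-JSON dialect (lossless round-trip)."""
    doc = {
        "scans": [
            {
                "time": s.scan_time,
                "polarity": s.polarity,
                "mz": s.mz.tolist(),
                "intensity": s.intensity.tolist(),
            }
            for s in run
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_run(path) -> list[ScanSpectrum]:
    """Read a native scan-JSON run file."""
    with open(path) as fh:
        doc = json.load(fh)
    scans = doc.get("scans")
    if not scans:
        raise ValueError(f"{path}: empty or missing scan list")
    return [
        ScanSpectrum(
            scan_time=float(s["time"]),
            polarity=s["polarity"],
            mz=np.asarray(s["mz"], dtype=float),
            intensity=np.asarray(s["intensity"], dtype=float),
        )
        for s in scans
    ]


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one mzML binaryDataArray element (float32/64, zlib or plain)."""
    import base64
    import zlib

    accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    dtype = "<f4" if "MS:1000521" in accs else "<f8"  # 32- vs 64-bit float
    node = bda.find(f"{_NS}binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[ScanSpectrum]:
    """Import centroided spectra from an mzML file.

    Maps scan start time (converted to seconds when given in minutes) and the
    centroid m/z / intensity arrays; profile-mode spectra are rejected with a
    clear message.  Supports plain and zlib-compressed 32/64-bit float
    arrays, which covers centroided exports from the common converters.
    """
    import xml.etree.ElementTree as ET

    run: list[ScanSpectrum] = []
    for _, spec in ET.iterparse(str(path)):
        if spec.tag != f"{_NS}spectrum":
            continue
        accs = {
            cv.get("accession"): cv for cv in spec.iter(f"{_NS}cvParam")
        }
        if "MS:1000128" in accs:
            raise ValueError(
                f"{path}: profile-mode spectra are not supported; centroid first"
            )
        t = 0.0
        time_cv = accs.get("MS:1000016")
        if time_cv is not None:
            t = float(time_cv.get("value"))
            if (time_cv.get("unitName") or "").startswith("minute"):
                t *= 60.0
        polarity = "-" if "MS:1000129" in accs else "+"
        mz = inten = None
        for bda in spec.iter(f"{_NS}binaryDataArray"):
            sub = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
            if "MS:1000514" in sub:
                mz = _decode_binary_array(bda)
            elif "MS:1000515" in sub:
                inten = _decode_binary_array(bda)
        if mz is None or inten is None:
            raise ValueError(f"{path}: spectrum without m/z or intensity array")
        order = np.argsort(mz)
        run.append(ScanSpectrum(t, polarity, mz[order], inten[order]))
        spec.clear()
    if not run:
        raise ValueError(f"{path}: no spectra found")
    return run


def write_spectrum(spec: RepresentativeSpectrum, csv_path, sidecar_path=None, extra: dict | None = None) -> None:
    """Write a representative spectrum as CSV plus an optional JSON sidecar."""
    pd.DataFrame({"mz": spec.mz, "intensity": spec.intensity}).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        doc = {
            "sample_id": spec.sample_id,
            "instrument_threshold": spec.instrument_threshold,
            "pulses_used": [
                {
                    "start_index": p.start_index,
                    "end_index": p.end_index,
                    "apex_index": p.apex_index,
                    "area": p.area,
                    "scan_count": p.scan_count,
                }
                for p in spec.pulses_used
            ],
        }
        if extra:
            doc.update(extra)
        with open(sidecar_path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def read_spectrum(csv_path, sample_id: str = "") -> RepresentativeSpectrum:
    df = pd.read_csv(csv_path)
    return RepresentativeSpectrum(
        sample_id or Path(csv_path).stem,
        df["mz"].to_numpy(),
        df["intensity"].to_numpy(),
    )


def write_table(table: FeatureTable, csv_path, provenance_path=None) -> None:
    """Serialize a feature table: CSV with role/group columns + provenance JSON.

    Feature columns are named by m/z to 4 decimals; values keep full precision.
    """
    out = table.meta[["role", "group"]].copy()
    data = table.data.copy()
    data.columns = [f"{float(c):.4f}" for c in data.columns]
    out = pd.concat([out, data], axis=1)
    out.to_csv(csv_path, index_label="run_id")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump({"applied_filters": table.log}, fh, indent=1, sort_keys=True)


def read_table(csv_path, provenance_path=None) -> FeatureTable:
    df = pd.read_csv(csv_path, index_col="run_id")
    meta = df[["role", "group"]]
    data = df.drop(columns=["role", "group"])
    data.columns = [float(c) for c in data.columns]
    log = []
    if provenance_path is not None:
        with open(provenance_path) as fh:
            log = json.load(fh)["applied_filters"]
    return FeatureTable(data, meta, log)
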