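"""Plain-text readers and writers.

Supported inputs:

* ASCII ECG — a header line ``fs=<Hz>`` followed by one amplitude sample
  per line (the export format of defibrillator-monitor review suites).
* RR tachogram — two whitespace-delimited columns: beat time (s) and the
  terminating NN interval (s); comment lines start with ``#``.
* Vitals table — CSV with columns ``record_id, age, heart_rate, resp_rate,
  sbp, dbp, spo2, temperature, gcs, pain_score, avpu`` (missing cells
  allowed) and optionally an ``outcome`` column of 0/1 labels.

Outputs: HRV feature CSV (one row per record, columns in the canonical
feature order) and QC report JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import EcgRecord, QcReport, RrSeries
from .hrv import HrvFeatures
from .mews import Vitals

VITALS_COLUMNS = ["record_id", "age", "heart_rate", "resp_rate", "sbp", "dbp",
                  "spo2", "temperature", "gcs", "pain_score", "avpu"]


def read_ascii_ecg(path: str | Path, fs: float | None = None,
                   record_id: str | None = None) -> EcgRecord:
    """Read a one-sample-per-line ASCII ECG with an ``fs=<Hz>`` header.

    An explicit ``fs`` argument overrides the header; with neither, 125 Hz
    is assumed.
    """
    path = Path(path)
    samples: list[float] = []
    header_fs = None
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("fs="):
                header_fs = float(line.split("=", 1)[1])
                continue
            samples.append(float(line))
    rate = fs if fs is not None else (header_fs if header_fs is not None else 125.0)
    return EcgRecord(np.asarray(samples), fs=rate,
                     record_id=record_id or path.stem)


def write_ascii_ecg(path: str | Path, ecg: EcgRecord) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"fs={ecg.fs:g}\n")
        for s in ecg.samples:
            fh.write(f"{s:.6f}\n")


def read_tachogram(path: str | Path) -> RrSeries:
    """Read a two-column (time_s, rr_s) whitespace-delimited tachogram."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError("tachogram file needs two columns: time_s rr_s")
    return RrSeries(arr[:, 0], arr[:, 1])


def write_tachogram(path: str | Path, rr: RrSeries) -> None:
    with Path(path).open("w") as fh:
        fh.write("# time_s rr_s\n")
        for t, v in zip(rr.times, rr.intervals):
            fh.write(f"{t:.6f} {v:.6f}\n")


def read_vitals(path: str | Path) -> pd.DataFrame:
    """Read a vitals CSV; unknown columns are preserved."""
    df = pd.read_csv(path)
    if "record_id" not in df.columns:
        df.insert(0, "record_id", [f"rec{i}" for i in range(len(df))])
    return df


def vitals_from_row(row: pd.Series) -> Vitals:
    kwargs = {}
    for name in ("resp_rate", "heart_rate", "sbp", "temperature", "age",
                 "dbp", "spo2", "gcs", "pain_score"):
        if name in row and pd.notna(row[name]):
            kwargs[name] = float(row[name])
    if "avpu" in row and pd.notna(row["avpu"]):
        kwargs["avpu"] = str(row["avpu"])
    return Vitals(**kwargs)


def features_frame(records: dict[str, HrvFeatures]) -> pd.DataFrame:
    """One row per record, HRV columns in the canonical order."""
    rows = [{"record_id": rid, **feats.as_dict()} for rid, feats in records.items()]
    return pd.DataFrame(rows, columns=["record_id"] + HrvFeatures.feature_names())


def write_qc_report(path: str | Path, reports: dict[str, QcReport]) -> None:
    payload = {
        rid: {"fraction_bad": qc.fraction_bad, "eligible": qc.eligible,
              "trimmed_spans": [list(s) for s in qc.trimmed_spans]}
        for rid, qc in reports.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
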