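"""Reading and writing wingbeat records, manifests and feature archives.

Records are stored one per file as mono 8 kHz WAV (float32 by default, or
16-bit PCM) or as single-column numeric CSV. A manifest CSV
(``record_id,path,species,population,timestamp,true_f0``) indexes a
dataset; feature matrices travel as compressed ``.npz`` archives and
validity verdicts as a per-record CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import ValidityReport
from .sensor_sim import WingbeatRecord

MANIFEST_COLUMNS = ["record_id", "path", "species", "population",
                    "timestamp", "true_f0"]


class FormatError(ValueError):
    """A record file violates the expected container format."""


def read_record(path: str | Path, expected_fs: int = 8000) -> WingbeatRecord:
    """Load one record from WAV (mono, 8 kHz) or single-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        if data.ndim != 1:
            raise FormatError(f"{path}: expected mono, got {data.shape[1]} channels")
        if fs != expected_fs:
            raise FormatError(f"{path}: expected sample rate {expected_fs} Hz, got {fs}")
        if data.dtype == np.int16:
            samples = data.astype(np.float64) / 32767.0
        elif data.dtype in (np.float32, np.float64):
            samples = data.astype(np.float64)
        else:
            raise FormatError(f"{path}: expected 16-bit PCM or float WAV, got {data.dtype}")
        return WingbeatRecord(samples=samples, fs=fs, record_id=path.stem)
    if path.suffix.lower() == ".csv":
        values = pd.read_csv(path, header=None).to_numpy()
        if values.ndim != 2 or values.shape[1] != 1:
            raise FormatError(f"{path}: expected a single numeric column")
        return WingbeatRecord(samples=values[:, 0].astype(np.float64),
                              fs=expected_fs, record_id=path.stem)
    raise FormatError(f"{path}: unsupported record format {path.suffix!r}")


def write_record(record: WingbeatRecord, path: str | Path,
                 pcm16: bool = False) -> None:
    """Write one record; float32 WAV by default (no quantization), or PCM16/CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".wav":
        if pcm16:
            clipped = np.clip(record.samples, -1.0, 1.0)
            wavfile.write(path, record.fs,
                          np.round(clipped * 32767.0).astype(np.int16))
        else:
            wavfile.write(path, record.fs, record.samples.astype(np.float32))
        return
    if path.suffix.lower() == ".csv":
        pd.DataFrame(record.samples).to_csv(path, header=False, index=False)
        return
    raise FormatError(f"{path}: unsupported record format {path.suffix!r}")


def write_dataset(records: list[WingbeatRecord], manifest: pd.DataFrame,
                  out_dir: str | Path, pcm16: bool = False) -> pd.DataFrame:
    """Write every record as WAV and the manifest CSV; returns the manifest
    with its ``path`` column filled in (paths relative to ``out_dir``)."""
    out_dir = Path(out_dir)
    (out_dir / "records").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for rec in records:
        rel = f"records/{rec.record_id}.wav"
        write_record(rec, out_dir / rel, pcm16=pcm16)
        paths.append(rel)
    manifest["path"] = paths
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"record_id": str, "species": str,
                                        "population": str})
    missing = set(MANIFEST_COLUMNS) - {"true_f0"} - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if manifest["record_id"].duplicated().any():
        raise FormatError("manifest contains duplicate record ids")
    return manifest


def load_records(manifest: pd.DataFrame, root: str | Path,
                 expected_fs: int = 8000) -> list[WingbeatRecord]:
    """Load every manifest row's record file, restoring its metadata."""
    root = Path(root)
    records = []
    for row in manifest.itertuples():
        rec = read_record(root / row.path, expected_fs=expected_fs)
        rec.record_id = row.record_id
        rec.species = row.species
        rec.population = row.population
        rec.timestamp = str(row.timestamp)
        f0 = getattr(row, "true_f0", None)
        rec.true_f0 = None if f0 is None or pd.isna(f0) else float(f0)
        records.append(rec)
    return records


def save_features(features: dict[str, np.ndarray], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **features)


def load_features(path: str | Path) -> dict[str, np.ndarray]:
    data = np.load(path)
    return {k: data[k] for k in data.files}


def write_validity_csv(reports: list[ValidityReport], path: str | Path) -> None:
    frame = pd.DataFrame({
        "record_id": [r.record_id for r in reports],
        "psd_score": [r.psd_score for r in reports],
        "n_peaks": [r.n_peaks for r in reports],
        "valid": [r.valid for r in reports],
        "reasons": ["; ".join(r.reasons) for r in reports],
    })
    frame.to_csv(path, index=False)


def read_validity_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"record_id": str})
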