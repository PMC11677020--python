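"""File I/O: HDF5 spectra, TIFF enface images, CSV metadata, JSON truth."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import EnfaceImage, GroundTruth, SpectrumRecord

METADATA_COLUMNS = ["record_id", "subject_id", "sample_id", "modality", "label", "path"]


def save_spectra_h5(path, records: list[SpectrumRecord]) -> None:
    """Spectra as one (n_records, n_channels) matrix plus the shared axis."""
    path = Path(path)
    x = records[0].wavenumbers
    with h5py.File(path, "w") as f:
        f.create_dataset("wavenumbers", data=x)
        f.create_dataset("intensities", data=np.stack([r.intensities for r in records]))
        ids = np.array([r.record_id for r in records], dtype=h5py.string_dtype())
        f.create_dataset("record_id", data=ids)


def load_spectra_h5(path, metadata: pd.DataFrame) -> list[SpectrumRecord]:
    with h5py.File(path, "r") as f:
        x = f["wavenumbers"][()]
        Y = f["intensities"][()]
        ids = [s.decode() if isinstance(s, bytes) else s for s in f["record_id"][()]]
    meta = metadata.set_index("record_id")
    records = []
    for rid, row in zip(ids, Y):
        m = meta.loc[rid]
        records.append(
            SpectrumRecord(x, row, m["subject_id"], m["sample_id"], rid, m["label"])
        )
    return records


def save_spectrum_csv(path, record: SpectrumRecord) -> None:
    """One record as a two-column (wavenumber, intensity) CSV."""
    pd.DataFrame(
        {"wavenumber_cm1": record.wavenumbers, "intensity": record.intensities}
    ).to_csv(path, index=False)


def load_spectrum_csv(path, subject_id="", sample_id="", record_id="", label="healthy"):
    df = pd.read_csv(path)
    return SpectrumRecord(
        df["wavenumber_cm1"].to_numpy(),
        df["intensity"].to_numpy(),
        subject_id,
        sample_id,
        record_id or Path(path).stem,
        label,
    )


def save_images(directory, images: list[EnfaceImage]) -> dict[str, str]:
    """Write each image as 16-bit grayscale TIFF; returns record_id -> filename."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for im in images:
        fname = f"{im.record_id}.tiff"
        data = np.clip(im.pixels, 0.0, 1.0)
        tifffile.imwrite(directory / fname, (data * 65535).astype(np.uint16))
        paths[im.record_id] = fname
    return paths


def load_images(directory, metadata: pd.DataFrame) -> list[EnfaceImage]:
    directory = Path(directory)
    images = []
    for _, m in metadata[metadata["modality"] == "OCT"].iterrows():
        pix = tifffile.imread(directory / m["path"]).astype(float) / 65535.0
        side = pix.shape[0]
        images.append(
            EnfaceImage(
                pix,
                m["subject_id"],
                m["sample_id"],
                m["record_id"],
                m["label"],
                pixel_size_um=4.0,
                field_of_view_mm=side * 4.0 / 1000.0,
            )
        )
    return images


def build_metadata(
    spectra: list[SpectrumRecord],
    images: list[EnfaceImage],
    image_paths: dict[str, str] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in spectra:
        rows.append([r.record_id, r.subject_id, r.sample_id, "RS", r.label, ""])
    for im in images:
        p = (image_paths or {}).get(im.record_id, "")
        rows.append([im.record_id, im.subject_id, im.sample_id, "OCT", im.label, p])
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def save_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "sample_purity": truth.sample_purity,
        "record_latent": truth.record_latent,
        "fiber_orientation_deg": truth.fiber_orientation_deg,
        "spike_channels": truth.spike_channels,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def save_band_selection(path, selection) -> None:
    pd.DataFrame(selection.regions, columns=["start_cm1", "end_cm1"]).to_csv(
        path, index=False
    )


def save_features_csv(path, record_ids, matrix, names) -> None:
    df = pd.DataFrame(matrix, columns=names)
    df.insert(0, "record_id", record_ids)
    df.to_csv(path, index=False)
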