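"""File formats: calibrated TIFF images, ground-truth JSON sidecars
(run-length-encoded masks) and columnar sweep files with JSON protocol
descriptors."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (
    CalibratedImage,
    SweepSet,
    SyntheticCellTruth,
    TruthFilopodium,
    VoltageProtocol,
)

# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(img: CalibratedImage, path) -> None:
    """Single-channel TIFF with pixel-size/channel metadata in the
    image-description tag (JSON)."""
    meta = {"pixel_size_um": img.pixel_size_um, "channel": img.channel,
            "modality": img.modality}
    tifffile.imwrite(str(path), img.pixels, description=json.dumps(meta),
                     photometric="minisblack")


def read_image(path, pixel_size_um: float | None = None,
               channel: str | None = None,
               modality: str | None = None) -> CalibratedImage:
    """Load a single-channel TIFF written by :func:`write_image` or any
    grayscale TIFF plus an explicit ``pixel_size_um`` override.

    Raises on multi-channel data (no channel selector is supported) and on
    missing pixel-size metadata without an override.  An explicit override
    always wins over metadata.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if arr.ndim != 2:
        raise ValueError("multi-channel TIFF without a channel selector")
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError("no pixel size in metadata and no override given")
    return CalibratedImage(
        np.asarray(arr, dtype=float), float(px),
        channel=channel or meta.get("channel", "protein"),
        modality=modality or meta.get("modality", "TIRF"),
    )


# ---------------------------------------------------------------------------
# ground truth (JSON sidecar, RLE masks)
# ---------------------------------------------------------------------------


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encoding of a binary mask ([start, length] runs over the
    flattened array)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [flat.size]])
    runs = [[int(s), int(e - s)] for s, e, v in zip(starts, ends, flat[starts]) if v]
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(data: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(data["shape"])), dtype=bool)
    for start, length in data["runs"]:
        flat[start:start + length] = True
    return flat.reshape(data["shape"])


def write_truth(truth: SyntheticCellTruth, path) -> None:
    payload = {
        "pixel_size_um": truth.pixel_size_um,
        "enrichment_rho": truth.enrichment_rho,
        "footprint_mask": rle_encode(truth.footprint_mask),
        "process_masks": [rle_encode(m) for m in truth.process_masks],
        "soma_mask": rle_encode(truth.soma_mask) if truth.soma_mask is not None else None,
        "dendrite_paths_px": [np.asarray(p).tolist() for p in truth.dendrite_paths_px],
        "axon_paths_px": [np.asarray(p).tolist() for p in truth.axon_paths_px],
        "filopodia": [
            {
                "attachment_px": list(f.attachment_px),
                "attachment_centerline_px": list(f.attachment_centerline_px),
                "length_um": f.length_um,
                "path_px": np.asarray(f.path_px).tolist(),
            }
            for f in truth.filopodia
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> SyntheticCellTruth:
    data = json.loads(Path(path).read_text())
    return SyntheticCellTruth(
        footprint_mask=rle_decode(data["footprint_mask"]),
        process_masks=[rle_decode(m) for m in data["process_masks"]],
        filopodia=[
            TruthFilopodium(
                attachment_px=tuple(f["attachment_px"]),
                attachment_centerline_px=tuple(f["attachment_centerline_px"]),
                length_um=f["length_um"],
                path_px=np.asarray(f["path_px"], dtype=float),
            )
            for f in data["filopodia"]
        ],
        enrichment_rho=data.get("enrichment_rho"),
        soma_mask=rle_decode(data["soma_mask"]) if data.get("soma_mask") else None,
        dendrite_paths_px=[np.asarray(p, dtype=float) for p in data["dendrite_paths_px"]],
        axon_paths_px=[np.asarray(p, dtype=float) for p in data["axon_paths_px"]],
        pixel_size_um=data["pixel_size_um"],
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _vtag(v: float) -> str:
    return f"{'m' if v < 0 else 'p'}{abs(v):g}"


def write_sweeps(sweeps: SweepSet, traces_path, protocol_path) -> None:
    """One columnar CSV (time + one pA column per trace) plus a JSON
    protocol descriptor carrying everything needed to reload the set."""
    cols = {"time_ms": sweeps.time_ms}
    for v in sweeps.protocol.test_voltages_mV:
        cols[f"test_{_vtag(v)}"] = sweeps.test[v]
        for k in range(sweeps.subs[v].shape[0]):
            cols[f"sub_{_vtag(v)}_{k}"] = sweeps.subs[v][k]
    pd.DataFrame(cols).to_csv(traces_path, index=False)
    proto = sweeps.protocol
    payload = {
        "holding_mV": proto.holding_mV,
        "test_voltages_mV": list(proto.test_voltages_mV),
        "pulse_ms": proto.pulse_ms,
        "sampling_khz": proto.sampling_khz,
        "pre_ms": proto.pre_ms,
        "post_ms": proto.post_ms,
        "p4_fraction": proto.p4_fraction,
        "p4_count": proto.p4_count,
        "p4_polarity": proto.p4_polarity,
        "sub_amplitude_mV": {_vtag(v): a for v, a in sweeps.sub_amplitude_mV.items()},
        "metadata": sweeps.metadata,
    }
    Path(protocol_path).write_text(json.dumps(payload, indent=2))


def read_sweeps(traces_path, protocol_path) -> SweepSet:
    """Inverse of :func:`write_sweeps`; raises when a trace column named in
    the protocol is missing."""
    data = json.loads(Path(protocol_path).read_text())
    proto = VoltageProtocol(
        holding_mV=data["holding_mV"],
        test_voltages_mV=data["test_voltages_mV"],
        pulse_ms=data["pulse_ms"],
        sampling_khz=data["sampling_khz"],
        pre_ms=data["pre_ms"],
        post_ms=data["post_ms"],
        p4_fraction=data["p4_fraction"],
        p4_count=data["p4_count"],
        p4_polarity=data["p4_polarity"],
    )
    df = pd.read_csv(traces_path)
    test, subs, sub_amp = {}, {}, {}
    for v in proto.test_voltages_mV:
        tag = _vtag(v)
        col = f"test_{tag}"
        if col not in df.columns:
            raise ValueError(f"missing trace column '{col}'")
        test[v] = df[col].to_numpy()
        sub_cols = []
        for k in range(proto.p4_count):
            scol = f"sub_{tag}_{k}"
            if scol not in df.columns:
                raise ValueError(f"missing trace column '{scol}'")
            sub_cols.append(df[scol].to_numpy())
        subs[v] = np.stack(sub_cols)
        sub_amp[v] = data["sub_amplitude_mV"][tag]
    return SweepSet(time_ms=df["time_ms"].to_numpy(), protocol=proto, test=test,
                    subs=subs, sub_amplitude_mV=sub_amp,
                    metadata=data.get("metadata", {}))
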