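"""One auditable configuration object for the whole pipeline.

Defaults equal the method constants used throughout: 5x5 um normalization
ROI, 3x3 um SNR ROIs (10 of each), 10 radial selections of 10 um, 20 um
dendrite selections, length bins at 4 and 8 um, 2 um high-pass sigma,
15 MOhm access-resistance ceiling and 295 K for the gating-charge
conversion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.1
    diff_roi_side_um: float = 5.0
    snr_roi_side_um: float = 3.0
    n_rois: int = 10
    n_segments: int = 10
    segment_length_um: float = 10.0
    selection_length_um: float = 20.0
    bin_edges_um: tuple[float, float] = (4.0, 8.0)
    highpass_sigma_um: float = 2.0
    width_max_um: float = 1.0
    min_length_um: float = 0.5
    ra_max_MOhm: float = 15.0
    temperature_K: float = 295.0
    e_rev_mV: float | None = 65.0
    seed: int = 0
    # synthetic-mode run sizes (kept small so `b2mq run` is quick)
    n_tirf_cells: int = 2
    n_neurons: int = 2
    n_vc_cells: int = 3
    enrichment_rho: float = 1.34
    filopodia_density_high: float = 7.6
    filopodia_density_low: float = 1.89

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "diff_roi_side_um", "snr_roi_side_um",
                     "segment_length_um", "selection_length_um",
                     "highpass_sigma_um", "width_max_um", "ra_max_MOhm",
                     "temperature_K"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        self.bin_edges_um = tuple(self.bin_edges_um)  # type: ignore[assignment]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
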