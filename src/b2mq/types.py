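"""Core containers shared across the analysis stages.

All physical quantities carry explicit units in their field names:
micrometres (``_um``), millivolts (``_mV``), picoamperes (``pA``),
megaohms (``_MOhm``), gigaohms (``_GOhm``), picofarads (``_pF``),
nanosiemens (``_nS``) and milliseconds (``_ms``).  Fluorescence is in
arbitrary units (AU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: channels a CalibratedImage may carry
CHANNELS = ("protein", "membrane_reference", "morphology", "difference")
MODALITIES = ("TIRF", "epifluorescence")


@dataclass
class CalibratedImage:
    """A single-channel fluorescence image with a physical pixel scale.

    Input channels (protein / membrane_reference / morphology) must be
    finite and non-negative; ``difference`` images (output of the
    intensity-difference analysis) may legitimately contain negative
    values and are exempt from the non-negativity check.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "protein"
    modality: str = "TIRF"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D single-channel image, got ndim={self.pixels.ndim}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.channel != "difference" and np.any(self.pixels < 0):
            raise ValueError("input image contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size_um, self.shape[1] * self.pixel_size_um)


@dataclass
class RoiSquare:
    """A square region of interest given by its centre (row, col) in pixels
    and its physical side length."""

    center: tuple[float, float]
    side_um: float

    def __post_init__(self) -> None:
        if not self.side_um > 0:
            raise ValueError("side_um must be > 0")

    def slices(self, img: CalibratedImage) -> tuple[slice, slice]:
        """Pixel slices of the ROI; raises if the ROI leaves the image."""
        half = self.side_um / (2.0 * img.pixel_size_um)
        r0 = int(round(self.center[0] - half))
        r1 = int(round(self.center[0] + half))
        c0 = int(round(self.center[1] - half))
        c1 = int(round(self.center[1] + half))
        r1, c1 = max(r1, r0 + 1), max(c1, c0 + 1)
        if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
            raise ValueError("ROI extends beyond the image bounds")
        return slice(r0, r1), slice(c0, c1)


@dataclass
class IntensityProfile:
    """Fluorescence sampled along a 10 um segment crossing the cell edge.

    ``positions_um`` start at 0 at the *interior* end of the segment.
    ``edge_index`` is the last sample on the cell side of the detected
    edge crossing.  The border window holds the 5 samples strictly inside
    the cell that end at the edge; the centre window holds the first 5
    samples at the interior end.
    """

    positions_um: np.ndarray
    values: np.ndarray
    edge_index: int
    border_window: np.ndarray  # integer sample indices, length 5
    center_window: np.ndarray  # integer sample indices, length 5

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.border_window = np.asarray(self.border_window, dtype=int)
        self.center_window = np.asarray(self.center_window, dtype=int)
        if self.positions_um.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")
        if np.intersect1d(self.border_window, self.center_window).size:
            raise ValueError("border and center windows must be disjoint")


@dataclass
class ExpressionSnr:
    """(S - N)/N membrane-expression index in arbitrary units."""

    S: float
    N: float
    R: float

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError("background level N must be > 0")


# --------------------------------------------------------------------------
# morphometry
# --------------------------------------------------------------------------


@dataclass
class Filopodium:
    """A thin membrane process extracted from a segmented image.

    ``attachment_px`` is where the process meets its parent structure
    (at the parent's edge); ``attachment_on_parent_px`` is the nearest
    point on the parent centreline (skeleton), which is what selection
    counting uses.
    """

    path_px: np.ndarray  # (n, 2) ordered (row, col) polyline
    length_um: float
    attachment_px: tuple[float, float]
    attachment_on_parent_px: tuple[float, float]
    mean_width_um: float


@dataclass
class LengthHistogram:
    """Process lengths binned into <4 um, [4, 8) um and >=8 um groups."""

    bin_edges_um: tuple[float, float]
    counts: np.ndarray
    percentages: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.percentages = np.asarray(self.percentages, dtype=float)
        total = int(self.counts.sum())
        if total and abs(self.percentages.sum() - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")


@dataclass
class BranchingIndex:
    """Percentage of the (soma-excluded) field occupied by branches."""

    value_percent: float
    branch_area_px: int
    total_area_px: int
    soma_excluded: bool
    threshold_used: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value_percent <= 100.0):
            raise ValueError("value_percent must be in [0, 100]")


# --------------------------------------------------------------------------
# electrophysiology
# --------------------------------------------------------------------------


@dataclass
class VoltageProtocol:
    """Step protocol for steady-state activation with P/4 leak subtraction.

    Test pulses of ``pulse_ms`` duration step from ``holding_mV`` to each
    voltage in ``test_voltages_mV`` (ascending).  Each test pulse is
    accompanied by ``p4_count`` subpulses of ``p4_fraction`` of the test
    amplitude; ``p4_polarity`` -1 means the subpulses are inverted
    (hyperpolarizing from holding), which avoids channel activation.
    """

    holding_mV: float = -90.0
    test_voltages_mV: Sequence[float] = field(
        default_factory=lambda: tuple(float(v) for v in range(-80, 45, 5))
    )
    pulse_ms: float = 60.0
    sampling_khz: float = 100.0
    pre_ms: float = 2.0
    post_ms: float = 2.0
    p4_fraction: float = 0.25
    p4_count: int = 4
    p4_polarity: int = -1

    def __post_init__(self) -> None:
        v = np.asarray(self.test_voltages_mV, dtype=float)
        if v.size < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("test voltages must be strictly ascending")
        if not self.pulse_ms > 0:
            raise ValueError("pulse_ms must be > 0")
        if self.p4_polarity not in (-1, 1):
            raise ValueError("p4_polarity must be -1 or +1")
        self.test_voltages_mV = tuple(float(x) for x in v)

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_khz

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_ms + self.pulse_ms + self.post_ms) * self.sampling_khz))

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms


@dataclass
class SweepSet:
    """Voltage-clamp sweeps: one test trace plus P/4 subpulse traces per
    test voltage.  Currents are in pA, inward negative."""

    time_ms: np.ndarray
    protocol: VoltageProtocol
    test: dict  # voltage (mV) -> (n,) current trace
    subs: dict  # voltage (mV) -> (p4_count, n) subpulse traces
    sub_amplitude_mV: dict  # voltage (mV) -> actual subpulse step amplitude
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        for v, tr in self.test.items():
            if len(tr) != n:
                raise ValueError(f"trace at {v} mV does not share the time base")
            if not np.all(np.isfinite(tr)):
                raise ValueError(f"non-finite current at {v} mV")

    @property
    def pulse_window_ms(self) -> tuple[float, float]:
        return (self.protocol.pre_ms, self.protocol.pre_ms + self.protocol.pulse_ms)


@dataclass
class PassiveParams:
    """Passive membrane parameters from the P/4 RC transient."""

    Ra_MOhm: float
    Rm_GOhm: float
    Cm_pF: float
    tau_ms: float
    fit_residual_rms: float

    def __post_init__(self) -> None:
        for name in ("Ra_MOhm", "Rm_GOhm", "Cm_pF", "tau_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ConductanceCurve:
    """Per-voltage peak conductance after access-resistance correction.

    ``g_norm`` is G_M/G_0: conductance normalized to its value at the
    highest retained depolarizing voltage (the normalization anchor).
    """

    vcmd_mV: np.ndarray
    i_peak_pA: np.ndarray
    vm_mV: np.ndarray
    g_nS: np.ndarray
    g_norm: np.ndarray
    retained: np.ndarray  # bool, points used for fitting
    e_rev_mV: float
    anchor_index: int


@dataclass
class ActivationFit:
    """Boltzmann steady-state activation parameters.

    G_M/G_0 = 1 / (1 + exp((V_half - Vm)/s)); the gating charge is the
    equivalent q_g = (k_B T / e) / s at ``temperature_K``.
    """

    v_half_mV: float
    slope_mV: float
    q_gating: float
    gmax_nS: float
    se_v_half_mV: float
    se_slope_mV: float
    temperature_K: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not self.slope_mV > 0:
            raise ValueError("slope must be > 0 for a converged fit")


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass
class Comparison:
    group_a: GroupSummary
    group_b: GroupSummary
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    fold_change: float
    fold_rounded: int
    variant: str = "student"


# --------------------------------------------------------------------------
# synthetic-data ground truth
# --------------------------------------------------------------------------


@dataclass
class TruthFilopodium:
    """Generator-side record of one protrusion."""

    attachment_px: tuple[float, float]  # at the parent's edge
    attachment_centerline_px: tuple[float, float]  # on the parent centreline
    length_um: float
    path_px: np.ndarray  # (n, 2) polyline from parent edge to tip


@dataclass
class SyntheticCellTruth:
    """Ground truth emitted alongside every synthetic image."""

    footprint_mask: np.ndarray
    process_masks: list
    filopodia: list  # list[TruthFilopodium]
    enrichment_rho: float | None = None
    soma_mask: np.ndarray | None = None
    dendrite_paths_px: list = field(default_factory=list)  # list of (n,2) polylines
    axon_paths_px: list = field(default_factory=list)
    pixel_size_um: float = 0.1
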