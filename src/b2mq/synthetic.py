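"""Seeded synthetic data generators with full ground truth.

Three generators emulate the raw data the analysis stages consume:

* :func:`generate_tirf_pair` — paired TIRF images of an adherent cell in a
  protein channel (border-enriched expression) and a membrane-reference
  channel (uniform expression, e.g. a lipophilic dye).  Both channels share
  the same membrane-proximity/adhesion field, so the reference channel can
  be used to discount adhesion and evanescent-excitation artifacts.
* :func:`generate_neuron_image` — a neuron with a soma, branching dendrites
  carrying filopodia-like protrusions, and a sparsely branched axon that by
  construction carries none (protrusion growth is dendrite-specific).
* :func:`simulate_vc` — whole-cell voltage-clamp sweep sets from a passive
  RC cell (series resistance Ra, membrane capacitance Cm and resistance Rm)
  plus a Boltzmann-activated sodium conductance, including P/4 subpulses.

Every generator is deterministic given its spec and seed: independent seed
streams are spawned per generated object from ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .types import (
    CalibratedImage,
    SweepSet,
    SyntheticCellTruth,
    TruthFilopodium,
    VoltageProtocol,
)

# ---------------------------------------------------------------------------
# TIRF cell pair
# ---------------------------------------------------------------------------


@dataclass
class LobeSpec:
    """A lamellipodium-like lobe: a broad bump on the cell boundary."""

    angle_deg: float
    extent_um: float
    width_deg: float = 40.0


@dataclass
class FiloSpec:
    """A filopodium-like process attached to the cell body boundary."""

    angle_deg: float
    length_um: float
    width_um: float = 0.4


@dataclass
class TirfCellSpec:
    """Geometry and imaging model of one synthetic adherent cell.

    The footprint is an ellipse with optional lamellipodial lobes and
    filopodia.  Expression in the protein channel is 1 inside the
    footprint and ``enrichment_rho`` within ``ring_width_um`` of the edge
    and inside processes; the reference channel has uniform expression.
    The shared adhesion factor is 1 on the body and ``adhesion_gain``
    inside processes.  Additive Gaussian noise has SD ``noise_sigma``
    relative to the mean in-cell signal.
    """

    image_size_um: float = 51.2
    pixel_size_um: float = 0.1
    body_center_um: tuple[float, float] = (25.6, 25.6)
    body_semi_axes_um: tuple[float, float] = (16.0, 13.0)
    lamellipodia: Sequence[LobeSpec] = field(
        default_factory=lambda: (LobeSpec(30.0, 3.0), LobeSpec(200.0, 2.5))
    )
    filopodia: Sequence[FiloSpec] = field(
        default_factory=lambda: tuple(
            FiloSpec(a, l) for a, l in ((100.0, 5.0), (140.0, 3.0), (300.0, 6.0))
        )
    )
    enrichment_rho: float = 1.34
    ring_width_um: float = 1.0
    adhesion_gain: float = 1.5
    noise_sigma: float = 0.10
    base_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.enrichment_rho > 0:
            raise ValueError("enrichment_rho must be > 0")
        if self.ring_width_um < 0 or self.noise_sigma < 0:
            raise ValueError("lengths and noise must be >= 0")
        if self.adhesion_gain < 1:
            raise ValueError("adhesion_gain must be >= 1 in processes")


def _polar_grid(shape: tuple[int, int], center_px: tuple[float, float]):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center_px[0]
    dx = cc - center_px[1]
    return np.hypot(dy, dx), np.arctan2(dy, dx)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _ellipse_radius(a_um: float, b_um: float, theta: np.ndarray) -> np.ndarray:
    return a_um * b_um / np.hypot(b_um * np.cos(theta), a_um * np.sin(theta))


def _thick_line_mask(shape, p0, p1, width_px: float) -> np.ndarray:
    """Rasterize a segment (row,col endpoints in px) with the given width."""
    canvas = np.zeros(shape, dtype=bool)
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    rr, cc = draw_line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    canvas[rr[keep], cc[keep]] = True
    radius = max(1, int(round(width_px / 2.0)))
    return ndimage.binary_dilation(canvas, structure=disk(radius))


def generate_tirf_pair(spec: TirfCellSpec):
    """Return ``(beta_image, fm_image, truth)`` for one synthetic cell.

    Raises ``ValueError`` if any geometry element exceeds the image bounds.
    """
    n = int(round(spec.image_size_um / spec.pixel_size_um))
    shape = (n, n)
    px = spec.pixel_size_um
    center_px = (spec.body_center_um[0] / px, spec.body_center_um[1] / px)
    r_um, theta = _polar_grid(shape, center_px)
    r_um = r_um * px

    a, b = spec.body_semi_axes_um
    r_body = _ellipse_radius(a, b, theta)

    bump = np.zeros(shape)
    lam_masks = []
    for lobe in spec.lamellipodia:
        th0 = math.radians(lobe.angle_deg)
        sig = math.radians(lobe.width_deg) / 2.355  # FWHM -> sigma
        this = lobe.extent_um * np.exp(-0.5 * (_wrap_angle(theta - th0) / sig) ** 2)
        bump = np.maximum(bump, this)
        lam_masks.append((r_um <= r_body + this) & (r_um > r_body) & (this > 0.1))

    body_mask = r_um <= r_body
    footprint = r_um <= r_body + bump

    filo_masks = []
    truth_filos = []
    cy, cx = spec.body_center_um
    for filo in spec.filopodia:
        th = math.radians(filo.angle_deg)
        rb = float(_ellipse_radius(a, b, np.asarray(th)))
        base_um = (cy + rb * math.sin(th), cx + rb * math.cos(th))
        tip_um = (base_um[0] + filo.length_um * math.sin(th), base_um[1] + filo.length_um * math.cos(th))
        margin = filo.width_um / 2 + px
        for coord in tip_um:
            if coord < margin or coord > spec.image_size_um - margin:
                raise ValueError("filopodium geometry exceeds the image bounds")
        # anchor slightly inside the body so the process connects to it
        inset = (base_um[0] - 0.5 * math.sin(th), base_um[1] - 0.5 * math.cos(th))
        m = _thick_line_mask(
            shape,
            (inset[0] / px, inset[1] / px),
            (tip_um[0] / px, tip_um[1] / px),
            filo.width_um / px,
        )
        filo_masks.append(m & ~body_mask)
        path = np.array([[base_um[0] / px, base_um[1] / px], [tip_um[0] / px, tip_um[1] / px]])
        truth_filos.append(
            TruthFilopodium(
                attachment_px=(base_um[0] / px, base_um[1] / px),
                attachment_centerline_px=(base_um[0] / px, base_um[1] / px),
                length_um=filo.length_um,
                path_px=path,
            )
        )
        footprint = footprint | m

    if footprint[0, :].any() or footprint[-1, :].any() or footprint[:, 0].any() or footprint[:, -1].any():
        raise ValueError("cell geometry exceeds the image bounds")

    process_mask = np.zeros(shape, dtype=bool)
    for m in lam_masks + filo_masks:
        process_mask |= m

    adhesion = np.where(footprint, 1.0, 0.0)
    adhesion[process_mask] = spec.adhesion_gain

    ring = np.zeros(shape, dtype=bool)
    dist_in = ndimage.distance_transform_edt(footprint) * px
    ring[(dist_in > 0) & (dist_in <= spec.ring_width_um)] = True

    expression = np.where(footprint, 1.0, 0.0)
    expression[ring | process_mask] = spec.enrichment_rho

    beta = adhesion * expression * spec.base_level
    fm = adhesion * spec.base_level

    ss = np.random.SeedSequence(spec.seed)
    rng_beta, rng_fm = (np.random.default_rng(s) for s in ss.spawn(2))
    if spec.noise_sigma > 0:
        beta = beta + rng_beta.normal(0.0, spec.noise_sigma * beta[footprint].mean(), shape)
        fm = fm + rng_fm.normal(0.0, spec.noise_sigma * fm[footprint].mean(), shape)
        np.clip(beta, 0.0, None, out=beta)
        np.clip(fm, 0.0, None, out=fm)

    truth = SyntheticCellTruth(
        footprint_mask=footprint,
        process_masks=lam_masks + filo_masks,
        filopodia=truth_filos,
        enrichment_rho=spec.enrichment_rho,
        pixel_size_um=px,
    )
    beta_img = CalibratedImage(beta, px, channel="protein", modality="TIRF")
    fm_img = CalibratedImage(fm, px, channel="membrane_reference", modality="TIRF")
    return beta_img, fm_img, truth


# ---------------------------------------------------------------------------
# neuron arbor
# ---------------------------------------------------------------------------


@dataclass
class NeuronSpec:
    """Synthetic neuron: soma, branching dendrites with filopodia-like
    protrusions, and a sparsely branched axon without protrusions.

    ``filopodia_density`` is protrusions per 20 um of dendrite; lengths are
    drawn from a three-component mixture over the <4, 4-8 and >8 um ranges
    with weights ``length_mixture``.
    """

    image_size_um: float = 64.0
    pixel_size_um: float = 0.1
    soma_radius_um: float = 6.0
    n_dendrites: int = 5
    dendrite_length_um: tuple[float, float] = (22.0, 38.0)  # uniform range
    branch_prob_per_um: float = 0.02
    dendrite_width_um: float = 1.2
    filopodia_density: float = 7.6  # per 20 um of dendrite
    min_gap_um: float = 1.0  # hard-core spacing: protrusions are discrete structures
    filopodium_width_um: float = 0.4
    length_mixture: tuple[float, float, float] = (0.6, 0.3, 0.1)
    axon_length_um: float = 45.0
    axon_branches: int = 2
    noise_sigma: float = 0.05
    base_level: float = 100.0
    soma_level: float = 130.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filopodia_density < 0 or self.branch_prob_per_um < 0:
            raise ValueError("densities must be >= 0")
        if abs(sum(self.length_mixture) - 1.0) > 1e-9:
            raise ValueError("length mixture weights must sum to 1")


#: length ranges (um) of the three mixture components; kept clear of the
#: 4 um and 8 um bin boundaries so generated bin membership is unambiguous
_MIX_RANGES = ((1.0, 3.8), (4.2, 7.8), (8.2, 11.5))


def sample_filopodia_lengths(weights, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` protrusion lengths (um) from the three-bin mixture."""
    comp = rng.choice(3, size=n, p=np.asarray(weights, dtype=float))
    lo = np.array([_MIX_RANGES[c][0] for c in comp])
    hi = np.array([_MIX_RANGES[c][1] for c in comp])
    return rng.uniform(lo, hi)


def _grow_path(rng, start_um, direction, length_um, bounds_um, margin_um,
               branch_prob_per_um=0.0, depth=0, step_um=0.5, jitter_deg=5.0):
    """Random-walk a neurite; returns a list of polylines (um coords),
    the first being the main path, the rest branches."""
    paths = []
    pts = [np.asarray(start_um, dtype=float)]
    d = float(direction)
    remaining = length_um
    while remaining > 0:
        d += math.radians(rng.normal(0.0, jitter_deg))
        nxt = pts[-1] + step_um * np.array([math.sin(d), math.cos(d)])
        if np.any(nxt < margin_um) or np.any(nxt > bounds_um - margin_um):
            break
        pts.append(nxt)
        remaining -= step_um
        if depth < 2 and rng.random() < branch_prob_per_um * step_um and remaining > 4:
            side = 1 if rng.random() < 0.5 else -1
            child = _grow_path(
                rng, nxt, d + side * math.radians(rng.uniform(25, 45)),
                remaining * 0.6, bounds_um, margin_um,
                branch_prob_per_um, depth + 1, step_um, jitter_deg,
            )
            paths.extend(child)
    if len(pts) >= 2:
        paths.insert(0, np.vstack(pts))
    return paths


def _polyline_length_um(path_um: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(path_um, axis=0).T)))


def _render_paths(shape, paths_px, width_px) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    for path in paths_px:
        p = np.asarray(path)
        for i in range(len(p) - 1):
            rr, cc = draw_line(
                int(round(p[i, 0])), int(round(p[i, 1])),
                int(round(p[i + 1, 0])), int(round(p[i + 1, 1])),
            )
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            canvas[rr[keep], cc[keep]] = True
    radius = max(1, int(round(width_px / 2.0)))
    return ndimage.binary_dilation(canvas, structure=disk(radius))


def generate_neuron_image(spec: NeuronSpec):
    """Return ``(image, truth)`` for a synthetic neuron arbor.

    The truth lists every protrusion with its attachment point (parent
    edge and parent centreline) and length; the axon carries none.
    """
    n = int(round(spec.image_size_um / spec.pixel_size_um))
    shape = (n, n)
    px = spec.pixel_size_um
    bounds = np.array([spec.image_size_um, spec.image_size_um])
    margin = 1.5

    ss = np.random.SeedSequence(spec.seed)
    rng_arbor, rng_filo, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    center = bounds / 2.0
    rr, cc = np.mgrid[0:n, 0:n]
    soma_mask = (np.hypot(rr - center[0] / px, cc - center[1] / px) * px) <= spec.soma_radius_um

    axon_dir = rng_arbor.uniform(0, 2 * math.pi)
    dendrite_paths = []
    for k in range(spec.n_dendrites):
        d = axon_dir + math.pi * (0.35 + 1.3 * k / max(spec.n_dendrites - 1, 1)) \
            + math.radians(rng_arbor.normal(0, 8))
        start = center + (spec.soma_radius_um - 0.3) * np.array([math.sin(d), math.cos(d)])
        length = rng_arbor.uniform(*spec.dendrite_length_um)
        dendrite_paths.extend(
            _grow_path(rng_arbor, start, d, length, bounds, margin, spec.branch_prob_per_um)
        )

    axon_start = center + (spec.soma_radius_um - 0.3) * np.array(
        [math.sin(axon_dir), math.cos(axon_dir)]
    )
    axon_paths = _grow_path(rng_arbor, axon_start, axon_dir, spec.axon_length_um,
                            bounds, margin, jitter_deg=3.0)
    for _ in range(spec.axon_branches):
        if not axon_paths:
            break
        main = axon_paths[0]
        idx = rng_arbor.integers(len(main) // 3, len(main) - 1)
        seg_dir = math.atan2(*(main[min(idx + 1, len(main) - 1)] - main[idx - 1]))
        side = 1 if rng_arbor.random() < 0.5 else -1
        axon_paths.extend(
            _grow_path(rng_arbor, main[idx], seg_dir + side * math.radians(50), 6.0,
                       bounds, margin, jitter_deg=3.0)
        )

    # --- filopodia along dendrites (Poisson process, rate density/20 per um)
    truth_filos: list[TruthFilopodium] = []
    filo_paths_um = []
    rate = spec.filopodia_density / 20.0
    half_w = spec.dendrite_width_um / 2.0
    for path in dendrite_paths:
        seg = np.diff(path, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        if rate <= 0 or total <= 0:
            continue
        # hard-core renewal process: gaps are min_gap + Exp with the mean
        # reduced so the realized density stays exactly at the spec rate;
        # the first arrival uses the equilibrium delay distribution so the
        # process is stationary (no density deficit on short branches)
        mean_gap = 1.0 / rate
        if mean_gap <= spec.min_gap_um:
            raise ValueError("filopodia_density too high for min_gap_um")
        exp_mean = mean_gap - spec.min_gap_um
        if rng_filo.random() < spec.min_gap_um / mean_gap:
            pos = rng_filo.uniform(0.0, spec.min_gap_um)
        else:
            pos = spec.min_gap_um + rng_filo.exponential(exp_mean)
        while pos < total:
            i = int(np.searchsorted(cum, pos) - 1)
            frac = (pos - cum[i]) / seg_len[i]
            p = path[i] + frac * seg[i]
            tangent = math.atan2(seg[i, 0], seg[i, 1])
            side = 1 if rng_filo.random() < 0.5 else -1
            d = tangent + side * (math.pi / 2) + math.radians(rng_filo.normal(0, 15))
            length = float(sample_filopodia_lengths(spec.length_mixture, 1, rng_filo)[0])
            placed = False
            for d_try in (d, tangent - side * (math.pi / 2)):
                unit = np.array([math.sin(d_try), math.cos(d_try)])
                edge = p + half_w * unit
                tip = edge + length * unit
                if np.all(tip >= margin) and np.all(tip <= bounds - margin):
                    placed = True
                    break
            if placed:
                filo_paths_um.append(np.vstack([p, tip]))
                truth_filos.append(
                    TruthFilopodium(
                        attachment_px=tuple(edge / px),
                        attachment_centerline_px=tuple(p / px),
                        length_um=length,
                        path_px=np.vstack([edge, tip]) / px,
                    )
                )
            pos += spec.min_gap_um + rng_filo.exponential(exp_mean)

    to_px = lambda paths: [np.asarray(p) / px for p in paths]
    branches_mask = _render_paths(shape, to_px(dendrite_paths + axon_paths),
                                  spec.dendrite_width_um / px)
    filo_mask_all = _render_paths(shape, to_px(filo_paths_um), spec.filopodium_width_um / px) \
        if filo_paths_um else np.zeros(shape, dtype=bool)

    img = np.zeros(shape)
    img[branches_mask | filo_mask_all] = spec.base_level
    img[soma_mask] = spec.soma_level
    footprint = branches_mask | filo_mask_all | soma_mask

    if spec.noise_sigma > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sigma * img[footprint].mean(), shape)
        np.clip(img, 0.0, None, out=img)

    process_masks = []
    body = branches_mask | soma_mask
    for tf in truth_filos:
        m = _thick_line_mask(shape, tf.path_px[0], tf.path_px[-1], spec.filopodium_width_um / px)
        process_masks.append(m & ~body)

    truth = SyntheticCellTruth(
        footprint_mask=footprint,
        process_masks=process_masks,
        filopodia=truth_filos,
        soma_mask=soma_mask,
        dendrite_paths_px=to_px(dendrite_paths),
        axon_paths_px=to_px(axon_paths),
        pixel_size_um=px,
    )
    image = CalibratedImage(img, px, channel="morphology", modality="epifluorescence")
    return image, truth


def total_dendrite_length_um(truth: SyntheticCellTruth) -> float:
    """Summed arc length of all dendrite centreline polylines."""
    return sum(_polyline_length_um(np.asarray(p) * truth.pixel_size_um)
               for p in truth.dendrite_paths_px)


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------


@dataclass
class VcCellSpec:
    """One synthetic voltage-clamped cell.

    Passive pathway: series (access) resistance ``Ra_MOhm`` into the
    membrane RC (``Cm_pF`` parallel ``Rm_GOhm``); the leak reversal is
    pinned at the holding potential so leak is zero at rest.  The sodium
    conductance activates as m_inf(V) = 1/(1+exp((V_half - V)/s)).  In
    ``quasi_static`` mode the sodium current follows m_inf instantly; in
    ``kinetic`` mode activation relaxes with tau_m and inactivation decays
    with tau_h.  Noise is multiplicative Gaussian on every current sample.
    """

    Gmax_nS: float = 15.0
    V_half_mV: float = -18.56
    slope_mV: float = 6.29
    E_rev_mV: float = 65.0
    Ra_MOhm: float = 8.0
    Cm_pF: float = 10.0
    Rm_GOhm: float = 1.0
    kinetics_mode: str = "quasi_static"  # or "kinetic"
    tau_m_ms: float = 0.1
    tau_h_ms: float = 5.0
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Gmax_nS < 0 or self.Ra_MOhm < 0:
            raise ValueError("Gmax and Ra must be >= 0")
        if not (self.slope_mV > 0 and self.Cm_pF > 0):
            raise ValueError("slope and Cm must be > 0")
        if self.kinetics_mode not in ("quasi_static", "kinetic"):
            raise ValueError("kinetics_mode must be 'quasi_static' or 'kinetic'")


def m_inf(v_mV, v_half_mV: float, slope_mV: float):
    """Boltzmann steady-state activation."""
    return 1.0 / (1.0 + np.exp((v_half_mV - np.asarray(v_mV, dtype=float)) / slope_mV))


def steady_state_vm(spec: VcCellSpec, vcmd_mV: float, holding_mV: float,
                    tol_mV: float = 1e-4, max_iter: int = 20000) -> float:
    """Membrane voltage satisfying Vm = Vcmd - I(Vm)*Ra (damped fixed point).

    Raises ``RuntimeError`` if the iteration fails to contract (pathological
    Ra*Gmax products).
    """
    ra_G = spec.Ra_MOhm * 1e-3
    if ra_G == 0:
        return float(vcmd_mV)
    vm = float(vcmd_mV)
    for _ in range(max_iter):
        i_pA = _total_steady_current(spec, vm, holding_mV)
        nxt = 0.5 * vm + 0.5 * (vcmd_mV - i_pA * ra_G)
        if not np.isfinite(nxt) or abs(nxt) > 1e4:
            raise RuntimeError("voltage fixed point diverged (pathological Ra*Gmax)")
        if abs(nxt - vm) < 0.5 * tol_mV:
            return nxt
        vm = nxt
    raise RuntimeError("voltage fixed point did not converge")


def _total_steady_current(spec: VcCellSpec, vm_mV: float, holding_mV: float) -> float:
    leak = (vm_mV - holding_mV) / spec.Rm_GOhm  # mV / GOhm = pA
    na = spec.Gmax_nS * float(m_inf(vm_mV, spec.V_half_mV, spec.slope_mV)) * (vm_mV - spec.E_rev_mV)
    return leak + na


def _step_response(spec: VcCellSpec, t_ms: np.ndarray, dv_mV: float,
                   holding_mV: float, vstep_mV: float) -> np.ndarray:
    """Analytic current during a step of dv from holding (t_ms from onset)."""
    ra_G = max(spec.Ra_MOhm * 1e-3, 1e-9)
    tau = spec.Cm_pF * (ra_G * spec.Rm_GOhm) / (ra_G + spec.Rm_GOhm)  # pF*GOhm = ms
    vm = steady_state_vm(spec, vstep_mV, holding_mV)
    i_ss = _total_steady_current(spec, vm, holding_mV)
    i0 = dv_mV / ra_G  # capacitive: cap shorts Rm at t=0
    if spec.kinetics_mode == "quasi_static":
        return i_ss + (i0 - i_ss) * np.exp(-t_ms / tau)
    # kinetic mode: passive part relaxes to the passive steady state while the
    # sodium current turns on with tau_m and inactivates with tau_h (Vm held
    # at its self-consistent steady value -- a documented simplification)
    i_pass_ss = dv_mV / (ra_G + spec.Rm_GOhm)
    passive = i_pass_ss + (i0 - i_pass_ss) * np.exp(-t_ms / tau)
    na_ss = spec.Gmax_nS * float(m_inf(vm, spec.V_half_mV, spec.slope_mV)) * (vm - spec.E_rev_mV)
    gate = (1.0 - np.exp(-t_ms / spec.tau_m_ms)) * np.exp(-t_ms / spec.tau_h_ms)
    return passive + na_ss * gate


def simulate_vc(spec: VcCellSpec, protocol: VoltageProtocol | None = None,
                metadata: dict | None = None) -> SweepSet:
    """Simulate one cell's full sweep set (test pulses + P/4 subpulses)."""
    protocol = protocol or VoltageProtocol()
    t = protocol.time_ms()
    in_pulse = (t >= protocol.pre_ms) & (t < protocol.pre_ms + protocol.pulse_ms)
    post = t >= protocol.pre_ms + protocol.pulse_ms
    t_on = t[in_pulse] - protocol.pre_ms
    t_off = t[post] - (protocol.pre_ms + protocol.pulse_ms)

    ra_G = max(spec.Ra_MOhm * 1e-3, 1e-9)
    tau = spec.Cm_pF * (ra_G * spec.Rm_GOhm) / (ra_G + spec.Rm_GOhm)

    ss = np.random.SeedSequence(spec.seed)
    streams = iter(ss.spawn(len(protocol.test_voltages_mV) * (1 + protocol.p4_count)))

    def build(vstep: float) -> np.ndarray:
        dv = vstep - protocol.holding_mV
        trace = np.zeros_like(t)
        trace[in_pulse] = _step_response(spec, t_on, dv, protocol.holding_mV, vstep)
        trace[post] = -(dv / ra_G) * np.exp(-t_off / tau)  # off transient back to rest
        rng = np.random.default_rng(next(streams))
        if spec.noise_sigma > 0:
            trace = trace * (1.0 + rng.normal(0.0, spec.noise_sigma, trace.shape))
        return trace

    test, subs, sub_amp = {}, {}, {}
    for v in protocol.test_voltages_mV:
        test[v] = build(v)
        dv_sub = protocol.p4_polarity * protocol.p4_fraction * (v - protocol.holding_mV)
        vsub = protocol.holding_mV + dv_sub
        subs[v] = np.stack([build(vsub) for _ in range(protocol.p4_count)])
        sub_amp[v] = dv_sub

    meta = dict(metadata or {})
    meta.setdefault("kinetics_mode", spec.kinetics_mode)
    return SweepSet(time_ms=t, protocol=protocol, test=test, subs=subs,
                    sub_amplitude_mV=sub_amp, metadata=meta)
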