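"""Display-only rendering helpers (no measurement semantics)."""

from __future__ import annotations

import numpy as np

from .types import ActivationFit, CalibratedImage, ConductanceCurve


def pseudocolor_difference(img: CalibratedImage, ax=None, cmap: str = "viridis"):
    """Render a difference image in a perceptually uniform colormap,
    symmetric about zero."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lim = float(np.max(np.abs(img.pixels))) or 1.0
    h, w = img.shape
    im = ax.imshow(img.pixels, cmap=cmap, vmin=-lim, vmax=lim,
                   extent=(0, w * img.pixel_size_um, h * img.pixel_size_um, 0))
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.figure.colorbar(im, ax=ax, label="intensity difference (AU)")
    return ax


def plot_activation(curve: ConductanceCurve, fit: ActivationFit | None = None, ax=None):
    """Normalized conductance-voltage points with the Boltzmann fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.vm_mV[curve.retained], curve.g_norm[curve.retained], "o",
            label="G$_M$/G$_0$")
    if fit is not None:
        v = np.linspace(curve.vm_mV.min(), curve.vm_mV.max(), 200)
        ax.plot(v, 1.0 / (1.0 + np.exp((fit.v_half_mV - v) / fit.slope_mV)), "-",
                label=f"V$_{{0.5}}$={fit.v_half_mV:.2f} mV, s={fit.slope_mV:.2f}")
    ax.set_xlabel("V$_m$ (mV)")
    ax.set_ylabel("relative conductance")
    ax.legend()
    return ax
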