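"""Review graphics: dose-response curves and per-field QC overlays.

The overlay (MBP raster + mask outline + detected fiber skeletons) is the
artifact an operator reviews for the cascade's visual-morphology criterion;
the dose-response plot accompanies confirmation fits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dose_response import DoseResponseFit
from .fiber_morphometrics import Fiber, MBPMask


def plot_dose_response(
    dose: Sequence[float],
    response: Sequence[float],
    fit: DoseResponseFit,
    path: str | Path,
    title: str = "",
) -> Path:
    """Scatter the data over the fitted 4PL curve; writes a PNG."""
    dose = np.asarray(dose, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(dose, response, "o", mfc="none", color="tab:blue", label="data")
    grid = np.logspace(np.log10(dose.min()) - 0.5, np.log10(dose.max()) + 0.5, 200)
    ax.semilogx(grid, fit.predict(grid), "-", color="tab:red",
                label=f"4PL fit (EC50 = {fit.ec50_uM:.3g})")
    ax.set_xlabel("dose (uM)")
    ax.set_ylabel("response")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def overlay_field(
    mbp: np.ndarray,
    mask: MBPMask,
    fibers: Sequence[Fiber],
    path: str | Path,
    title: str = "",
) -> Path:
    """MBP raster with the threshold mask outline and detected fiber skeletons."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(mbp), cmap="gray", interpolation="nearest")
    ax.contour(mask.mask, levels=[0.5], colors="tab:cyan", linewidths=0.6)
    for f in fibers:
        rr = [p[0] for p in f.skeleton]
        cc = [p[1] for p in f.skeleton]
        ax.plot(cc, rr, color="tab:red", linewidth=1.0)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
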