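"""Plot helpers for the standard summary panels."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .field_analysis import CrossSectionMap, EnergyProfile
from .transmission import FrequencyResponse


def plot_energy_profile(profiles: dict[str, EnergyProfile], path=None):
    """Normalized energy density versus axial distance, one curve per run."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, prof in profiles.items():
        z = prof.positions - prof.positions[prof.reference_index]
        ax.semilogy(z * 1e3, np.maximum(prof.values, 1e-12), label=label)
    ax.set_xlabel("axial distance from source (mm)")
    ax.set_ylabel("normalized energy density")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_cross_section(cmap: CrossSectionMap, path=None):
    """Transverse |E| amplitude map at one axial station."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    extent_mm = np.array([0, cmap.amplitude.shape[0], 0, cmap.amplitude.shape[1]])
    extent_mm = (extent_mm - extent_mm[[1, 1, 3, 3]] / 2) * cmap.cell_size * 1e3
    im = ax.imshow(cmap.amplitude.T, origin="lower", extent=extent_mm, cmap="inferno")
    fig.colorbar(im, ax=ax, label="|E| (V/m)")
    ax.set_title(f"station: {cmap.station}")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_response(resp: FrequencyResponse, cutoff=None, path=None):
    """Efficiency versus frequency or duration on a log abscissa."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(resp.abscissa, 100 * resp.efficiency, "o-")
    if cutoff is not None:
        ax.axvline(cutoff, ls="--", color="gray")
    ax.set_xlabel("frequency (Hz)" if resp.mode == "frequency" else "pulse duration (s)")
    ax.set_ylabel("transmission efficiency (%)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
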