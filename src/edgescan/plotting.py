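"""Beam-caustic plots: measured w(z) with the diffraction-limited overlay."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .propagation_analysis import PropagationFit, RadiusSeries

__all__ = ["plot_caustic"]


def plot_caustic(
    series: RadiusSeries,
    fit: PropagationFit | None = None,
    ideal: RadiusSeries | None = None,
    path: str | Path | None = None,
    title: str = "",
):
    """Plot w(z), mirrored below the axis to show the beam envelope.

    The measured radii appear as markers above and (mirrored) below zero;
    the fitted hyperbola and the ideal full-NA caustic are drawn as lines.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.z, series.w, "d", color="tab:blue", label="measured")
    ax.plot(series.z, -series.w, "d", mfc="none", color="tab:blue")
    if fit is not None:
        import numpy as np

        zz = np.linspace(series.z.min(), series.z.max(), 400)
        wf = np.sqrt(fit.w0**2 + fit.theta**2 * (zz - fit.z0) ** 2)
        ax.plot(zz, wf, "-", color="tab:orange", label=f"fit ({fit.method})")
        ax.plot(zz, -wf, "-", color="tab:orange")
    if ideal is not None:
        ax.plot(ideal.z, ideal.w, "k-", lw=2, label="ideal (full NA)")
        ax.plot(ideal.z, -ideal.w, "k-", lw=2)
    ax.axhline(0, color="0.7", lw=0.5)
    ax.set_xlabel("z (um)")
    ax.set_ylabel("beam radius w (um)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
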