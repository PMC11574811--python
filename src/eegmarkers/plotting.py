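"""Optional annotated spectrum plots (matplotlib imported lazily)."""

from __future__ import annotations

from .peaks import PeakMeasures, SpectralPeak
from .spectral import PSDEstimate

__all__ = ["plot_annotated_psd"]


def plot_annotated_psd(psd: PSDEstimate, peaks: list[SpectralPeak],
                       measures: PeakMeasures | None = None, ax=None):
    """Log10 spectrum with detected peaks, prominences and widths marked.

    Mirrors the visual-inspection step of the analysis: every detected peak
    is annotated; the chosen band peak (if any) is highlighted.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(psd.freqs, psd.log_power, color="0.2", lw=1.2)
    for pk in peaks:
        ax.plot(pk.frequency, pk.height, "v", color="tab:red", ms=6)
        ax.vlines(pk.frequency, pk.height - pk.prominence, pk.height,
                  color="tab:red", lw=1, alpha=0.7)
        ax.hlines(pk.height - pk.prominence / 2, pk.left_cross, pk.right_cross,
                  color="tab:blue", lw=1, alpha=0.7)
    if measures is not None and measures.band != "none":
        ax.annotate(
            f"{measures.band}: {measures.frequency:.2f} Hz",
            xy=(measures.frequency, measures.power),
            xytext=(measures.frequency + 2, measures.power + 0.2),
            fontsize=9,
        )
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("log10 power (uV$^2$/Hz)")
    return ax
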