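"""Minimal waveform rendering (pressure / flow / lung volume panels)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .network import WaveformSeries  # noqa: E402


def plot_waveforms(waveforms: WaveformSeries, out_path: str | None = None,
                   last_cycles: int | None = 2):
    """Three stacked panels: node pressures, lung flows, lung volumes.

    Returns the matplotlib figure; saves a PNG when ``out_path`` is given.
    """
    if last_cycles is not None and waveforms.n_cycles > last_cycles:
        s, _ = waveforms.cycle_bounds(waveforms.n_cycles - last_cycles)
    else:
        s = 0
    t = waveforms.time[s:]

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
    for node, arr in waveforms.pressures.items():
        axes[0].plot(t, arr[s:], label=node)
    axes[0].set_ylabel("pressure (cmH$_2$O)")
    axes[0].legend(loc="upper right", fontsize=8)

    for name, arr in waveforms.flows.items():
        if name.startswith("lung_"):
            axes[1].plot(t, arr[s:], label=name.replace("lung_", "patient "))
    axes[1].set_ylabel("flow (L/min)")
    axes[1].legend(loc="upper right", fontsize=8)

    for pat, arr in waveforms.volumes.items():
        axes[2].plot(t, arr[s:], label=f"patient {pat}")
    axes[2].set_ylabel("lung volume (ml)")
    axes[2].set_xlabel("time (s)")
    axes[2].legend(loc="upper right", fontsize=8)

    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
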