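"""Optional diagnostic plots (requires the 'plot' extra)."""

from __future__ import annotations

from .fitting import MultiExpFit
from .simulate import Trace


def plot_fit(trace: Trace, fit: MultiExpFit, path=None):
    """Trace + fitted model on top, residuals below; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax, axr) = plt.subplots(
        2, 1, sharex=True, height_ratios=[3, 1], figsize=(6, 4.5), layout="constrained"
    )
    ax.plot(trace.times, trace.fluorescence, ".", ms=2, color="0.6", label="trace")
    ax.plot(trace.times, fit.model(trace.times), "-", color="C3", lw=1.5,
            label=f"{fit.n_phases}-phase fit")
    ax.set_ylabel("fluorescence (AU)")
    ax.legend(frameon=False, fontsize=8)
    axr.axhline(0.0, color="0.3", lw=0.8)
    axr.plot(trace.times, trace.fluorescence - fit.model(trace.times), ".", ms=2, color="C0")
    axr.set_xlabel("time (s)")
    axr.set_ylabel("residual (AU)")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
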