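"""SSC curve plots: per-segment rotation against cumulative block rotation."""

from __future__ import annotations

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from cervikin.kinematics import SSCCurve
from cervikin.segments import SEGMENTS

_COLORS = {"C4-C5": "tab:blue", "C5-C6": "tab:orange", "C6-C7": "tab:green"}


def plot_ssc(curve: SSCCurve, path=None, title: str | None = None):
    """Plot an SSC curve (degrees of per-frame rotation vs cumulative C4-C7
    rotation). Writes PNG/SVG when ``path`` is given; returns the Figure."""
    fig = Figure(figsize=(6.5, 4.0))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    if curve.insufficient_motion:
        ax.text(0.5, 0.5, "insufficient motion", ha="center", va="center",
                transform=ax.transAxes)
    else:
        for seg in SEGMENTS:
            ax.plot(curve.x, curve.y[seg], label=seg, color=_COLORS[seg])
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.legend(frameon=False)
    ax.set_xlabel("Cumulative sagittal rotation C4-C7 (deg)")
    ax.set_ylabel("Rotation (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
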