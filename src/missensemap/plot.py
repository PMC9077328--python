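"""1D variant plots: positional ticks, domain diagram, Vd/Vp labels.

The figure shows one tick per missense-variable residue position along a
1..protein_length axis, coloured rectangles for user-supplied domains on a
thin baseline bar, and (optionally) each domain's Vd/Vp ratio printed above
it.  Mark height is uniform by default — the plot encodes position, not
frequency — with an optional flag to scale tick height by frequency bin.

SVG output tags each variant tick with a ``variant-mark-<pos>`` group id
and each domain rectangle with ``domain-<name>``, so figure content is
machine-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .domains import DomainDefinition, VdVpResult
from .errors import ConfigurationError
from .profile import N_BINS, ResidueProfile

__all__ = ["PlotSpec", "plot_linear"]

_DOMAIN_PALETTE = (
    "#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
    "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd",
)


@dataclass
class PlotSpec:
    """Visual parameters of the 1D plot (dimensions in inches)."""

    width: float = 10.0
    height: float = 2.8
    domain_colors: dict[str, str] = field(default_factory=dict)
    show_vdvp_labels: bool = True
    pathogenic_marks: list[tuple[int, str]] = field(default_factory=list)
    scale_by_bin: bool = False
    tick_color: str = "#2166ac"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")


def plot_linear(
    profile: ResidueProfile,
    domains: Sequence[DomainDefinition],
    vdvp: Sequence[VdVpResult],
    spec: PlotSpec | None = None,
    out: str | Path = "plot.svg",
) -> Path:
    """Render the 1D variant plot and save it (SVG or PNG by extension)."""
    spec = spec or PlotSpec()
    L = profile.protein_length
    for dom in domains:
        if dom.end > L:
            raise ConfigurationError(
                f"domain {dom.name!r} ({dom.start}-{dom.end}) exceeds protein length {L}"
            )
    ratios = {r.domain.name: r.vdvp_ratio for r in vdvp}

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    base_y, base_h = 0.0, 0.12
    tick_y0, tick_full = base_h + 0.03, 0.55

    # thin baseline bar for unassigned inter-domain regions
    ax.add_patch(
        Rectangle((1, base_y + base_h / 3), L - 1, base_h / 3,
                  facecolor="#aaaaaa", edgecolor="none", gid="baseline")
    )
    for i, dom in enumerate(domains):
        color = spec.domain_colors.get(dom.name, _DOMAIN_PALETTE[i % len(_DOMAIN_PALETTE)])
        ax.add_patch(
            Rectangle((dom.start, base_y), dom.length, base_h,
                      facecolor=color, edgecolor="black", linewidth=0.5,
                      gid=f"domain-{dom.name}")
        )
        mid = (dom.start + dom.end) / 2
        ax.text(mid, base_y - 0.10, dom.name, ha="center", va="top", fontsize=7)
        if spec.show_vdvp_labels and dom.name in ratios:
            ratio = ratios[dom.name]
            label = "NA" if ratio is None else f"{ratio:.2f}"
            ax.text(mid, tick_y0 + tick_full + 0.06, label, ha="center",
                    va="bottom", fontsize=7, gid=f"vdvp-label-{dom.name}")

    for pos in profile.positions():
        if spec.scale_by_bin:
            h = tick_full * profile.aggregates[pos].bin_index / N_BINS
        else:
            h = tick_full
        ax.plot([pos, pos], [tick_y0, tick_y0 + h], color=spec.tick_color,
                linewidth=0.6, solid_capstyle="butt", gid=f"variant-mark-{pos}")

    for pos, label in spec.pathogenic_marks:
        ax.plot([pos], [base_y - 0.04], marker="^", markersize=5,
                color="#c0392b", gid=f"pathogenic-mark-{pos}")
        if label:
            ax.text(pos, base_y - 0.22, label, ha="center", va="top",
                    fontsize=6, color="#c0392b")

    ax.set_xlim(0, L + 1)
    ax.set_ylim(-0.45, tick_y0 + tick_full + 0.3)
    ax.set_yticks([])
    ax.set_xlabel("residue position")
    ax.set_title(profile.protein_id, fontsize=9)
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out
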