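"""Layered hypercube trajectory diagrams and fitness-by-environment panels.

Figures are structural: nodes are arranged in layers by Hamming distance
from the source, edges are single-substitution steps, and steps belonging
to accessible direct paths are highlighted.  An optional right-hand panel
plots each genotype's fitness across environments on a log scale (word
frequencies span orders of magnitude); zero fitness values are lifted to a
pseudocount and the lift is annotated.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .accessibility import AccessibilityReport
from .fitness import EnvironmentSeries

__all__ = ["render_trajectory_figure"]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def render_trajectory_figure(report: AccessibilityReport,
                             series: EnvironmentSeries | None, out) -> None:
    """Render the hypercube diagram (plus fitness panel when a series is given).

    Raises ``ValueError`` on an empty report.
    """
    if not report.verdicts:
        raise ValueError("cannot render an empty accessibility report")

    source = report.verdicts[0].path.genotypes[0]
    nodes = sorted({g for v in report.verdicts for g in v.path.genotypes})
    layers: dict[int, list[str]] = {}
    for g in nodes:
        layers.setdefault(_hamming(g, source), []).append(g)
    pos = {}
    for dist, members in layers.items():
        for k, g in enumerate(sorted(members)):
            pos[g] = (dist, k - (len(members) - 1) / 2.0)

    edges = set()
    highlight = set()
    for v in report.verdicts:
        chain = v.path.genotypes
        for a, b in zip(chain, chain[1:]):
            edges.add((a, b))
            if v.accessible:
                highlight.add((a, b))

    n_panels = 2 if series is not None and len(series) >= 1 else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(6 * n_panels, 5))
    ax = axes[0] if n_panels == 2 else axes

    for a, b in sorted(edges):
        (xa, ya), (xb, yb) = pos[a], pos[b]
        hot = (a, b) in highlight
        ax.annotate(
            "", xy=(xb, yb), xytext=(xa, ya),
            arrowprops=dict(
                arrowstyle="-|>",
                color="#d62728" if hot else "#bbbbbb",
                lw=2.0 if hot else 0.8,
            ),
        )
    for g, (x, y) in pos.items():
        ax.scatter([x], [y], s=550, zorder=3,
                   color="#1f77b4" if g in (source,) else "white",
                   edgecolors="#1f77b4")
        ax.annotate(g, (x, y), ha="center", va="center", fontsize=7, zorder=4,
                    color="white" if g == source else "#1f77b4")
    ax.set_xlabel("mutational steps from source")
    ax.set_yticks([])
    ax.set_title(
        f"environment {report.environment}: "
        f"{report.n_accessible}/{report.n_paths} direct paths accessible"
    )

    if n_panels == 2:
        ax2 = axes[1]
        envs = series.environments
        positive = [series[e][g] for e in envs for g in series.genotypes
                    if series[e][g] > 0]
        floor = (min(positive) / 10.0) if positive else 1e-12
        lifted = False
        for g in series.genotypes:
            ys = []
            for e in envs:
                f = series[e][g]
                if f <= 0:
                    f = floor
                    lifted = True
                ys.append(f)
            ax2.plot(range(len(envs)), ys, marker="o", label=g, lw=1)
        ax2.set_yscale("log")
        ax2.set_xticks(range(len(envs)))
        ax2.set_xticklabels([str(e) for e in envs])
        ax2.set_xlabel("environment")
        ax2.set_ylabel("fitness (log scale)")
        if lifted:
            ax2.annotate(f"zero fitness shown at pseudocount {floor:g}",
                         xy=(0.02, 0.02), xycoords="axes fraction", fontsize=7)
        if len(series.genotypes) <= 20:
            ax2.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
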