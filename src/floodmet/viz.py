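"""Optional plotting helpers (requires matplotlib, extra ``plot``)."""

from __future__ import annotations

from .gmea import EFFECTIVE_THRESHOLD, ReductionMatrix


def plot_reduction_heatmap(
    matrix: ReductionMatrix,
    path=None,
    threshold: float = EFFECTIVE_THRESHOLD,
    ax=None,
):
    """Heatmap of the reduction-ratio matrix with effective cells outlined.

    Cells with ratio below ``threshold`` (effective enzyme-metabolite
    pairs) are framed in red.  Returns the matplotlib Axes; writes to
    ``path`` (PNG/SVG by suffix) when given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    values = matrix.values
    if ax is None:
        _, ax = plt.subplots(
            figsize=(0.5 * len(values.columns) + 2, 0.35 * len(values.index) + 2)
        )
    im = ax.imshow(values.to_numpy(), cmap="RdBu", vmin=0.0, vmax=2.0, aspect="auto")
    ax.set_xticks(range(len(values.columns)), values.columns, rotation=90, fontsize=8)
    ax.set_yticks(range(len(values.index)), values.index, fontsize=8)
    for i, rid in enumerate(values.index):
        for j, mid in enumerate(values.columns):
            if values.at[rid, mid] < threshold:
                ax.add_patch(
                    Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                              edgecolor="red", linewidth=1.2)
                )
    ax.figure.colorbar(im, ax=ax, label="accumulation reduction ratio")
    ax.set_xlabel("metabolite")
    ax.set_ylabel("modified reaction")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
    return ax
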