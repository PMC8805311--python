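"""Optional matplotlib views: DVH curves and DVH-difference boxplots."""

from __future__ import annotations

import pandas as pd

from .dosimetry import DVHCurve


def plot_dvh(curves: dict[str, DVHCurve], prescription: float | None = None):
    """Cumulative DVH curves, one line per structure; volume in percent."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(curve.dose_gy, 100.0 * curve.volume_fraction, label=name)
    if prescription is not None:
        ax.axvline(prescription, color="k", ls=":", lw=0.8, label="prescription")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_dvh_difference_box(frame: pd.DataFrame):
    """Boxplots of per-case test-minus-reference DVH parameter differences.

    Two panels: organ-at-risk V-parameters (percentage points) and target
    D/V parameters (Gy / percentage points), from the ``diff_*`` columns of
    a cohort frame (see :func:`rtsegeval.cohort.cases_to_frame`).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    diff_cols = [c for c in frame.columns if c.startswith("diff_")]
    if not diff_cols:
        raise ValueError("frame has no diff_* columns")
    oar = [c for c in diff_cols if c.startswith(("diff_rectum", "diff_bladder"))]
    target = [c for c in diff_cols if c not in oar]
    fig, axes = plt.subplots(2, 1, figsize=(7, 6))
    for ax, cols, title in (
        (axes[0], oar, "organs at risk (percentage points)"),
        (axes[1], target, "target (Gy for D, percentage points for V)"),
    ):
        if not cols:
            ax.set_visible(False)
            continue
        data = [frame[c].dropna() for c in cols]
        ax.boxplot(data, tick_labels=[c.removeprefix("diff_") for c in cols],
                   whis=(5, 95))
        ax.axhline(0, color="k", lw=0.6)
        ax.set_title(title, fontsize=9)
        ax.tick_params(axis="x", labelrotation=30, labelsize=7)
    fig.tight_layout()
    return fig
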