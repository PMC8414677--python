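"""Summary figures: flatness by side and by NVC stratum.

Figures are derived artifacts only; no number is ever read back from them.
Significance annotations are keyed to the pipeline's own p-values.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import SubjectRecord, paired_side_comparison

__all__ = ["summary_plots"]


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return "n/a"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _panel(ax, groups: dict[str, np.ndarray], title: str, p: float) -> None:
    labels = list(groups)
    data = [groups[k] for k in labels]
    ax.boxplot(data, tick_labels=labels, widths=0.5)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.12, 0.12, len(vals)), vals, ".", alpha=0.4, ms=3)
    ax.set_title(f"{title}  [{_stars(p)}]", fontsize=9)
    ax.set_ylabel("flatness")


def summary_plots(records: list[SubjectRecord], out_dir) -> list[Path]:
    """Write flatness-by-side and flatness-by-NVC-stratum figures.

    Returns the list of files written; strata with fewer than 3 subjects are
    omitted (noted on the panel grid by their absence).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ptn = [r for r in records if r.group == "PTN"]
    hc = [r for r in records if r.group == "HC"]
    written: list[Path] = []

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    panels = [
        ("PTN affected vs unaffected", ptn, "affected"),
        ("PTN left vs right", ptn, "left_right"),
        ("HC left vs right", hc, "left_right"),
    ]
    for ax, (title, recs, pairing) in zip(axes, panels):
        if len(recs) < 3:
            ax.set_axis_off()
            continue
        res = paired_side_comparison(recs, "flatness", pairing)
        sides = ("affected", "unaffected") if pairing == "affected" else ("left", "right")
        groups = {s: np.array([getattr(r.side(s), "flatness") for r in recs]) for s in sides}
        _panel(ax, groups, title, res.p_value)
    fig.tight_layout()
    path = out_dir / "flatness_by_side.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    strata = {
        "no NVC both sides": lambda r: r.nvc_left == "no" and r.nvc_right == "no",
        "NVC both sides": lambda r: r.nvc_left == "yes" and r.nvc_right == "yes",
        "NVC affected only": lambda r: r.nvc("affected") == "yes" and r.nvc("unaffected") == "no",
        "NVC unaffected only": lambda r: r.nvc("affected") == "no" and r.nvc("unaffected") == "yes",
    }
    fig, axes = plt.subplots(1, len(strata), figsize=(13, 3.2))
    for ax, (title, pred) in zip(np.atleast_1d(axes), strata.items()):
        recs = [r for r in ptn if pred(r)]
        if len(recs) < 3:
            ax.set_axis_off()
            ax.set_title(f"{title} (n={len(recs)}, omitted)", fontsize=8)
            continue
        res = paired_side_comparison(recs, "flatness", "affected")
        groups = {
            s: np.array([getattr(r.side(s), "flatness") for r in recs])
            for s in ("affected", "unaffected")
        }
        _panel(ax, groups, f"{title} (n={len(recs)})", res.p_value)
    fig.tight_layout()
    path = out_dir / "flatness_by_nvc.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
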