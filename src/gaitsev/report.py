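"""Figures and text reports: confusion-matrix heat map, knee ROM curves,
ReliefF ranking table."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .config import GROUPS
from .models import CLASS_ORDER, CvReport
from .relieff import ReliefFWeights

__all__ = ["confusion_matrix_figure", "knee_rom_figure", "relieff_table"]

_PRETTY = {
    "healthy_control": "Healthy",
    "mci": "MCI",
    "mild_dementia": "Mild",
    "moderate_dementia": "Moderate",
}


def confusion_matrix_figure(report: CvReport, path: str | Path) -> None:
    """4x4 confusion-matrix heat map (rows = actual, columns = predicted)."""
    c = report.confusion
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(c, cmap="Blues")
    labels = [_PRETTY.get(g, g) for g in CLASS_ORDER[: c.shape[0]]]
    ax.set_xticks(range(c.shape[1]), labels, rotation=30, ha="right")
    ax.set_yticks(range(c.shape[0]), labels)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("Actual")
    thr = c.max() / 2.0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            ax.text(
                j, i, str(int(c[i, j])), ha="center", va="center",
                color="white" if c[i, j] > thr else "black",
            )
    ax.set_title(f"SVM severity classification (accuracy {report.accuracy:.1f}%)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def knee_rom_figure(curves: dict[str, tuple[np.ndarray, np.ndarray]], path: str | Path) -> None:
    """Sagittal knee-angle curves over the gait cycle, one line per group.

    ``curves`` maps group name to (percent-of-cycle, knee angle deg) for a
    representative subject; knee mobility shrinks with dementia severity.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for g in GROUPS:
        if g in curves:
            x, y = curves[g]
            ax.plot(x, y, label=_PRETTY.get(g, g))
    ax.set_xlabel("Gait cycle (%)")
    ax.set_ylabel("Knee flexion (deg)")
    ax.set_title("Knee sagittal motion by severity group")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def relieff_table(weights: ReliefFWeights) -> str:
    """Ranked feature-importance table as plain text."""
    lines = ["rank  weight    feature", "----  --------  -------"]
    w = weights.as_dict()
    for rank, name in enumerate(weights.ranking, start=1):
        lines.append(f"{rank:>4}  {w[name]:+.4f}   {name}")
    return "\n".join(lines)
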