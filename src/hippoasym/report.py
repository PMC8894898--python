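"""Quantitative report: left-vs-right scatter with normative limit bands.

One scan is one point (left metric on x, right on y). Perfect symmetry lies
on the identity diagonal; the 2-SD and 3-SD normative bands are drawn as
the loci of constant asymmetry index, AI(lh, rh) = mean +/- z*SD — since
the AI is a ratio these are rays through the origin (rh = lh (1-a)/(1+a)),
not parallel offsets. The same decision rule that classifies scans
(:func:`hippoasym.asymmetry.classify_by_asymmetry`) produces the report's
outside-band flags, and all numeric content is duplicated into a
coordinates CSV so the geometry can be checked without parsing images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .asymmetry import AsymmetryLimits, asymmetry_index, classify_by_asymmetry
from .io import ScanRecord

__all__ = ["ReportSpec", "render_report"]

_GROUP_COLORS = {
    "HC": "#9e9e9e",
    "EPI-other": "#1f77b4",
    "HS-left": "#d62728",
    "HS-right": "#ff7f0e",
    "HS-bilateral": "#9467bd",
}


@dataclass
class ReportSpec:
    metric: str = "surface_to_volume_ratio"
    levels: Tuple[str, ...] = ("2SD", "3SD")
    highlight_scan_ids: Tuple[str, ...] = ()
    image_path: Optional[str] = None       # written as both .svg and .png
    coordinates_path: Optional[str] = None


def _ai_ray(ai_value: float, lh: np.ndarray) -> np.ndarray:
    """rh along the constant-AI locus: AI=(lh-rh)/(lh+rh) -> rh=lh(1-a)/(1+a)."""
    return lh * (1.0 - ai_value) / (1.0 + ai_value)


def render_report(records: Sequence[ScanRecord], limits: AsymmetryLimits,
                  spec: ReportSpec) -> pd.DataFrame:
    """Render the biomarker report and return the per-scan coordinates table.

    The returned (and optionally written) table has one row per scan with
    its (x, y) = (lh, rh) coordinates, AI, and the classification at each
    requested limit level. Raises ``KeyError`` if any scan lacks the metric.
    """
    metric = spec.metric
    rows: List[Dict] = []
    for r in records:
        if metric not in r.measures:
            raise KeyError(f"scan {r.scan_id} lacks metric {metric!r}")
        lh, rh = r.measures[metric]
        ai = asymmetry_index(lh, rh)
        row = {"scan_id": r.scan_id, "subject_id": r.subject_id,
               "group": r.group, "lh": lh, "rh": rh, "ai": ai}
        for level in spec.levels:
            row[f"class_{level}"] = classify_by_asymmetry(ai, limits, level=level)
        rows.append(row)
    coords = pd.DataFrame(rows)

    fig, ax = plt.subplots(figsize=(6.5, 6.5))
    span = np.array([coords[["lh", "rh"]].min().min() * 0.9,
                     coords[["lh", "rh"]].max().max() * 1.1])
    line = np.linspace(span[0], span[1], 2)
    ax.plot(line, line, color="k", lw=0.8, label="symmetry")
    styles = {"2SD": (":", 0.8), "3SD": ("--", 1.0)}
    for level in spec.levels:
        lo, hi = limits.thresholds[level]
        ls, lw = styles.get(level, ("-.", 0.8))
        for a in (lo, hi):
            ax.plot(line, _ai_ray(a, line), color="dimgray", ls=ls, lw=lw)
        ax.plot([], [], color="dimgray", ls=ls, lw=lw, label=f"±{level} AI limit")
    for group, sub in coords.groupby("group"):
        ax.scatter(sub["lh"], sub["rh"], s=14, alpha=0.75,
                   color=_GROUP_COLORS.get(group, "k"), label=group,
                   zorder=3)
    for sid in spec.highlight_scan_ids:
        sub = coords[coords["scan_id"] == sid]
        if len(sub):
            ax.scatter(sub["lh"], sub["rh"], s=90, facecolors="none",
                       edgecolors="k", lw=1.4, zorder=4)
            ax.annotate(sid, (sub["lh"].iloc[0], sub["rh"].iloc[0]),
                        textcoords="offset points", xytext=(6, 6), fontsize=7)
    ax.set_xlim(span)
    ax.set_ylim(span)
    ax.set_xlabel(f"left {metric}")
    ax.set_ylabel(f"right {metric}")
    ax.set_title(f"{metric}: left vs right with normative AI limits "
                 f"(n HC = {limits.n_hc})")
    ax.legend(fontsize=7, loc="upper left")
    fig.tight_layout()

    if spec.image_path is not None:
        base = Path(spec.image_path)
        base.parent.mkdir(parents=True, exist_ok=True)
        for ext in (".svg", ".png"):
            fig.savefig(base.with_suffix(ext), dpi=150)
    plt.close(fig)

    if spec.coordinates_path is not None:
        Path(spec.coordinates_path).parent.mkdir(parents=True, exist_ok=True)
        coords.to_csv(spec.coordinates_path, index=False)
    return coords
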