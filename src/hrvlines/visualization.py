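"""Plotting: the 4-dimensional variability graph and the signature space.

For the canonical order N=5 each window contributes a 4-component truncated
Delta vector; the graph renders the first three (optionally rotated)
components as 3D position and hue-encodes the fourth on a 0-1 color scale.
Catalog lines can be overlaid as chords through the origin.  The signature
space scatter places each record at (presence A1+, presence B1, Phi), the
three coordinates that separate normal from heart-failure-like records
most sharply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers only request files
import matplotlib.pyplot as plt
import numpy as np

from .catalog import ArrhythmiaLine, make_b1
from .geometry import DeltaField, truncate_for_graph

__all__ = [
    "GraphProjection",
    "hf_view_projection",
    "plot_delta_graph",
    "plot_signature_space",
]


@dataclass(frozen=True)
class GraphProjection:
    """Rotation of the first three truncated components plus hue mapping."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    hue_component: int = 3
    hue_range: tuple | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", r)


def hf_view_projection() -> GraphProjection:
    """A deterministic view that spreads the three B1-family lines.

    The published figures use a particular view angle that reduces the
    main lines and planes to three; that camera is not stated numerically,
    so this rotation is derived from the catalog geometry instead: the
    mean direction of the three canonical order-5 B1-family lines (their
    first three truncated components) becomes the line of sight, so the
    three lines spread maximally in the viewing plane.  Det(R) = +1.
    """
    v = [make_b1(5, i).truncated_unit()[:3] for i in range(3)]
    v = [u / np.linalg.norm(u) for u in v]
    z = v[0] + v[1] + v[2]
    z = z / np.linalg.norm(z)
    u1 = v[0] - (v[0] @ z) * z
    u1 = u1 / np.linalg.norm(u1)
    u2 = np.cross(z, u1)
    rot = np.vstack([u1, u2, z])
    if np.linalg.det(rot) < 0:
        rot[1] = -rot[1]
    return GraphProjection(rotation=rot)


def _hue_colors(h: np.ndarray, hue_range: tuple | None):
    if hue_range is None:
        lim = float(np.max(np.abs(h))) or 1.0
        hue_range = (-lim, lim)
    lo, hi = hue_range
    span = (hi - lo) or 1.0
    hue = np.clip((h - lo) / span, 0.0, 1.0)
    return plt.get_cmap("hsv")(hue), hue_range


def plot_delta_graph(
    field: DeltaField,
    out_path,
    projection: GraphProjection | None = None,
    overlay_lines: list[ArrhythmiaLine] | None = None,
    drop_quiescent: bool = False,
    quiescence_eps: float = 1e-6,
    point_size: float = 2.0,
):
    """3D + hue scatter of an order-5 Delta (or delta) field.

    Raises for other orders: the 4-dimensional rendering needs exactly
    four truncated components (use pairwise component plots for other N).
    Returns the number of points drawn.
    """
    if field.order != 5:
        raise ValueError(
            f"the 4D graph requires an order-5 field (got N={field.order}); "
            "plot pairwise truncated components for other orders"
        )
    projection = projection or GraphProjection()
    T = truncate_for_graph(field)
    if drop_quiescent:
        T = T[np.linalg.norm(T, axis=1) > quiescence_eps]
    xyz = T[:, :3] @ projection.rotation.T
    colors, hue_range = _hue_colors(T[:, projection.hue_component], projection.hue_range)

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(xyz[:, 0], xyz[:, 1], xyz[:, 2], c=colors, s=point_size, linewidths=0)
    if overlay_lines:
        reach = float(np.max(np.linalg.norm(T, axis=1))) if len(T) else 1.0
        for line in overlay_lines:
            if line.order != 5:
                continue
            d = line.truncated_unit()
            seg = np.outer([-reach, reach], d[:3]) @ projection.rotation.T
            ax.plot(seg[:, 0], seg[:, 1], seg[:, 2], lw=0.8, alpha=0.7)
            ax.text(*(reach * (d[:3] @ projection.rotation.T)), line.name, fontsize=7)
    label = "Δ" if field.normalization == "global" else "δ"
    ax.set_xlabel(f"{label} view-1")
    ax.set_ylabel(f"{label} view-2")
    ax.set_zlabel(f"{label} view-3")
    ax.set_title(
        f"{label} field, N=5 ({len(xyz)} windows); hue = component "
        f"{projection.hue_component} in [{hue_range[0]:.3g}, {hue_range[1]:.3g}]"
    )
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return len(xyz)


def plot_signature_space(points, labels, out_path):
    """Scatter of records at (A1+ presence, B1 presence) and in 3D with Phi.

    ``points`` is a sequence of (a1plus, b1, phi) triples, ``labels`` the
    matching group labels (one color per group).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or not len(pts):
        raise ValueError("points must be a non-empty sequence of (A1+, B1, phi)")
    labels = np.asarray(list(labels))
    if labels.size != len(pts):
        raise ValueError("labels must match points in length")

    fig = plt.figure(figsize=(11, 5))
    ax2 = fig.add_subplot(1, 2, 1)
    ax3 = fig.add_subplot(1, 2, 2, projection="3d")
    for grp in dict.fromkeys(labels):  # stable group order
        sel = labels == grp
        ax2.scatter(pts[sel, 0], pts[sel, 1], label=str(grp), s=18)
        ax3.scatter(pts[sel, 0], pts[sel, 1], pts[sel, 2], label=str(grp), s=18)
    ax2.set_xlabel("presence A1+ (%)")
    ax2.set_ylabel("presence B1 (%)")
    ax2.legend()
    ax3.set_xlabel("presence A1+ (%)")
    ax3.set_ylabel("presence B1 (%)")
    ax3.set_zlabel("Φ")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
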