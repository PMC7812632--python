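"""Topographic rendering of inter-brain links and significant sensors.

Two head outlines are drawn side by side with sensors projected by an
azimuthal equidistant projection; inter-brain links above a user-defined
threshold are drawn as 10th-order Bezier curves, colored on a sequential
red colormap for positive values and blue for negative, with line width
increasing with connection strength.  Bad channels are drawn with a cross.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .epochs_io import EpochArray
from .stats import _project_azimuthal

BEZIER_ORDER = 10
HEAD_GAP = 3.0  # distance between head centers in projected units


@dataclass
class LinkSet:
    """Suprathreshold inter-brain links: (channel_1 index, channel_2 index, value)."""

    links: list[tuple[int, int, float]]
    threshold: float
    mode: str = "signed"


def extract_links(inter: np.ndarray, threshold: float, mode: str = "signed") -> LinkSet:
    """All inter-brain cells exceeding ``threshold``, in row-major order.

    ``mode='signed'`` keeps cells with ``value > threshold``;
    ``mode='abs'`` keeps cells with ``|value| > threshold``.
    """
    inter = np.asarray(inter, dtype=float)
    if mode not in ("signed", "abs"):
        raise ValueError(f"mode must be 'signed' or 'abs', got {mode!r}")
    test = np.abs(inter) if mode == "abs" else inter
    links = [
        (int(i), int(j), float(inter[i, j]))
        for i, j in np.argwhere(test > threshold)
    ]
    return LinkSet(links=links, threshold=threshold, mode=mode)


def bezier_link(p_start, p_end, steps: int = 10) -> np.ndarray:
    """Polyline sampled from a 10th-order Bezier curve between two sensors.

    The 11 control points are the two endpoints plus 9 interior points
    interpolated linearly between them and displaced perpendicular to the
    segment by a fixed sinusoidal arch (peak height 0.25 of the segment
    length).  The perpendicular sign is normalized so the same two points
    give the same curve regardless of argument order; endpoints are exact.
    ``steps`` is the segment count: the polyline has ``steps + 1`` points.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    p0 = np.asarray(p_start, dtype=float)
    p1 = np.asarray(p_end, dtype=float)
    seg = p1 - p0
    length = np.linalg.norm(seg)
    if length < 1e-12:
        normal = np.zeros(2)
    else:
        normal = np.array([-seg[1], seg[0]]) / length
        # orientation-independent sign: arch toward +y (or +x when flat)
        if normal[1] < 0 or (normal[1] == 0 and normal[0] < 0):
            normal = -normal
    ts = np.linspace(0.0, 1.0, BEZIER_ORDER + 1)
    ctrl = p0[None, :] + ts[:, None] * seg[None, :]
    arch = 0.25 * length * np.sin(np.pi * ts)
    ctrl = ctrl + arch[:, None] * normal[None, :]
    ctrl[0], ctrl[-1] = p0, p1

    t = np.linspace(0.0, 1.0, steps + 1)
    bern = np.stack(
        [
            comb(BEZIER_ORDER, k) * t**k * (1 - t) ** (BEZIER_ORDER - k)
            for k in range(BEZIER_ORDER + 1)
        ]
    )  # (order+1, steps+1)
    poly = bern.T @ ctrl
    poly[0], poly[-1] = p0, p1  # exact endpoints despite rounding
    return poly


def link_width(value: float, w_min: float = 0.5, w_scale: float = 1.5) -> float:
    """Line width for a link: linear and strictly increasing in |value|."""
    return w_min + w_scale * abs(value)


def _head_layout(e1: EpochArray, e2: EpochArray) -> tuple[np.ndarray, np.ndarray]:
    for e in (e1, e2):
        if not e.has_positions:
            raise ValueError(
                "container is position-free; provide 3-D sensor positions to render"
            )
    xy1 = _project_azimuthal(e1.positions_array())
    xy2 = _project_azimuthal(e2.positions_array())

    def norm(xy):
        scale = np.abs(xy).max() or 1.0
        return xy / scale

    xy1, xy2 = norm(xy1), norm(xy2)
    xy1 = xy1 + np.array([-HEAD_GAP / 2, 0.0])
    xy2 = xy2 + np.array([HEAD_GAP / 2, 0.0])
    return xy1, xy2


def _draw_head(ax, center_x: float) -> None:
    theta = np.linspace(0, 2 * np.pi, 181)
    ax.plot(center_x + 1.15 * np.cos(theta), 1.15 * np.sin(theta), color="k", lw=1.0)
    ax.plot(
        [center_x - 0.12, center_x, center_x + 0.12],
        [1.14, 1.3, 1.14],
        color="k",
        lw=1.0,
    )


def _draw_sensors(ax, xy: np.ndarray, e: EpochArray, labels: bool) -> None:
    bad_idx = [i for i, ch in enumerate(e.ch_names) if ch in e.bads]
    good_idx = [i for i in range(e.n_channels) if i not in bad_idx]
    ax.scatter(xy[good_idx, 0], xy[good_idx, 1], s=12, c="k", marker="o", zorder=3)
    if bad_idx:
        ax.scatter(xy[bad_idx, 0], xy[bad_idx, 1], s=30, c="k", marker="x", zorder=3)
    if labels:
        for i, ch in enumerate(e.ch_names):
            ax.annotate(ch, xy[i], fontsize=6, textcoords="offset points", xytext=(2, 2))


def render_2d_inter(
    e1: EpochArray,
    e2: EpochArray,
    inter: np.ndarray,
    threshold: float = 2.0,
    steps: int = 10,
    labels: bool = False,
    mode: str = "signed",
) -> plt.Figure:
    """Two head outlines with suprathreshold inter-brain links between them.

    Positive link values use the sequential Reds colormap, negative Blues;
    width grows linearly with |value|.  Link artists carry ``gid='link'``
    so callers can count rendered links on the figure object.
    """
    links = extract_links(inter, threshold, mode=mode)
    xy1, xy2 = _head_layout(e1, e2)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.set_aspect("equal")
    ax.axis("off")
    _draw_head(ax, -HEAD_GAP / 2)
    _draw_head(ax, HEAD_GAP / 2)
    _draw_sensors(ax, xy1, e1, labels)
    _draw_sensors(ax, xy2, e2, labels)
    vmax = max((abs(v) for _, _, v in links.links), default=1.0) or 1.0
    for i, j, v in links.links:
        poly = bezier_link(xy1[i], xy2[j], steps=steps)
        cmap = matplotlib.colormaps["Reds"] if v >= 0 else matplotlib.colormaps["Blues"]
        color = cmap(0.35 + 0.6 * abs(v) / vmax)
        ax.plot(
            poly[:, 0],
            poly[:, 1],
            color=color,
            lw=link_width(v),
            gid="link",
            zorder=2,
        )
    ax.set_xlim(-HEAD_GAP / 2 - 1.5, HEAD_GAP / 2 + 1.5)
    ax.set_ylim(-1.6, 1.6)
    return fig


def count_links(fig: plt.Figure) -> int:
    """Number of link paths on a figure produced by :func:`render_2d_inter`."""
    return sum(
        1 for ax in fig.axes for line in ax.lines if line.get_gid() == "link"
    )


def render_3d_inter(
    e1: EpochArray,
    e2: EpochArray,
    inter: np.ndarray,
    threshold: float = 2.0,
    mode: str = "signed",
) -> plt.Figure:
    """Flat 3-D sensor-cloud rendering with straight inter-brain links."""
    for e in (e1, e2):
        if not e.has_positions:
            raise ValueError("container is position-free; cannot render in 3-D")
    links = extract_links(inter, threshold, mode=mode)
    p1 = e1.positions_array() + np.array([-0.15, 0.0, 0.0])
    p2 = e2.positions_array() + np.array([0.15, 0.0, 0.0])
    fig = plt.figure(figsize=(8, 5))
    ax = fig.add_subplot(projection="3d")
    for pts, e in ((p1, e1), (p2, e2)):
        bad = np.array([ch in e.bads for ch in e.ch_names])
        ax.scatter(*pts[~bad].T, c="k", marker="o", s=10)
        if bad.any():
            ax.scatter(*pts[bad].T, c="k", marker="x", s=25)
    vmax = max((abs(v) for _, _, v in links.links), default=1.0) or 1.0
    for i, j, v in links.links:
        cmap = matplotlib.colormaps["Reds"] if v >= 0 else matplotlib.colormaps["Blues"]
        seg = np.stack([p1[i], p2[j]])
        ax.plot(*seg.T, color=cmap(0.35 + 0.6 * abs(v) / vmax), lw=link_width(v), gid="link")
    ax.set_axis_off()
    return fig


def plot_significant_sensors(values: np.ndarray, e: EpochArray) -> plt.Figure:
    """Scalp map of per-channel statistic values; zero-masked channels greyed.

    ``values`` (length = channel count) typically holds t statistics masked
    to significant channels (zeros elsewhere); nonzero channels are drawn
    colored on a diverging map symmetric about 0, zero channels as small
    grey points.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) != e.n_channels:
        raise ValueError(
            f"{len(values)} values for {e.n_channels} channels"
        )
    if not e.has_positions:
        raise ValueError("container is position-free; cannot plot a scalp map")
    xy = _project_azimuthal(e.positions_array())
    scale = np.abs(xy).max() or 1.0
    xy = xy / scale
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.set_aspect("equal")
    ax.axis("off")
    _draw_head(ax, 0.0)
    nz = values != 0
    ax.scatter(xy[~nz, 0], xy[~nz, 1], s=8, c="0.7", marker="o", zorder=2)
    if nz.any():
        vmax = np.abs(values).max()
        sc = ax.scatter(
            xy[nz, 0],
            xy[nz, 1],
            s=60,
            c=values[nz],
            cmap="RdBu_r",
            vmin=-vmax,
            vmax=vmax,
            marker="o",
            zorder=3,
            gid="significant",
        )
        fig.colorbar(sc, ax=ax, shrink=0.7)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.6)
    return fig
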