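"""Rendering of networks and treatment animations.

Frames are drawn on the generator's own (x, y) embedding: nidus columns at
integer x, AF terminals at x = 0, DV terminals at x = K + 1, extranidal
vessels fanning out on either side.  Filled vessels are drawn in blue over
the gray network; one PNG per frame, optionally stitched to an animated GIF
(or MP4 where an ffmpeg backend is available).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection

from .errors import ParameterError
from .metrics import Frame
from .network import VesselNetwork


def _segments(network: VesselNetwork):
    nodes = network.nodes
    return {v.id: ((nodes[v.tail].x, nodes[v.tail].y),
                   (nodes[v.head].x, nodes[v.head].y))
            for v in network.vessels.values()}


def render_frame(network: VesselNetwork, frame: Frame, path,
                 title: str | None = None) -> None:
    segs = _segments(network)
    base = [s for vid, s in segs.items() if vid not in frame.filled]
    filled = [segs[vid] for vid in frame.filled if vid in segs]
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.add_collection(LineCollection(base, colors="0.75", linewidths=0.5))
    if filled:
        ax.add_collection(
            LineCollection(filled, colors="tab:blue", linewidths=1.2))
    ax.autoscale()
    ax.set_axis_off()
    label = title or (f"{frame.phase}  "
                      f"{frame.injection_mmhg:.0f} mmHg"
                      if frame.phase == "ingress" else "exit")
    ax.set_title(label, fontsize=10)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def render_animation(network: VesselNetwork, frames: Sequence[Frame],
                     out_dir, stitch: bool = False,
                     fps: int = 4) -> list[str]:
    """Write one PNG per frame (and optionally a stitched animation).

    Returns the written file paths.  An empty frame list is a parameter
    error.
    """
    if not frames:
        raise ParameterError("no frames to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:04d}.png"
        render_frame(network, frame, p)
        paths.append(str(p))
    if stitch:
        import imageio.v3 as iio
        images = [iio.imread(p) for p in paths]
        h = min(im.shape[0] for im in images)
        w = min(im.shape[1] for im in images)
        images = [im[:h, :w] for im in images]
        movie = out / "animation.gif"
        iio.imwrite(movie, images, duration=1000 / fps, loop=0)
        paths.append(str(movie))
    return paths
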