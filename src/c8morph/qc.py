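"""Quality-control overlays: slice, cluster anchors, thickness profile."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .image_io import WMSliceMap


def plot_slice_qc(slc: WMSliceMap, slice_result, path) -> None:
    """Overlay of the WM probability slice with median-line anchors and profile."""
    fig, (ax, axp) = plt.subplots(1, 2, figsize=(10, 4),
                                  gridspec_kw={"width_ratios": [3, 2]})
    extent = [slc.y_axis[0], slc.y_axis[-1], slc.z_axis[0], slc.z_axis[-1]]
    ax.imshow(slc.data.T, origin="lower", extent=extent, cmap="gray", vmin=0, vmax=1)
    anchors = np.asarray(slice_result.anchors_mm)
    ax.plot(anchors[:, 0], anchors[:, 1], "r.-", ms=3, lw=0.8, label="median line")
    ax.set_xlabel("y (mm, anterior →)")
    ax.set_ylabel("z (mm, superior →)")
    ax.set_title(f"x = {slice_result.x_offset_mm:+.0f} mm")
    ax.invert_xaxis()  # radiological convention: anterior left
    ax.legend(loc="lower right", fontsize=8)
    axp.plot(slice_result.profile_mm, "b-")
    axp.set_xlabel("anchor (anterior → posterior)")
    axp.set_ylabel("thickness (mm)")
    axp.set_title("minimum traversal thickness")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
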