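"""Mask-overlay utility for qualitative inspection of slice predictions."""

from __future__ import annotations

import numpy as np


def overlay_mask(image: np.ndarray, mask: np.ndarray,
                 reference: np.ndarray | None = None, path=None, ax=None):
    """Show a grayscale slice with the predicted mask filled and, if given,
    the reference mask as a contour. Saves to `path` if provided."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray", interpolation="nearest")
    shown = np.ma.masked_where(mask == 0, mask)
    ax.imshow(shown, cmap="autumn", alpha=0.4, interpolation="nearest")
    if reference is not None:
        ax.contour(reference, levels=[0.5], colors="red", linewidths=1.0)
    ax.set_axis_off()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(ax.figure)
    return ax
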