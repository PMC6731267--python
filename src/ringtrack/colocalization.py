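"""Per-nucleus pixelwise colocalization of two channels.

The co-occurrence of gamma-H2AX and 53BP1 signal is summarised as the
Pearson product-moment correlation between the two intensities over the
member pixels of each nucleus, on raw intensities without background
subtraction.  The coefficient is undefined (NaN, flagged rather than an
error) when either channel is constant within the nucleus or when the
nucleus has fewer than 10 pixels.
"""

from __future__ import annotations

import numpy as np

from .model import ChannelImage, ColocalizationResult, FormatError

__all__ = ["pixel_correlation"]


def pixel_correlation(
    chan_a: ChannelImage | np.ndarray,
    chan_b: ChannelImage | np.ndarray,
    nucleus_mask: np.ndarray,
    nucleus_id: int = 0,
) -> ColocalizationResult:
    """Pearson correlation of two channels over one nucleus's pixels."""
    a = (chan_a.pixels if isinstance(chan_a, ChannelImage) else np.asarray(chan_a)).astype(
        np.float64
    )
    b = (chan_b.pixels if isinstance(chan_b, ChannelImage) else np.asarray(chan_b)).astype(
        np.float64
    )
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if a.shape != b.shape or a.shape != nucleus_mask.shape:
        raise FormatError("channels and nucleus mask must be pixel-aligned")
    x = a[nucleus_mask]
    y = b[nucleus_mask]
    n = int(x.size)
    if n < 10 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return ColocalizationResult(nucleus_id=nucleus_id, pearson_r=float("nan"), n_pixels=n)
    r = float(np.corrcoef(x, y)[0, 1])
    return ColocalizationResult(nucleus_id=nucleus_id, pearson_r=r, n_pixels=n)
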