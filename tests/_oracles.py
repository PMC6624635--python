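"""Independent reference implementations used to cross-check the package."""

import numpy as np
from scipy import ndimage as ndi


def brute_force_threshold(image: np.ndarray, n_levels: int = 256) -> float:
    """Exhaustive gradient-maximization threshold search.

    Written independently of the package: its own Sobel magnitude
    (scipy, proportional to the package's normalized operator, which
    leaves the argmax unchanged) and its own padded-shift neighbor
    logic for the boundary pixels.  Ties keep the lower threshold.
    """
    gr = ndi.sobel(image, axis=0, mode="reflect")
    gc = ndi.sobel(image, axis=1, mode="reflect")
    grad = np.hypot(gr / 4.0, gc / 4.0)
    lo, hi = float(image.min()), float(image.max())
    best_t, best_score = None, -np.inf
    for t in np.linspace(lo, hi, n_levels):
        high = image >= t
        hp = np.pad(high, 1, mode="edge")
        boundary = np.zeros_like(high)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                shifted = hp[1 + dr : hp.shape[0] - 1 + dr, 1 + dc : hp.shape[1] - 1 + dc]
                boundary |= shifted != high
        if not boundary.any():
            continue
        score = grad[boundary].mean()
        if score > best_score:
            best_score, best_t = score, float(t)
    return best_t
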