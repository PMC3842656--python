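"""Literal per-pixel reference implementations used as independent oracles.

Everything here is deliberately written as plain double loops over pixel
coordinates, mirroring the mathematical definitions one-to-one, and shares
no code with the package implementation it checks.
"""

import numpy as np


def disc_offsets(size):
    r = (size - 1) // 2
    return [(dm, dn) for dm in range(-r, r + 1) for dn in range(-r, r + 1)
            if dm * dm + dn * dn <= r * r]


def oracle_open(img, size, order="as-printed"):
    """Grey-scale max-then-min (or min-then-max) over the disc, shrinking window."""
    m, n = img.shape
    offs = disc_offsets(size)

    def sweep(src, fn):
        out = np.empty_like(src, dtype=float)
        for i in range(m):
            for j in range(n):
                vals = [src[i + dm, j + dn] for dm, dn in offs
                        if 0 <= i + dm < m and 0 <= j + dn < n]
                out[i, j] = fn(vals)
        return out

    if order == "as-printed":
        return sweep(sweep(img, max), min)
    return sweep(sweep(img, min), max)


def oracle_mean(norm, size, direction):
    """Mean over the forward (+1..+size) or backward (-size..-1) square window."""
    m, n = norm.shape
    rng_off = range(1, size + 1) if direction == "fwd" else range(-size, 0)
    out = np.zeros_like(norm, dtype=float)
    for i in range(m):
        for j in range(n):
            vals = [norm[i + dm, j + dn] for dm in rng_off for dn in rng_off
                    if 0 <= i + dm < m and 0 <= j + dn < n]
            out[i, j] = np.mean(vals) if vals else 0.0
    return out


def oracle_norm(img):
    lo, hi = img.min(), img.max()
    return np.zeros_like(img, dtype=float) if hi == lo else (img - lo) / (hi - lo)


def oracle_cond_erosion(binary, grey, p_we, p_mn, size):
    m, n = binary.shape
    s_re = oracle_mean(oracle_norm(grey), size, "fwd")
    offs = disc_offsets(size)
    out = np.empty_like(binary)
    for i in range(m):
        for j in range(n):
            if (1 - p_we) * p_mn <= s_re[i, j]:
                out[i, j] = binary[i, j]
            else:
                out[i, j] = min(binary[i + dm, j + dn] for dm, dn in offs
                                if 0 <= i + dm < m and 0 <= j + dn < n)
    return out


def oracle_cond_dilation(binary, grey, p_wd, p_mn, size):
    m, n = binary.shape
    s_rd = oracle_mean(oracle_norm(grey), size, "bwd")
    offs = disc_offsets(size)
    out = np.empty_like(binary)
    for i in range(m):
        for j in range(n):
            if (p_wd + 1) * p_mn >= s_rd[i, j]:
                out[i, j] = binary[i, j]
            else:
                out[i, j] = max(binary[i - dm, j - dn] for dm, dn in offs
                                if 0 <= i - dm < m and 0 <= j - dn < n)
    return out
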