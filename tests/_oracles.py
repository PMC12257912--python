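"""Independent scalar-loop oracles shared by the decoder and acceptance tests."""

import numpy as np

from cret.decoder import positional_encode


def literal_cret(sq, zst, roi, g):
    """Naive scalar loop over pixels and views, written from the geometry
    conventions independently of the vectorized plan."""
    H = W = roi.out_resolution
    spacing = roi.patch_extent / roi.out_resolution
    out = np.zeros((H, W))
    dbeta = g.angular_range / g.n_views
    n = zst.basis.n
    for r in range(H):
        for c in range(W):
            x = roi.center[0] - (W - 1) / 2.0 * spacing + c * spacing
            y = roi.center[1] + (H - 1) / 2.0 * spacing - r * spacing
            total = 0.0
            for v, beta in enumerate(g.view_angles):
                sx = -g.source_to_iso * np.sin(beta)
                sy = g.source_to_iso * np.cos(beta)
                vx, vy = x - sx, y - sy
                tw = vx * np.sin(beta) - vy * np.cos(beta)
                tu = vx * np.cos(beta) + vy * np.sin(beta)
                u = g.source_to_det * tu / tw
                k = u / g.det_pitch + (g.n_detectors - 1) / 2.0
                i0 = int(np.floor(k))
                if i0 < 0 or i0 + 1 > g.n_detectors - 1:
                    continue
                col0 = i0 - sq.window_start[v]
                frac = k - i0
                L2 = vx * vx + vy * vy
                z0, z1 = sq.z[v, col0], sq.z[v, col0 + 1]
                f0 = float(zst.data[v, col0] @ positional_encode(frac, n))
                f1 = float(zst.data[v, col0 + 1] @ positional_encode(frac - 1.0, n))
                val = (1 - frac) * (z0 + f0) + frac * (z1 + f1)
                total += 0.5 * dbeta * g.source_to_iso**2 / L2 * val
            out[r, c] = total
    return out
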