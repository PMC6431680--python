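"""Adhesion spatial statistics: E-function slope and G-function mean.

The E-slope (1/µm) is the origin-constrained fit to the cumulative
distribution of adhesion-to-nucleus distances — high when adhesions crowd
the nucleus. The cell G-function (µm) is the mean nearest-neighbor
distance between adhesions — low when adhesions are clustered.
"""

import numpy as np

from famet import cell_g, e_function, e_slope, g_function

rng = np.random.default_rng(0)

# body-wide pattern: 30 adhesions spread uniformly over a 30 µm disk
r = 15 * np.sqrt(rng.uniform(0, 1, 30))
phi = rng.uniform(0, 2 * np.pi, 30)
spread = np.column_stack([r * np.cos(phi), r * np.sin(phi)])

# perinuclear pattern: 30 adhesions clustered 3 µm around the nucleus
clustered = rng.normal(0, 3, (30, 2))

for name, pts in [("body-wide", spread), ("perinuclear", clustered)]:
    e = e_function(pts, (0.0, 0.0))
    print(
        f"{name:12s} E-slope {e_slope(e):.3f} 1/µm, "
        f"G-function {cell_g(g_function(pts)):.2f} µm"
    )

# The clustered pattern has the steeper E-slope (adhesions near the
# nucleus) and the smaller G-function (tighter nearest neighbors) — the
# signature of cells confined on woven microfiber substrates.
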