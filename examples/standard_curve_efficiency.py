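"""Amplification efficiency from a cDNA dilution series.

Fits Cq against log10(input amount) by least squares.  With perfect
doubling chemistry the slope is -1/log10(2) = -3.3219 cycles per decade
(100% efficiency); a shallower slope means lower per-cycle gain.
"""

import numpy as np

from refstab import standard_curve_efficiency

# five-point 10-fold dilution series, slightly noisy around slope -3.45
rng = np.random.default_rng(4)
points = [(x, 33.0 - 3.45 * x + rng.normal(0, 0.05)) for x in range(5)]
rec = standard_curve_efficiency(points, gene="EF1A")

print(f"gene             : {rec.gene}")
print(f"slope            : {rec.slope:.4f} cycles per log10(input)")
print(f"efficiency       : {rec.efficiency_pct:.2f} %")
print(f"R^2              : {rec.r_squared:.4f}")
print(f"amplification A  : {rec.amplification_factor:.4f}x per cycle")
# Efficiencies between ~90 and ~110% with R^2 > 0.99 are the usual
# acceptance window for a qPCR assay; the fitted A feeds directly into
# relative_quantities(..., efficiencies=...) instead of the naive A = 2.
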