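"""Physical constants and unit conversions used across the package.

All public interfaces take lengths in millimetres, currents in amperes and
report magnetic flux density in tesla; conversions to SI happen at the edge
of each numerical routine.
"""

import math

#: Vacuum permeability, H/m.
MU_0 = 4.0e-7 * math.pi

#: Copper resistivity at room temperature, ohm-metre.
RHO_COPPER = 1.68e-8

#: Millimetres per inch (the flat-spiral inductance formula wants inches).
MM_PER_INCH = 25.4

#: Geometric-mean-distance factor turning a rectangular w x h conductor
#: cross-section into an equivalent round-filament radius: r = 0.2235 (w + h).
GMD_FACTOR = 0.2235

MM_TO_M = 1e-3
UM_TO_MM = 1e-3
H_TO_UH = 1e6
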