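"""Physical constants used across the field, loss-power and thermal stages."""

import math

#: Vacuum permeability, H/m.
MU0 = 4.0e-7 * math.pi

#: Boltzmann constant, J/K.
K_B = 1.380649e-23
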