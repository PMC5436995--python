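"""Physical constants and unit conversions used throughout the package.

Internal unit conventions:

* time: hours (minutes only at the I/O boundary),
* activity: MBq,
* organ mass: grams,
* absorbed dose: mGy/MBq administered,
* S values: mGy/(MBq.h).
"""

import math

MIN_PER_H = 60.0

MEV_TO_J = 1.602176634e-13

#: decays per MBq.h of cumulated activity
DECAYS_PER_MBQ_H = 1.0e6 * 3600.0

#: S [mGy/(MBq.h)] = energy-per-decay [MeV] * MEV_PER_DECAY_TO_MGY / mass [g]
MEV_PER_DECAY_TO_MGY = MEV_TO_J * DECAYS_PER_MBQ_H * 1.0e6

LN2 = math.log(2.0)

#: density of soft tissue / water used by the unit-density sphere model, g/cm^3
UNIT_DENSITY = 1.0
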