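"""Core-biopsy needle geometry.

A core needle is modelled by its outer diameter, the spring throw (forward
advance on firing; zero for a manual push-pull device), the specimen-notch
length, and ``tip_to_notch_center_mm`` — how far behind the final tip
position the centre of the captured core sits.  The guide-length calibration
aims that point at the ROI centre of mass under the fixed insertion depth.

Presets cover the two devices used for ex vivo prostate sampling: a manual
14 G Tru-Cut style needle (tip-targeted, ``tip_to_notch_center=0``) and a
spring-fired 18 G device whose fired notch centres ~13 mm behind the tip.
Hole sizing derives from the outer diameter plus per-side clearance, so both
are configurable rather than hard-coded.
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class NeedleModel:
    gauge_label: str
    outer_diameter_mm: float
    throw_mm: float
    notch_length_mm: float
    tip_to_notch_center_mm: float

    def __post_init__(self):
        if self.outer_diameter_mm <= 0 or self.notch_length_mm <= 0:
            raise ValueError("needle dimensions must be positive")
        if self.throw_mm < 0 or self.tip_to_notch_center_mm < 0:
            raise ValueError("throw and tip-to-notch distances must be >= 0")
        if self.tip_to_notch_center_mm > self.throw_mm + self.notch_length_mm:
            raise ValueError(
                "tip_to_notch_center_mm cannot exceed throw + notch length")


#: Manual 14-gauge Tru-Cut style needle; targeting is referenced to the tip.
TRUCUT_14G = NeedleModel(
    gauge_label="14G manual",
    outer_diameter_mm=2.11,
    throw_mm=0.0,
    notch_length_mm=20.0,
    tip_to_notch_center_mm=0.0,
)

#: Spring-loaded 18-gauge core needle; the fired notch centres behind the tip.
BARD_18G = NeedleModel(
    gauge_label="18G spring-loaded",
    outer_diameter_mm=1.27,
    throw_mm=22.0,
    notch_length_mm=18.0,
    tip_to_notch_center_mm=13.0,
)

PRESETS = {"trucut14": TRUCUT_14G, "bard18": BARD_18G}
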