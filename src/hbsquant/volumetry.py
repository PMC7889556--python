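"""Liver volumetry: standardized volumes, ratios, hypertrophy increase.

Standardized total liver volume (sTLV) is estimated from body surface
area by the Vauthey formula; the measured total liver volume (mTLV)
subtracts the tumor volume from the CT-measured liver volume.  The
future liver remnant is expressed as a share of sTLV or mTLV, or per
kilogram of body weight assuming a liver density of 1.00 g/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "Volumetrics",
    "stlv_vauthey",
    "flr_share",
    "flr_mtlv",
    "flr_bw",
    "mtlv",
    "compute_increase",
    "adequacy_check",
]

#: Minimum adequate FLR/sTLV (%) by clinical context.
ADEQUACY_STLV_THRESHOLD = {"healthy": 25.0, "donor": 30.0, "diseased": 30.0}
ADEQUACY_BW_THRESHOLD = 0.5  # FLR/BW %, all contexts


def stlv_vauthey(bsa: float) -> float:
    """Standardized total liver volume (mL) from BSA (m2), Vauthey formula.

    ``sTLV = -794.41 + 1267.28 * BSA``.  BSA below ~0.627 m2 yields a
    non-positive volume and is outside the model's range.
    """
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    value = -794.41 + 1267.28 * bsa
    if value <= 0:
        raise ValueError(
            f"BSA {bsa} m2 is below the formula's valid range (sTLV would be {value:.1f} mL)"
        )
    return value


def flr_share(flr_vol: float, stlv: float) -> float:
    """FLR as a percentage of standardized total liver volume."""
    if stlv <= 0:
        raise ValueError("sTLV must be positive")
    if flr_vol < 0:
        raise ValueError("FLR volume must be nonnegative")
    return 100.0 * flr_vol / stlv


def flr_mtlv(flr_vol: float, mtlv_ml: float) -> float:
    """FLR as a percentage of measured (tumor-subtracted) liver volume."""
    if mtlv_ml <= 0:
        raise ValueError("mTLV must be positive")
    if flr_vol < 0:
        raise ValueError("FLR volume must be nonnegative")
    return 100.0 * flr_vol / mtlv_ml


def flr_bw(flr_vol: float, bw: float, density: float = 1.00) -> float:
    """FLR weight as a percentage of body weight.

    FLR volume (mL) is converted to grams at the given liver density
    (default 1.00 g/mL): ``100 * flr_vol * density / (bw * 1000)``.
    """
    if bw <= 0:
        raise ValueError("body weight must be positive")
    if flr_vol < 0:
        raise ValueError("FLR volume must be nonnegative")
    return 100.0 * flr_vol * density / (bw * 1000.0)


def mtlv(tlv: float, tumor_vol: float) -> float:
    """Measured total liver volume: CT liver volume minus tumor volume."""
    if tumor_vol < 0 or tlv < 0:
        raise ValueError("volumes must be nonnegative")
    if tumor_vol > tlv:
        raise ValueError("tumor volume exceeds total liver volume")
    value = tlv - tumor_vol
    if value == 0:
        warnings.warn("mTLV is zero (tumor occupies the whole liver volume)", stacklevel=2)
    return value


def compute_increase(pre_value: float, post_value: float) -> float:
    """Percentage increase from a pre- to a post-hypertrophy value."""
    if pre_value <= 0:
        raise ValueError("pre-hypertrophy value must be positive")
    return 100.0 * (post_value - pre_value) / pre_value


@dataclass(frozen=True)
class Volumetrics:
    """Raw and derived volumetric quantities for one patient."""

    flr_vol: float
    tlv: float
    tumor_vol: float
    bw: float
    bsa: float
    stlv: float
    mtlv: float
    flr_stlv: float
    flr_bw: float
    flr_mtlv: float

    @classmethod
    def from_raw(
        cls,
        flr_vol: float,
        tlv: float,
        tumor_vol: float,
        bw: float,
        bsa: float,
        density: float = 1.00,
    ) -> "Volumetrics":
        stlv = stlv_vauthey(bsa)
        mtlv_ml = mtlv(tlv, tumor_vol)
        return cls(
            flr_vol=flr_vol,
            tlv=tlv,
            tumor_vol=tumor_vol,
            bw=bw,
            bsa=bsa,
            stlv=stlv,
            mtlv=mtlv_ml,
            flr_stlv=flr_share(flr_vol, stlv),
            flr_bw=flr_bw(flr_vol, bw, density=density),
            flr_mtlv=flr_mtlv(flr_vol, mtlv_ml) if mtlv_ml > 0 else float("nan"),
        )


def adequacy_check(vol: Volumetrics, context: str = "healthy") -> tuple[bool, str]:
    """Decide whether the FLR is volumetrically adequate for resection.

    In healthy livers FLR/sTLV >= 25 % or FLR/BW >= 0.5 % is adequate;
    living donors and diseased livers (cholestasis, cirrhosis,
    prolonged chemotherapy) require FLR/sTLV >= 30 % (the FLR/BW rule
    is kept unchanged).  Thresholds are inclusive.  Returns the verdict
    and the rule that fired (``"flr_stlv"``, ``"flr_bw"`` or
    ``"none"``).
    """
    if context not in ADEQUACY_STLV_THRESHOLD:
        raise ValueError(f"unknown context {context!r}; expected one of "
                         f"{sorted(ADEQUACY_STLV_THRESHOLD)}")
    if vol.flr_stlv >= ADEQUACY_STLV_THRESHOLD[context]:
        return True, "flr_stlv"
    if vol.flr_bw >= ADEQUACY_BW_THRESHOLD:
        return True, "flr_bw"
    return False, "none"
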