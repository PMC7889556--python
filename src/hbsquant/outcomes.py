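"""Postoperative outcome grading: ISGLS PHLF, 50-50 criteria, morbidity.

Post-hepatectomy liver failure (PHLF) per the International Study
Group of Liver Surgery (ISGLS) is an increased INR together with
hyperbilirubinemia on or after postoperative day 5, graded by the
change of clinical management it requires: grade A needs none, grade
B a noninvasive deviation from the normal course, grade C invasive
treatment.  The 50-50 criteria define liver failure as prothrombin
time < 50 % of normal together with serum bilirubin > 50 umol/L on
day 5 exactly.  Laboratory normal ranges are institution-specific and
therefore configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PostopCourse",
    "isgls_grade",
    "fifty_fifty",
    "major_morbidity",
    "hbs_eligibility",
    "MGDL_TO_UMOL",
]

#: Bilirubin conversion factor, mg/dL to umol/L.
MGDL_TO_UMOL = 17.104

#: Default upper normal limits (configurable, institution-specific).
INR_UPPER_NORMAL = 1.2
BILIRUBIN_UPPER_NORMAL_UMOL = 20.5

_DINDO_RANK = {
    "1": 1, "2": 2, "3a": 3, "3b": 4, "4a": 5, "4b": 6, "5": 7,
}


@dataclass(frozen=True)
class PostopCourse:
    """Per-postoperative-day laboratory series and management flags.

    Bilirubin is stored in umol/L; use :meth:`from_mg_dl` values via
    the ``bilirubin_mg_dl`` argument to convert on ingest.  ``pt_pct``
    is the prothrombin time as percent of normal.
    """

    pods: np.ndarray
    bilirubin_umol_l: np.ndarray
    inr: np.ndarray
    pt_pct: np.ndarray | None = None
    any_deviation_noninvasive: bool = False
    invasive_procedure: bool = False
    complications: tuple[str, ...] = field(default_factory=tuple)
    preop_bilirubin_mg_dl: float | None = None

    def __post_init__(self) -> None:
        pods = np.asarray(self.pods, dtype=int)
        bili = np.asarray(self.bilirubin_umol_l, dtype=float)
        inr = np.asarray(self.inr, dtype=float)
        if pods.ndim != 1 or len(set(pods.tolist())) != len(pods):
            raise ValueError("PODs must be a 1-D sequence of unique day indices")
        if np.any(pods < 1):
            raise ValueError("POD indices start at 1")
        if bili.shape != pods.shape or inr.shape != pods.shape:
            raise ValueError("lab series must match the POD sequence in length")
        pt = self.pt_pct
        if pt is not None:
            pt = np.asarray(pt, dtype=float)
            if pt.shape != pods.shape:
                raise ValueError("PT series must match the POD sequence in length")
            if np.any((pt <= 0) | (pt > 150)):
                raise ValueError("PT (% of normal) must lie in (0, 150]")
        object.__setattr__(self, "pods", pods)
        object.__setattr__(self, "bilirubin_umol_l", bili)
        object.__setattr__(self, "inr", inr)
        object.__setattr__(self, "pt_pct", pt)

    @classmethod
    def single_day(
        cls,
        pod: int,
        bilirubin_umol_l: float | None = None,
        bilirubin_mg_dl: float | None = None,
        inr: float = 1.0,
        pt_pct: float | None = None,
        **flags,
    ) -> "PostopCourse":
        if bilirubin_umol_l is None:
            if bilirubin_mg_dl is None:
                raise ValueError("provide bilirubin in umol/L or mg/dL")
            bilirubin_umol_l = bilirubin_mg_dl * MGDL_TO_UMOL
        return cls(
            pods=np.asarray([pod]),
            bilirubin_umol_l=np.asarray([bilirubin_umol_l]),
            inr=np.asarray([inr]),
            pt_pct=None if pt_pct is None else np.asarray([pt_pct]),
            **flags,
        )


def isgls_grade(
    course: PostopCourse,
    inr_limit: float = INR_UPPER_NORMAL,
    bilirubin_limit_umol: float = BILIRUBIN_UPPER_NORMAL_UMOL,
) -> str:
    """ISGLS PHLF grade: ``"none"``, ``"A"``, ``"B"`` or ``"C"``.

    PHLF is present iff INR and bilirubin are simultaneously above
    their upper normal limits on some POD >= 5.  Severity follows the
    management required: invasive procedure -> C, noninvasive
    deviation -> B, otherwise A.

    Raises
    ------
    ValueError
        If no labs on or after POD 5 are available (``"ungradable"``).
    """
    late = course.pods >= 5
    if not late.any():
        raise ValueError("ungradable: no laboratory values on or after POD 5")
    phlf = np.any(
        (course.inr[late] > inr_limit)
        & (course.bilirubin_umol_l[late] > bilirubin_limit_umol)
    )
    if not phlf:
        return "none"
    if course.invasive_procedure:
        return "C"
    if course.any_deviation_noninvasive:
        return "B"
    return "A"


def fifty_fifty(course: PostopCourse) -> bool:
    """50-50 criteria: PT < 50 % and bilirubin > 50 umol/L on POD 5."""
    at5 = course.pods == 5
    if not at5.any():
        raise ValueError("POD 5 laboratory values are required for the 50-50 criteria")
    if course.pt_pct is None:
        raise ValueError("PT (% of normal) is required for the 50-50 criteria")
    pt = float(course.pt_pct[at5][0])
    bili = float(course.bilirubin_umol_l[at5][0])
    return pt < 50.0 and bili > 50.0


def major_morbidity(complication_grades) -> bool:
    """True iff any Dindo-Clavien complication grade is >= 3a."""
    rank_3a = _DINDO_RANK["3a"]
    for g in complication_grades:
        label = str(g).lower()
        if label not in _DINDO_RANK:
            raise ValueError(f"unknown Dindo-Clavien grade {g!r}")
        if _DINDO_RANK[label] >= rank_3a:
            return True
    return False


def hbs_eligibility(preop_bilirubin_mg_dl: float) -> bool:
    """Eligibility for HBS-based function measurement.

    Mebrofenin uptake competes with bilirubin for the hepatocyte
    transporter, so elevated serum bilirubin (>= 2.9 mg/dL) makes the
    study unreliable and excludes the patient.
    """
    if preop_bilirubin_mg_dl < 0:
        raise ValueError("bilirubin must be nonnegative")
    return preop_bilirubin_mg_dl < 2.9
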