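"""Threshold-based CT densitometry and parametric response mapping (PRM).

Lung CT attenuation in Hounsfield Units (HU) falls as parenchyma is
destroyed or gas is trapped.  Two canonical cut-offs quantify this:
voxels below -950 HU on an inspiratory scan mark emphysema (%LAA_-950insp)
and voxels below -856 HU on an expiratory scan mark total gas trapping
(%LAA_-856exp).  Co-registered inspiratory/expiratory pairs refine the
picture per voxel:

=============  ==================  ==================
class          inspiration          expiration
=============  ==================  ==================
Normal         >= -950 HU           >= -856 HU
fLDA           >= -950 HU           <  -856 HU
pLDA           <  -950 HU           <  -856 HU
Other          <  -950 HU           >= -856 HU
=============  ==================  ==================

pLDA (persistent low-density area) is emphysematous destruction; fLDA
(functional low-density area) is non-emphysematous gas trapping from
airway closure.  The fourth combination (low at inspiration only) has no
established name; it is labelled Other, excluded from the three named
percentages but kept in the denominator.  Equality at a threshold is
assigned to the non-low side, preserving complementarity of the rules.

Subjects are staged on %LAA_-950insp: no emphysema (NE) below 6, moderate
(ME) in [6, 14), severe (SE) at or above 14.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, MalformedInputError

INSP_THRESHOLD_HU = -950.0
EXP_THRESHOLD_HU = -856.0

#: integer label codes (also used in exported NIfTI label maps)
LABEL_OUTSIDE = 0
LABEL_NORMAL = 1
LABEL_FLDA = 2
LABEL_PLDA = 3
LABEL_OTHER = 4

LABEL_NAMES = {
    LABEL_OUTSIDE: "OutsideMask",
    LABEL_NORMAL: "Normal",
    LABEL_FLDA: "fLDA",
    LABEL_PLDA: "pLDA",
    LABEL_OTHER: "Other",
}


@dataclass(frozen=True)
class PairedCTStudy:
    """Voxel-aligned inspiratory/expiratory HU grids with a lung mask."""

    insp_hu: np.ndarray
    exp_hu: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        insp = np.asarray(self.insp_hu, dtype=float)
        exp_ = np.asarray(self.exp_hu, dtype=float)
        mask = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "insp_hu", insp)
        object.__setattr__(self, "exp_hu", exp_)
        object.__setattr__(self, "mask", mask)
        if not (insp.shape == exp_.shape == mask.shape):
            raise MalformedInputError("inspiratory, expiratory and mask grids must share a shape")
        if not mask.any():
            raise DomainError("lung mask is empty")
        if not (np.all(np.isfinite(insp[mask])) and np.all(np.isfinite(exp_[mask]))):
            raise MalformedInputError("HU values inside the mask must be finite")


@dataclass(frozen=True)
class PRMSummary:
    """Voxel-class percentages and threshold metrics for one study."""

    pct_normal: float
    pct_flda: float
    pct_plda: float
    pct_other: float
    laa950_insp: float
    laa856_exp: float
    emphysema_class: str

    def as_dict(self) -> dict:
        return {
            "pct_normal": self.pct_normal,
            "pct_flda": self.pct_flda,
            "pct_plda": self.pct_plda,
            "pct_other": self.pct_other,
            "laa950_insp": self.laa950_insp,
            "laa856_exp": self.laa856_exp,
            "emphysema_class": self.emphysema_class,
        }


def laa_fraction(volume_hu: np.ndarray, mask: np.ndarray, threshold_hu: float) -> float:
    """Percent of masked voxels strictly below ``threshold_hu``."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DomainError("lung mask is empty")
    vol = np.asarray(volume_hu, dtype=float)
    if vol.shape != mask.shape:
        raise MalformedInputError("volume and mask shapes differ")
    return float(100.0 * np.count_nonzero(vol[mask] < threshold_hu) / np.count_nonzero(mask))


def prm_classify(study: PairedCTStudy) -> np.ndarray:
    """Per-voxel response-map labels (integer codes, 0 outside the mask)."""
    insp_low = study.insp_hu < INSP_THRESHOLD_HU
    exp_low = study.exp_hu < EXP_THRESHOLD_HU
    labels = np.full(study.mask.shape, LABEL_OUTSIDE, dtype=np.uint8)
    labels[study.mask & ~insp_low & ~exp_low] = LABEL_NORMAL
    labels[study.mask & ~insp_low & exp_low] = LABEL_FLDA
    labels[study.mask & insp_low & exp_low] = LABEL_PLDA
    labels[study.mask & insp_low & ~exp_low] = LABEL_OTHER
    return labels


def emphysema_class(laa950_insp: float) -> str:
    """Stage a subject on %LAA_-950insp: NE (<6), ME ([6, 14)), SE (>=14)."""
    if not 0.0 <= laa950_insp <= 100.0:
        raise DomainError(f"%LAA must lie in [0, 100], got {laa950_insp}")
    if laa950_insp < 6.0:
        return "NE"
    if laa950_insp < 14.0:
        return "ME"
    return "SE"


def prm_summary(labels: np.ndarray, study: PairedCTStudy) -> PRMSummary:
    """Summarise a label map into class percentages and staged metrics."""
    if labels.shape != study.mask.shape:
        raise MalformedInputError("label map and study shapes differ")
    n = np.count_nonzero(study.mask)
    pct = {
        code: 100.0 * np.count_nonzero(labels[study.mask] == code) / n
        for code in (LABEL_NORMAL, LABEL_FLDA, LABEL_PLDA, LABEL_OTHER)
    }
    laa950 = laa_fraction(study.insp_hu, study.mask, INSP_THRESHOLD_HU)
    laa856 = laa_fraction(study.exp_hu, study.mask, EXP_THRESHOLD_HU)
    return PRMSummary(
        pct_normal=pct[LABEL_NORMAL],
        pct_flda=pct[LABEL_FLDA],
        pct_plda=pct[LABEL_PLDA],
        pct_other=pct[LABEL_OTHER],
        laa950_insp=laa950,
        laa856_exp=laa856,
        emphysema_class=emphysema_class(laa950),
    )
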