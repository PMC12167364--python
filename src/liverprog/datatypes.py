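"""Core in-memory containers shared across the pipeline.

The pipeline passes around three kinds of per-patient objects: a
:class:`TriphasicScan` (three co-registered contrast phases plus liver and
tumor masks), a :class:`ClinicalRecord` (baseline covariates), and one
:class:`SurvivalLabel` per endpoint (overall survival, progression-free
survival).  Everything downstream — preprocessing, radiomics, the deep
survival networks, fusion and evaluation — consumes these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "TriphasicScan",
    "SurvivalLabel",
    "ClinicalRecord",
    "PHASES",
    "CHILD_PUGH_CLASSES",
    "BCLC_STAGES",
    "MRECIST_CATEGORIES",
]

#: Contrast phases, in the canonical stacking order.
PHASES = ("A", "V", "D")  # arterial, portal-venous, delayed

CHILD_PUGH_CLASSES = ("A", "B", "C")
BCLC_STAGES = ("A", "B", "C", "D")
MRECIST_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass
class TriphasicScan:
    """Three co-registered 3D HU volumes plus liver/tumor masks.

    Axis order is (z, y, x) with 0-based voxel indices; ``spacing`` is the
    voxel size in millimetres for those axes.  Masks are strictly binary and
    the tumor mask must lie inside the liver mask (up to a one-voxel
    dilation tolerance, checked by :meth:`validate`).
    """

    patient_id: str
    phases: dict  # phase letter -> float ndarray, HU
    spacing: tuple  # (z, y, x) mm
    liver_mask: np.ndarray  # uint8 {0,1}
    tumor_mask: np.ndarray  # uint8 {0,1}
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.affine is None:
            aff = np.eye(4)
            # nibabel convention: world axes ordered (x, y, z)
            aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing[::-1]
            self.affine = aff

    @property
    def shape(self) -> tuple:
        return tuple(self.liver_mask.shape)

    def validate(self) -> None:
        """Raise ``ValueError`` on any geometry/mask inconsistency."""
        from scipy.ndimage import binary_dilation

        shapes = {tuple(v.shape) for v in self.phases.values()}
        shapes |= {tuple(self.liver_mask.shape), tuple(self.tumor_mask.shape)}
        if len(shapes) != 1:
            raise ValueError(f"phases and masks disagree on shape: {shapes}")
        if set(self.phases) != set(PHASES):
            raise ValueError(f"expected phases {PHASES}, got {sorted(self.phases)}")
        for name, m in (("liver", self.liver_mask), ("tumor", self.tumor_mask)):
            vals = np.unique(m)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"{name} mask is not binary: values {vals[:5]}")
        liver_tol = binary_dilation(self.liver_mask.astype(bool))
        if np.any(self.tumor_mask.astype(bool) & ~liver_tol):
            raise ValueError("tumor mask extends outside the (dilated) liver mask")


@dataclass(frozen=True)
class SurvivalLabel:
    """Right-censored outcome: follow-up time in months and event indicator."""

    time: float
    event: int
    endpoint: str = "OS"  # "OS" or "PFS"

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"survival time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0/1, got {self.event}")


# Categorical vocabularies used when validating clinical tables.
_CLINICAL_VOCAB = {
    "sex": ("M", "F"),
    "child_pugh": CHILD_PUGH_CLASSES,
    "bclc": BCLC_STAGES,
    "mrecist": MRECIST_CATEGORIES,
}
_BINARY_FIELDS = (
    "afp_gt_400",
    "hbv",
    "cirrhosis",
    "up_to_seven",
    "pvtt",
    "lung_met",
    "bone_met",
    "lymph_met",
    "prior_local_therapy",
)


@dataclass
class ClinicalRecord:
    """Baseline clinical covariates for one patient.

    Mirrors the covariate groups used for the clinical benchmark and the
    multimodal fusion: demographics, liver function and labs, tumor burden,
    metastasis pattern, and treatment history, plus the first-follow-up
    mRECIST response category.
    """

    patient_id: str
    age: float
    sex: str
    afp_gt_400: int
    hbv: int
    cirrhosis: int
    child_pugh: str
    ecog: int
    bclc: str
    up_to_seven: int
    tumor_size_cm: float
    tumor_number: int
    pvtt: int
    lung_met: int
    bone_met: int
    lymph_met: int
    therapy_line: int
    prior_local_therapy: int
    mrecist: str

    def validate(self) -> None:
        for fname, vocab in _CLINICAL_VOCAB.items():
            val = getattr(self, fname)
            if val not in vocab:
                raise ValueError(
                    f"{self.patient_id}: {fname}={val!r} not in vocabulary {vocab}"
                )
        for fname in _BINARY_FIELDS:
            if getattr(self, fname) not in (0, 1):
                raise ValueError(f"{self.patient_id}: {fname} must be 0/1")
        if not self.tumor_size_cm > 0:
            raise ValueError(f"{self.patient_id}: tumor size must be > 0")
        if self.ecog not in (0, 1, 2, 3, 4):
            raise ValueError(f"{self.patient_id}: ECOG PS must be an integer 0-4")
        if self.tumor_number < 1:
            raise ValueError(f"{self.patient_id}: tumor number must be >= 1")
        if self.therapy_line < 1:
            raise ValueError(f"{self.patient_id}: therapy line must be >= 1")
        # tumor-burden consistency: count + largest diameter (cm) <= 7
        derived = int(self.tumor_number + self.tumor_size_cm <= 7)
        if derived != self.up_to_seven:
            raise ValueError(
                f"{self.patient_id}: up_to_seven flag inconsistent with "
                f"size {self.tumor_size_cm} cm + count {self.tumor_number}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def labels_to_arrays(labels: Sequence[SurvivalLabel]) -> tuple:
    """Return (time, event) float/int arrays from a label sequence."""
    t = np.array([l.time for l in labels], dtype=float)
    e = np.array([l.event for l in labels], dtype=int)
    return t, e
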