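"""Kinetic model linking mean glucose to steady-state HbA1c.

Hemoglobin glycation is modelled as a pseudo-first-order reaction whose
substrate is the intracellular glucose exposure.  Because red-cell glucose
uptake is carrier-mediated, exposure saturates with extracellular glucose
through a Michaelis–Menten transport term with constant ``K_M`` (472 mg/dL).
It is convenient to work with the *apparent glucose* composite

    X(MG) = 1/MG + 1/K_M        [dL/mg]

which is the reciprocal of the harmonic combination of mean glucose MG and
K_M.  At steady state the glycated fraction A1c (NGSP %) satisfies

    A1c = 100 / (1 + 1e5 · X(MG) / AGR)

where AGR (apparent glycation ratio, mL/mg) is a per-person constant that
bundles glycation rate and red-cell lifespan.  Inverting at a calibration
visit gives the person's AGR:

    AGR = 1e5 · X(MG) / (100/A1c − 1)

A later measured A1c is then mapped onto the scale of a *reference glycator*
(AGR = 65.1 mL/mg, the standard red-cell-lifespan glycation rate constant):

    pA1c = 100 / (1 + (AGR/65.1) · (100/A1c − 1))

For the reference glycator pA1c ≡ A1c; for a high glycator (AGR > 65.1) the
measured A1c overstates glycemia and pA1c is revised downward.  The central
algebraic identity is that pA1c computed from any (A1c, AGR(MG, A1c)) pair
depends only on MG and equals the reference-glycator curve evaluated at MG.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlycationConstants",
    "GlycationRecord",
    "DEFAULT_CONSTANTS",
    "apparent_glucose",
    "compute_agr",
    "forward_a1c",
    "compute_pa1c",
    "reference_ea1c",
    "estimate_mg",
    "convert_a1c",
]

#: NGSP ↔ IFCC master equation constants: IFCC = 10.929 · (NGSP − 2.15).
IFCC_SLOPE = 10.929
IFCC_OFFSET = 2.15


@dataclass(frozen=True)
class GlycationConstants:
    """Reference constants of the glycation kinetic model.

    Parameters
    ----------
    k_m : float
        Michaelis constant of red-cell glucose transport, mg/dL.
    agr_ref : float
        Reference (standard red-cell lifespan) glycation rate constant,
        mL/mg.  The personalization transform is the identity map at this
        AGR.
    """

    k_m: float = 472.0
    agr_ref: float = 65.1

    def __post_init__(self) -> None:
        if self.k_m <= 0:
            raise ValueError(f"k_m must be positive, got {self.k_m}")
        if self.agr_ref <= 0:
            raise ValueError(f"agr_ref must be positive, got {self.agr_ref}")


DEFAULT_CONSTANTS = GlycationConstants()


@dataclass
class GlycationRecord:
    """Per-subject calibration and evaluation quantities.

    ``calibration_mg`` is mean glucose pooled over the first two sensor
    wears; ``calibration_a1c`` the laboratory A1c at the end of wear 2 (POC
    A1c is never used for AGR calibration).  ``evaluation_mg`` pools all
    readings through the end of wear 3, against which the visit-3 A1c
    variants and the pA1c are compared.
    """

    subject_id: str
    calibration_mg: float
    calibration_a1c: float
    agr: float
    visit3_a1c_lab: float
    visit3_a1c_poc: float
    pa1c: float
    evaluation_mg: float

    def __post_init__(self) -> None:
        if self.agr <= 0:
            raise ValueError(f"{self.subject_id}: agr must be positive")
        for name in ("calibration_a1c", "visit3_a1c_lab", "visit3_a1c_poc", "pa1c"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{self.subject_id}: {name}={v} outside (0, 100)")
        if self.calibration_mg <= 0 or self.evaluation_mg <= 0:
            raise ValueError(f"{self.subject_id}: mean glucose must be positive")


def _ret(x: np.ndarray) -> "float | np.ndarray":
    """Return a Python float for scalar input, an ndarray otherwise."""
    return float(x) if np.ndim(x) == 0 else x


def apparent_glucose(mg, constants: GlycationConstants = DEFAULT_CONSTANTS):
    """Apparent-glucose composite X(MG) = 1/MG + 1/K_M, in dL/mg.

    Decreasing in MG, with asymptote 1/K_M as MG → ∞.
    """
    mg = np.asarray(mg, dtype=float)
    if np.any(mg <= 0):
        raise ValueError("mean glucose must be positive (mg/dL)")
    return _ret(1.0 / mg + 1.0 / constants.k_m)


def compute_agr(mg, a1c, constants: GlycationConstants = DEFAULT_CONSTANTS):
    """Apparent glycation ratio (mL/mg) from a paired (MG, A1c) calibration.

    AGR = 1e5 · X(MG) / (100/A1c − 1).  Strictly increasing in A1c at
    fixed MG, strictly decreasing in MG at fixed A1c.
    """
    a1c = np.asarray(a1c, dtype=float)
    if np.any((a1c <= 0) | (a1c >= 100)):
        raise ValueError("A1c must lie in (0, 100) NGSP %")
    x = np.asarray(apparent_glucose(mg, constants), dtype=float)
    return _ret(1e5 * x / (100.0 / a1c - 1.0))


def forward_a1c(mg, agr, constants: GlycationConstants = DEFAULT_CONSTANTS):
    """Steady-state A1c (NGSP %) implied by mean glucose and a given AGR.

    A1c = 100 / (1 + 1e5 · X(MG) / AGR); the algebraic inverse of
    :func:`compute_agr`.  Strictly increasing in both MG and AGR, bounded
    above by the finite-MG asymptote 100 / (1 + 1e5/(AGR·K_M)).
    """
    agr = np.asarray(agr, dtype=float)
    if np.any(agr <= 0):
        raise ValueError("AGR must be positive (mL/mg)")
    x = np.asarray(apparent_glucose(mg, constants), dtype=float)
    return _ret(100.0 / (1.0 + 1e5 * x / agr))


def compute_pa1c(a1c_measured, agr, constants: GlycationConstants = DEFAULT_CONSTANTS):
    """Personalized A1c: a measured A1c mapped onto the reference-glycator scale.

    pA1c = 100 / (1 + (AGR/AGR_ref) · (100/A1c − 1)).  Equals the measured
    A1c exactly when AGR = AGR_ref; strictly increasing in the measured A1c
    and strictly decreasing in AGR.
    """
    a1c = np.asarray(a1c_measured, dtype=float)
    if np.any((a1c <= 0) | (a1c >= 100)):
        raise ValueError("A1c must lie in (0, 100) NGSP %")
    agr = np.asarray(agr, dtype=float)
    if np.any(agr <= 0):
        raise ValueError("AGR must be positive (mL/mg)")
    return _ret(100.0 / (1.0 + (agr / constants.agr_ref) * (100.0 / a1c - 1.0)))


def reference_ea1c(mg, constants: GlycationConstants = DEFAULT_CONSTANTS):
    """Reference-glycator A1c curve: forward model evaluated at AGR_ref.

    For any measured A1c a, compute_pa1c(a, compute_agr(mg, a)) collapses to
    this value — the pA1c of a subject with mean glucose ``mg`` is
    independent of where on the A1c axis they were calibrated.
    """
    return forward_a1c(mg, constants.agr_ref, constants)


def estimate_mg(a1c, agr, constants: GlycationConstants = DEFAULT_CONSTANTS):
    """Mean glucose (mg/dL) implied by an A1c under a given AGR.

    Inverts the forward model: MG = 1 / ((100/A1c − 1)·AGR/1e5 − 1/K_M).
    Defined only below the forward model's asymptote; above it no finite
    glucose can produce the requested A1c.
    """
    a1c = np.asarray(a1c, dtype=float)
    if np.any((a1c <= 0) | (a1c >= 100)):
        raise ValueError("A1c must lie in (0, 100) NGSP %")
    agr = np.asarray(agr, dtype=float)
    if np.any(agr <= 0):
        raise ValueError("AGR must be positive (mL/mg)")
    denom = (100.0 / a1c - 1.0) * agr / 1e5 - 1.0 / constants.k_m
    if np.any(denom <= 0):
        raise ValueError(
            "A1c too high for this AGR under the kinetic model "
            "(at or above the finite-glucose asymptote)"
        )
    return _ret(1.0 / denom)


def convert_a1c(value, direction: str):
    """Convert A1c between NGSP % and IFCC mmol/mol via the master equation.

    IFCC = 10.929 · (NGSP − 2.15).  ``direction`` is ``"ngsp_to_ifcc"`` or
    ``"ifcc_to_ngsp"``.  Reporting conventionally rounds IFCC to an integer;
    this function returns the unrounded value.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("A1c value must be non-negative")
    if direction == "ngsp_to_ifcc":
        return _ret(IFCC_SLOPE * (v - IFCC_OFFSET))
    if direction == "ifcc_to_ngsp":
        return _ret(v / IFCC_SLOPE + IFCC_OFFSET)
    raise ValueError(f"unknown direction {direction!r}")
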