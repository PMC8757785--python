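"""Laplace-law estimation of an effective aortic wall stiffness.

Treating the wall as a thin pressurized membrane, the circumferential (hoop)
stress is sigma = P D / (2 t).  Between diastole and systole the stress
increment is

    d_sigma = (P_sys D_sys - P_dia D_dia) / (2 t),

and the corresponding strain is the normalized diameter variation
eps = (D_sys - D_dia) / D_dia, giving an effective linear-elastic Young's
modulus E = d_sigma / eps.  This incremental (pulse-pressure) form is what a
gated-CT diameter pair plus cuff pressures can support.
"""

from __future__ import annotations

from dataclasses import dataclass

MMHG_TO_PA = 133.322


@dataclass
class MaterialEstimate:
    """Effective wall material estimate and its inputs."""

    E_mpa: float
    thickness_mm: float
    p_sys_mmhg: float
    p_dia_mmhg: float
    d_sys_mm: float
    d_dia_mm: float

    def __post_init__(self) -> None:
        if self.E_mpa <= 0:
            raise ValueError("Young's modulus must be positive")
        if self.d_sys_mm < self.d_dia_mm:
            raise ValueError("systolic diameter must be >= diastolic")


def estimate_young_modulus(p_sys_mmhg: float, p_dia_mmhg: float,
                           d_sys_mm: float, d_dia_mm: float,
                           thickness_mm: float = 2.0) -> MaterialEstimate:
    """Effective Young's modulus from pressures (mmHg) and diameters (mm).

    Raises on zero strain (equal diameters), where the modulus is undefined.
    """
    if thickness_mm <= 0:
        raise ValueError("wall thickness must be positive")
    if d_dia_mm <= 0 or d_sys_mm <= 0:
        raise ValueError("diameters must be positive")
    if p_sys_mmhg <= p_dia_mmhg:
        raise ValueError("systolic pressure must exceed diastolic")
    if d_sys_mm == d_dia_mm:
        raise ValueError("zero diameter strain: Young's modulus undefined")
    if d_sys_mm < d_dia_mm:
        raise ValueError("systolic diameter must exceed diastolic")
    p_sys = p_sys_mmhg * MMHG_TO_PA
    p_dia = p_dia_mmhg * MMHG_TO_PA
    d_sigma = (p_sys * d_sys_mm - p_dia * d_dia_mm) / (2.0 * thickness_mm)  # Pa
    strain = (d_sys_mm - d_dia_mm) / d_dia_mm
    return MaterialEstimate(E_mpa=d_sigma / strain / 1e6,
                            thickness_mm=thickness_mm,
                            p_sys_mmhg=p_sys_mmhg, p_dia_mmhg=p_dia_mmhg,
                            d_sys_mm=d_sys_mm, d_dia_mm=d_dia_mm)
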