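"""Y-90 microsphere treatment-planning dosimetry (MIRD partition model).

For yttrium-90 under local energy deposition the absorbed dose reduces to

    D [Gy] = 50 * A [GBq] / M [kg],

with the delivered hepatic activity reduced by the lung shunt fraction S and
compartment masses obtained from measured volumes via the liver tissue
density 1.03 kg/L.  Injected activity splits between tumor and healthy liver
in proportion to their MAA count integrals (CP_tum, CP_HL) — the partition
model.  Planning inverts the dose model for a prescription (typically
120 +/- 20 Gy to the vascularized volume).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DOSE_CONSTANT_GY_KG_PER_GBQ",
    "TISSUE_DENSITY_KG_PER_L",
    "CompartmentQuant",
    "DosePlan",
    "DoseReport",
    "mass_from_volume",
    "dose_from_activity",
    "activity_for_dose",
    "lung_shunt_fraction",
    "partition",
    "dose_report",
]

#: 50 Gy·kg/GBq — Y-90 mean dose per unit activity under local deposition.
DOSE_CONSTANT_GY_KG_PER_GBQ = 50.0
#: 1.03 kg/L — liver tissue density converting volume to mass.
TISSUE_DENSITY_KG_PER_L = 1.03


@dataclass(frozen=True)
class CompartmentQuant:
    """Volume and count integral of one compartment (liver, tumor, ...)."""

    label: str
    volume_mL: float
    counts: float

    def __post_init__(self):
        if self.volume_mL < 0:
            raise ValueError(f"{self.label}: volume must be >= 0")
        if self.counts < 0:
            raise ValueError(f"{self.label}: counts must be >= 0")


@dataclass(frozen=True)
class DosePlan:
    """Injected activity, lung shunt and prescription."""

    injected_activity_GBq: float
    lung_shunt: float = 0.0
    prescription_Gy: float = 120.0

    def __post_init__(self):
        if self.injected_activity_GBq < 0:
            raise ValueError("injected activity must be >= 0")
        if not 0 <= self.lung_shunt < 1:
            raise ValueError("lung shunt must lie in [0, 1)")


@dataclass(frozen=True)
class DoseReport:
    """Per-compartment activities, masses and absorbed doses."""

    injected_activity_GBq: float
    lung_shunt: float
    tumor_uptake_fraction: float
    D_treated_Gy: float
    A_tum_GBq: float
    A_HL_GBq: float
    W_tum_kg: float
    W_HL_kg: float
    D_tum_Gy: float
    D_HL_Gy: float


def mass_from_volume(volume_mL: float) -> float:
    """Compartment mass in kg: volume [mL] / 1000 * 1.03."""
    if volume_mL < 0:
        raise ValueError("volume must be >= 0")
    return volume_mL / 1000.0 * TISSUE_DENSITY_KG_PER_L


def dose_from_activity(A_inj_GBq: float, lung_shunt: float, volume_mL: float) -> float:
    """Absorbed dose (Gy) to a volume from an injected activity.

    D = A_inj * (1 - S) * 50 / M, with M = mass_from_volume(volume).
    """
    if not 0 <= lung_shunt < 1:
        raise ValueError("lung shunt must lie in [0, 1)")
    if volume_mL <= 0:
        raise ValueError("volume must be > 0")
    if A_inj_GBq < 0:
        raise ValueError("activity must be >= 0")
    return A_inj_GBq * (1.0 - lung_shunt) * DOSE_CONSTANT_GY_KG_PER_GBQ / mass_from_volume(volume_mL)


def activity_for_dose(D_target_Gy: float, lung_shunt: float, volume_mL: float) -> float:
    """Injected activity (GBq) delivering a target dose; exact inverse of
    :func:`dose_from_activity`."""
    if D_target_Gy <= 0:
        raise ValueError("target dose must be > 0")
    if not 0 <= lung_shunt < 1:
        raise ValueError("lung shunt must lie in [0, 1) — S = 1 delivers nothing")
    if volume_mL <= 0:
        raise ValueError("volume must be > 0")
    return D_target_Gy * mass_from_volume(volume_mL) / (DOSE_CONSTANT_GY_KG_PER_GBQ * (1.0 - lung_shunt))


def lung_shunt_fraction(lung: CompartmentQuant, liver: CompartmentQuant) -> float:
    """Lung shunt fraction: lung counts / (lung + liver counts)."""
    total = lung.counts + liver.counts
    if total <= 0:
        raise ValueError("lung and liver counts are both zero")
    return lung.counts / total


def partition(liver: CompartmentQuant, tumor: CompartmentQuant) -> tuple[CompartmentQuant, float]:
    """Subtract the tumor from the whole liver.

    Returns the healthy-liver compartment (CP_HL = CP_L - CP_tum,
    V_HL = V_L - V_tum) and the tumor uptake fraction
    CP_tum / (CP_tum + CP_HL).
    """
    if tumor.volume_mL > liver.volume_mL:
        raise ValueError("tumor volume exceeds liver volume")
    if tumor.counts > liver.counts:
        raise ValueError("tumor counts exceed liver counts")
    healthy = CompartmentQuant("healthy_liver", liver.volume_mL - tumor.volume_mL,
                               liver.counts - tumor.counts)
    if liver.counts == 0:
        raise ValueError("liver compartment holds no counts")
    fraction = tumor.counts / liver.counts
    return healthy, fraction


def dose_report(plan: DosePlan, liver: CompartmentQuant, tumor: CompartmentQuant) -> DoseReport:
    """Full partition-model dose report from liver and tumor VOI quantities.

    A_tum = A_inj (1-S) CP_tum / (CP_tum + CP_HL) and symmetrically for the
    healthy liver; each compartment dose is 50 * A / W with W from
    :func:`mass_from_volume`.  The whole-treated-volume dose uses the liver
    volume.  Activity conservation A_tum + A_HL = A_inj (1-S) holds by
    construction and is asserted.
    """
    healthy, fraction = partition(liver, tumor)
    hepatic = plan.injected_activity_GBq * (1.0 - plan.lung_shunt)
    A_tum = hepatic * fraction
    A_HL = hepatic * (1.0 - fraction)
    assert abs((A_tum + A_HL) - hepatic) <= 1e-9 * max(hepatic, 1.0)
    W_tum = mass_from_volume(tumor.volume_mL)
    W_HL = mass_from_volume(healthy.volume_mL)
    if W_tum == 0 and A_tum > 0:
        raise ValueError("tumor has activity but zero mass")
    if W_HL == 0 and A_HL > 0:
        raise ValueError("healthy liver has activity but zero mass")
    D_tum = DOSE_CONSTANT_GY_KG_PER_GBQ * A_tum / W_tum if W_tum > 0 else 0.0
    D_HL = DOSE_CONSTANT_GY_KG_PER_GBQ * A_HL / W_HL if W_HL > 0 else 0.0
    D_treated = dose_from_activity(plan.injected_activity_GBq, plan.lung_shunt,
                                   liver.volume_mL)
    return DoseReport(
        injected_activity_GBq=plan.injected_activity_GBq,
        lung_shunt=plan.lung_shunt,
        tumor_uptake_fraction=fraction,
        D_treated_Gy=D_treated,
        A_tum_GBq=A_tum,
        A_HL_GBq=A_HL,
        W_tum_kg=W_tum,
        W_HL_kg=W_HL,
        D_tum_Gy=D_tum,
        D_HL_Gy=D_HL,
    )
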