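"""Parameter containers for the apixaban biopharmaceutics model.

All containers are frozen dataclasses with eager validation, so invalid
physiology or drug constants fail at construction time rather than deep
inside an ODE right-hand side.

Internal unit regime: mass in mg, volume in mL (= cm^3), time in h,
length in cm.  Concentrations are reported in ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)

import numpy as np

__all__ = [
    "DrugProperties",
    "FormulationSpec",
    "DissolutionCondition",
    "ZModelParams",
    "GIPhysiology",
    "DispositionParams",
    "extrapolate_peff",
    "apixaban",
    "apixaban_disposition",
    "default_physiology",
]

#: Peff extrapolation coefficients: log10(Peff) = a + b*log10(Papp) + c*RBN
_PEFF_INTERCEPT = 0.932
_PEFF_SLOPE_PAPP = 0.763
_PEFF_SLOPE_RBN = 0.0324


def extrapolate_peff(papp_cm_h: float, rbn: int) -> float:
    """Extrapolate human effective jejunal permeability from Caco-2 data.

    Implements the log-linear correlation
    ``log10(Peff) = 0.932 + 0.763*log10(Papp) + 0.0324*RBN`` with both
    permeabilities in cm/h and RBN the number of rotatable bonds.

    Parameters
    ----------
    papp_cm_h : float
        Apparent Caco-2 monolayer permeability in cm/h (note: *not* the
        more common cm/s — multiply by 3600 first).
    rbn : int
        Rotatable bond count of the molecule (non-negative).

    Returns
    -------
    float
        Effective permeability Peff in cm/h.
    """
    if papp_cm_h <= 0:
        raise ValueError(f"Papp must be positive, got {papp_cm_h}")
    if rbn < 0 or int(rbn) != rbn:
        raise ValueError(f"RBN must be a non-negative integer, got {rbn}")
    return 10.0 ** (
        _PEFF_INTERCEPT
        + _PEFF_SLOPE_PAPP * math.log10(papp_cm_h)
        + _PEFF_SLOPE_RBN * rbn
    )


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical and permeability constants of the drug.

    Defaults are apixaban's: a non-ionizable, borderline BCS III/IV
    molecule with pH-independent solubility.
    """

    molecular_weight: float = 495.5  #: g/mol
    solubility_ug_ml: float = 40.0  #: aqueous solubility Cs, µg/mL
    diffusion_coeff: float = 0.018  #: CD, cm^2/h
    density: float = 1200.0  #: true density ro, mg/cm^3
    diffusion_layer: float = 0.003  #: diffusion layer thickness h, cm
    caco2_papp_cm_s: float = 0.9e-6  #: apparent Caco-2 permeability, cm/s
    rotatable_bonds: int = 5  #: RBN

    def __post_init__(self) -> None:
        for name in (
            "molecular_weight",
            "solubility_ug_ml",
            "diffusion_coeff",
            "density",
            "diffusion_layer",
            "caco2_papp_cm_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rotatable_bonds < 0 or int(self.rotatable_bonds) != self.rotatable_bonds:
            raise ValueError("rotatable_bonds must be a non-negative integer")

    @property
    def solubility_mg_ml(self) -> float:
        """Cs in mg/mL (= mg/cm^3), the internal unit."""
        return self.solubility_ug_ml * 1e-3

    @property
    def papp_cm_h(self) -> float:
        return self.caco2_papp_cm_s * 3600.0

    @property
    def peff(self) -> float:
        """Effective jejunal permeability, cm/h (derived, cached per call)."""
        return extrapolate_peff(self.papp_cm_h, self.rotatable_bonds)


@dataclass(frozen=True)
class FormulationSpec:
    """Dose and formulation attributes of one drug product.

    ``d90_um`` is the D90 of the API particle-size distribution, used as a
    monodisperse particle *diameter* throughout.
    """

    dose_mg: float
    form: str = "ir_tablet"  #: 'solution' | 'ir_tablet'
    granulation: str | None = None  #: 'wet' | 'dry' | None (solutions)
    d90_um: float | None = None
    z: float | None = None  #: optional Z-factor override

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be positive")
        if self.form not in ("solution", "ir_tablet"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "ir_tablet":
            if self.d90_um is None:
                raise ValueError("ir_tablet requires a particle size (d90_um)")
            if not 0 < self.d90_um <= 1000:
                raise ValueError("d90_um must lie in (0, 1000] µm")
            if self.granulation not in ("wet", "dry"):
                raise ValueError("ir_tablet requires granulation 'wet' or 'dry'")
        elif self.d90_um is not None:
            raise ValueError("solutions carry no particle size")

    @property
    def size_cm(self) -> float:
        """Particle diameter in cm."""
        if self.d90_um is None:
            raise ValueError("no particle size for a solution")
        return self.d90_um * 1e-4


@dataclass(frozen=True)
class DissolutionCondition:
    """In vitro dissolution test conditions."""

    medium: str = "hcl_01n"  #: 'ph68_sds' | 'hcl_01n'
    volume_ml: float = 900.0
    apparatus: str = "USP II, 75 rpm"

    def __post_init__(self) -> None:
        if self.medium not in ("ph68_sds", "hcl_01n"):
            raise ValueError(f"unknown medium {self.medium!r}")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")


@dataclass(frozen=True)
class ZModelParams:
    """Covariate model for the dissolution Z-factor.

    Z = z_wet + [dry granulation]*dz_dry + [0.1 N HCl medium]*dz_hcl.
    ``sigma_add`` is the additive residual SD on % dissolved.
    """

    z_wet: float = 44.8
    dz_dry: float = 8.6
    dz_hcl: float = -22.5
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.z_wet <= 0:
            raise ValueError("z_wet must be positive")
        if self.sigma_add < 0:
            raise ValueError("sigma_add must be non-negative")
        for gran in ("wet", "dry"):
            for med in ("ph68_sds", "hcl_01n"):
                if self.z_for(gran, med, validate=False) <= 0:
                    raise ValueError(
                        f"Z non-positive for granulation={gran}, medium={med}"
                    )

    def z_for(self, granulation: str, medium: str, validate: bool = True) -> float:
        """Resolve Z for a granulation/medium combination."""
        if granulation not in ("wet", "dry"):
            raise ValueError(f"unknown granulation {granulation!r}")
        if medium not in ("ph68_sds", "hcl_01n"):
            raise ValueError(f"unknown medium {medium!r}")
        z = (
            self.z_wet
            + (self.dz_dry if granulation == "dry" else 0.0)
            + (self.dz_hcl if medium == "hcl_01n" else 0.0)
        )
        if validate and z <= 0:
            raise ValueError(
                f"resulting Z = {z:.4g} is non-positive for "
                f"granulation={granulation}, medium={medium}"
            )
        return z


@dataclass(frozen=True)
class GIPhysiology:
    """Fasted-state gastrointestinal physiology.

    The gut is a stomach, ``n_si`` small-intestinal compartments in series
    and a colon.  Luminal water follows a parallel compartment chain fed by
    secretions and drained by first-order reabsorption; see docs/methods.md
    for the calibration of the four water parameters.
    """

    n_si: int = 7
    gastric_emptying_ks: float = math.log(2) / 0.25  #: h^-1 (t1/2 = 15 min)
    si_transit_time_h: float = 3.32  #: total small-intestinal transit time
    radius_proximal: float = 1.75  #: cm
    radius_distal: float = 1.0  #: cm
    dose_water_ml: float = 250.0
    secretion_r1: float = 90.0  #: salivary+gastric secretion, mL/h
    secretion_r2: float = 150.0  #: duodenal secretion (into SI 1), mL/h
    secretion_r3: float = 30.0  #: mucous secretion (split over SI 2..n), mL/h
    water_reabsorption_kh2o: float = 0.80  #: h^-1, first order on SI water
    precipitation_k: float = 1000.0  #: h^-1 relaxation of supersaturation

    def __post_init__(self) -> None:
        if self.n_si < 1 or int(self.n_si) != self.n_si:
            raise ValueError("n_si must be a positive integer")
        for name in ("gastric_emptying_ks", "si_transit_time_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "dose_water_ml",
            "secretion_r1",
            "secretion_r2",
            "secretion_r3",
            "water_reabsorption_kh2o",
            "precipitation_k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.radius_distal <= self.radius_proximal:
            raise ValueError("need 0 < radius_distal <= radius_proximal")

    @property
    def si_transit_kt(self) -> float:
        """Per-compartment transit rate kT = n_si / total transit time, h^-1."""
        return self.n_si / self.si_transit_time_h


@dataclass(frozen=True)
class DispositionParams:
    """Mammillary 2- or 3-compartment disposition micro-constants."""

    k10: float
    k12: float
    k21: float
    v1_l: float
    k13: float = 0.0
    k31: float = 0.0
    n_compartments: int = 3

    def __post_init__(self) -> None:
        if self.n_compartments not in (2, 3):
            raise ValueError("n_compartments must be 2 or 3")
        if self.k10 <= 0:
            raise ValueError("k10 must be positive")
        if self.v1_l <= 0:
            raise ValueError("v1_l must be positive")
        for name in ("k12", "k21", "k13", "k31"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_compartments == 2 and (self.k13 != 0 or self.k31 != 0):
            raise ValueError("2-compartment model requires k13 = k31 = 0")
        eig = np.linalg.eigvals(self.rate_matrix())
        if np.any(eig.real >= 1e-12):
            raise ValueError("rate constants give an unstable (non-Hurwitz) system")

    def rate_matrix(self) -> np.ndarray:
        """3x3 matrix A with d(amounts)/dt = A @ amounts (2-cmt embeds as k13=k31=0)."""
        return np.array(
            [
                [-(self.k10 + self.k12 + self.k13), self.k21, self.k31],
                [self.k12, -self.k21, 0.0],
                [self.k13, 0.0, -self.k31],
            ]
        )

    @property
    def clearance_l_h(self) -> float:
        """CL = k10 * V1, L/h."""
        return self.k10 * self.v1_l

    @property
    def n_parameters(self) -> int:
        """Number of kinetic parameters (micro-constants + V1)."""
        return 4 if self.n_compartments == 2 else 6


def apixaban() -> DrugProperties:
    """Apixaban drug constants (the dataclass defaults, named for clarity)."""
    return DrugProperties()


def apixaban_disposition() -> DispositionParams:
    """The fitted 3-compartment IV disposition of apixaban (5 mg IV mean data)."""
    return DispositionParams(
        k10=0.5409, k12=0.086, k21=0.0441, k13=4.319, k31=2.24, v1_l=4.756,
        n_compartments=3,
    )


def default_physiology() -> GIPhysiology:
    """Fasted human GI physiology with the frozen water-submodel calibration."""
    return GIPhysiology()
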