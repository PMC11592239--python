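"""HU-to-elastic-property mapping for cancellous bone.

The cancellous compartment of each vertebral body is assigned a single
isotropic elastic modulus and strength derived from its mean CT attenuation
(in Hounsfield units) through a density calibration chain:

    HU  →  ρ_BMD (equivalent mineral density, phantom-calibrated)
        →  ρ_CHA (calcium-hydroxyapatite density)
        →  ρ_ash (ash density)
        →  E_spong = 21700 · ρ_ash^2.07  MPa
        →  S_max,spong = 137 · ρ_ash^1.88  MPa

with ρ_BMD = a + b·HU (a = −14 mg/cm³, b = 0.385 mg/cm³/HU) and HU clamped
from below at HU_min = 50 so that low-attenuation marrow maps to a floor
material rather than a non-physical negative density.  The ash-density
offset is ρ_ash = 0.0633 + 0.887·ρ_CHA (g/cm³).

Two readings of the ρ_BMD → ρ_CHA step are provided because the published
form of that relation is ambiguous:

``pragmatic`` (default)
    ρ_CHA ≡ ρ_BMD.  Phantom-calibrated BMD is already expressed as an
    equivalent hydroxyapatite density, so no further conversion is applied.
``literal``
    ρ_CHA = max(0, D_CHA·(ρ_BMD − D_H2O)/(D_CHA − D_H2O)), i.e. ρ_BMD is
    treated as a water/CHA mixture density.  Every physiologic vertebral
    HU then falls below water density and collapses to the 0.0633 g/cm³
    ash floor, which is why this mode is not the default.

Cortical bone bypasses the chain entirely and uses a fixed modulus
E_cor (default 8000 MPa).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "MappingParams",
    "DensityChain",
    "MaterialCard",
    "hu_to_density_chain",
    "density_to_modulus",
    "density_to_strength",
    "build_material_card",
]

#: additive ash-density floor, g/cm^3
ASH_OFFSET = 0.0633
#: multiplicative ash-density slope (per g/cm^3 of CHA density)
ASH_SLOPE = 0.887


@dataclass(frozen=True)
class MappingParams:
    """Constants of the HU → density → (E, S_max) calibration chain.

    Units: ``a`` mg/cm³, ``b`` mg/cm³ per HU, densities g/cm³, moduli and
    strengths MPa.
    """

    a: float = -14.0
    b: float = 0.385
    hu_min: float = 50.0
    d_h2o: float = 1.0
    d_cha: float = 3.18
    rho_cha_mode: str = "pragmatic"
    e_coeff: float = 21700.0
    e_exp: float = 2.07
    s_coeff: float = 137.0
    s_exp: float = 1.88
    e_cor: float = 8000.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")
        if not (self.d_cha > self.d_h2o > 0):
            raise ValueError("require d_cha > d_h2o > 0")
        if self.e_exp <= 0 or self.s_exp <= 0:
            raise ValueError("power-law exponents must be positive")
        if self.rho_cha_mode not in ("pragmatic", "literal"):
            raise ValueError(f"unknown rho_cha_mode {self.rho_cha_mode!r}")

    def digest(self) -> str:
        """Short stable hash of the parameter set, for provenance records."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class DensityChain:
    """Fully recorded evaluation of the density chain for one HU value."""

    hu_in: float
    hu_clamped: float
    rho_bmd: float  # g/cm^3
    rho_cha: float  # g/cm^3
    rho_ash: float  # g/cm^3
    e_spong: float  # MPa
    s_max_spong: float  # MPa
    mode: str


def hu_to_density_chain(hu: float, params: MappingParams | None = None) -> DensityChain:
    """Evaluate the full HU → ρ_BMD → ρ_CHA → ρ_ash → (E, S_max) chain.

    HU values below ``params.hu_min`` are clamped to it (floor material,
    not exclusion).  ``rho_bmd`` is converted from mg/cm³ to g/cm³ before
    the ash-density and power-law steps.
    """
    params = params or MappingParams()
    hu = float(hu)
    if not np.isfinite(hu):
        raise ValueError("hu must be finite")
    hu_clamped = max(hu, params.hu_min)
    rho_bmd = (params.a + hu_clamped * params.b) / 1000.0  # mg/cm^3 -> g/cm^3
    if params.rho_cha_mode == "pragmatic":
        rho_cha = rho_bmd
    else:  # literal mixture-density reading
        rho_cha = max(
            0.0, params.d_cha * (rho_bmd - params.d_h2o) / (params.d_cha - params.d_h2o)
        )
    rho_ash = ASH_OFFSET + ASH_SLOPE * rho_cha
    e_spong = params.e_coeff * rho_ash**params.e_exp
    s_max = params.s_coeff * rho_ash**params.s_exp
    return DensityChain(
        hu_in=hu,
        hu_clamped=hu_clamped,
        rho_bmd=rho_bmd,
        rho_cha=rho_cha,
        rho_ash=rho_ash,
        e_spong=e_spong,
        s_max_spong=s_max,
        mode=params.rho_cha_mode,
    )


def density_to_modulus(chain: DensityChain, params: MappingParams | None = None) -> float:
    """Cancellous modulus E_spong = e_coeff · ρ_ash^e_exp, MPa."""
    params = params or MappingParams()
    if chain.rho_ash <= 0:
        raise ValueError("rho_ash must be positive")
    return params.e_coeff * chain.rho_ash**params.e_exp


def density_to_strength(chain: DensityChain, params: MappingParams | None = None) -> float:
    """Cancellous strength S_max,spong = s_coeff · ρ_ash^s_exp, MPa."""
    params = params or MappingParams()
    if chain.rho_ash <= 0:
        raise ValueError("rho_ash must be positive")
    return params.s_coeff * chain.rho_ash**params.s_exp


@dataclass(frozen=True)
class MaterialCard:
    """Per-vertebra material assignment with provenance.

    One spatially uniform cancellous (E, S_max) pair derived from the
    vertebra's mean cancellous HU, plus the fixed cortical modulus.
    """

    vertebra_label: str
    mean_hu: float
    e_cor: float  # MPa
    e_spong: float  # MPa
    s_max_spong: float  # MPa
    mode: str
    params_digest: str
    chain: DensityChain = field(repr=False, default=None)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def build_material_card(
    mean_hu: float,
    params: MappingParams | None = None,
    vertebra_label: str = "",
) -> MaterialCard:
    """Build the uniform material card for one vertebra from its mean HU."""
    params = params or MappingParams()
    chain = hu_to_density_chain(mean_hu, params)
    return MaterialCard(
        vertebra_label=vertebra_label,
        mean_hu=float(mean_hu),
        e_cor=params.e_cor,
        e_spong=chain.e_spong,
        s_max_spong=chain.s_max_spong,
        mode=params.rho_cha_mode,
        params_digest=params.digest(),
        chain=chain,
    )
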