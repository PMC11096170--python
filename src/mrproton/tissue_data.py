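"""Tissue composition tables and proton stopping-power physics.

This module holds the material ground truth for the tissue-substitute and
animal-tissue phantoms (elemental mass fractions, measured mass density,
measured relative stopping power and mean excitation energy) together with
the small amount of physics needed to parameterize and cross-check synthetic
scenes:

* mean ``Z/A`` of a mixture and its relative electron density,
* the Bragg additivity rule for the mean excitation energy ``I``,
* the Bethe-ratio relative stopping power of a proton beam,
* a power-law effective atomic number ``Z_eff``.

Relative quantities are expressed against liquid water (``rho = 1 g/cm^3``,
``I_w = 75 eV`` by default). Mass fractions are stored as fractions in
``[0, 1]``; the packaged CSV tables carry percentages and are divided by 100
at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "ElementRecord",
    "TissueSpec",
    "BeamSpec",
    "PROTON_REST_ENERGY_MEV",
    "ELECTRON_REST_ENERGY_MEV",
    "WATER_COMPOSITION",
    "load_elements",
    "load_tissues",
    "water_spec",
    "z_over_a",
    "relative_electron_density",
    "bragg_additivity_I",
    "effective_atomic_number",
    "theoretical_rsp",
    "rsp_from_wet",
]

#: Proton rest energy in MeV (CODATA).
PROTON_REST_ENERGY_MEV = 938.272

#: Electron rest energy in MeV (CODATA).
ELECTRON_REST_ENERGY_MEV = 0.511

#: Elemental mass fractions of water.
WATER_COMPOSITION: Mapping[str, float] = {"H": 0.1119, "O": 0.8881}


class UnknownElementError(KeyError):
    """Raised when a composition references an element without a record."""


@dataclass(frozen=True)
class ElementRecord:
    """One chemical element as used in stopping-power mixture rules.

    Parameters
    ----------
    symbol : str
        Element symbol, e.g. ``"Ca"``.
    atomic_number : int
        Atomic number ``Z``.
    atomic_mass : float
        Standard atomic mass ``A`` in g/mol.
    mean_excitation_energy : float
        Elemental I-value in eV under the configured convention
        (ICRU condensed-phase values by default).
    """

    symbol: str
    atomic_number: int
    atomic_mass: float
    mean_excitation_energy: float

    def __post_init__(self) -> None:
        if self.atomic_number < 1:
            raise ValueError(f"{self.symbol}: atomic_number must be >= 1")
        if self.atomic_mass <= 0:
            raise ValueError(f"{self.symbol}: atomic_mass must be > 0")
        if self.mean_excitation_energy <= 0:
            raise ValueError(f"{self.symbol}: mean_excitation_energy must be > 0")

    @property
    def z_over_a(self) -> float:
        return self.atomic_number / self.atomic_mass


@dataclass(frozen=True)
class TissueSpec:
    """A named material: elemental composition plus measured properties.

    ``mass_fractions`` maps element symbols to dimensionless mass fractions
    (percent / 100) and must sum to 1 within 0.005. ``recipe`` optionally
    records the ingredient mixture (water / gelatin / lard / hydroxyapatite /
    SDS mass fractions) the phantom was made from.
    """

    name: str
    mass_fractions: Mapping[str, float]
    measured_density: float
    measured_rsp: float
    mean_excitation_energy: float
    recipe: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.mass_fractions:
            raise ValueError(f"{self.name}: empty composition")
        for sym, w in self.mass_fractions.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{self.name}: mass fraction {sym}={w} outside [0, 1]")
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 0.005:
            raise ValueError(
                f"{self.name}: mass fractions sum to {total:.4f}, expected 1 within 0.005"
            )
        if self.measured_density <= 0:
            raise ValueError(f"{self.name}: measured_density must be > 0")
        if self.measured_rsp <= 0:
            raise ValueError(f"{self.name}: measured_rsp must be > 0")
        if self.mean_excitation_energy <= 0:
            raise ValueError(f"{self.name}: mean_excitation_energy must be > 0")


def _water_z_over_a() -> float:
    # computed from H 11.19% / O 88.81% with the packaged element table
    elements = load_elements()
    return sum(w * elements[s].z_over_a for s, w in WATER_COMPOSITION.items())


@dataclass(frozen=True)
class BeamSpec:
    """Proton beam and water-reference parameters for the Bethe ratio.

    Defaults: 150 MeV kinetic energy, water ``I_w = 75 eV``, water ``Z/A``
    computed from the H 11.19% / O 88.81% composition. All overridable.
    """

    kinetic_energy: float = 150.0
    water_mean_excitation_energy: float = 75.0
    water_z_over_a: float = field(default_factory=_water_z_over_a)

    def __post_init__(self) -> None:
        if self.kinetic_energy <= 0:
            raise ValueError("kinetic_energy must be > 0")
        if self.water_mean_excitation_energy <= 0:
            raise ValueError("water_mean_excitation_energy must be > 0")

    @property
    def beta_squared(self) -> float:
        gamma = 1.0 + self.kinetic_energy / PROTON_REST_ENERGY_MEV
        return 1.0 - 1.0 / gamma**2


def _data_path(name: str):
    return resources.files("mrproton.data").joinpath(name)


_ELEMENT_CACHE: dict[str, ElementRecord] | None = None


def load_elements() -> dict[str, ElementRecord]:
    """Load the packaged element table (Z, A, elemental I-value per symbol)."""
    global _ELEMENT_CACHE
    if _ELEMENT_CACHE is None:
        with resources.as_file(_data_path("elements.csv")) as p:
            df = pd.read_csv(p)
        _ELEMENT_CACHE = {
            row.symbol: ElementRecord(
                symbol=row.symbol,
                atomic_number=int(row.atomic_number),
                atomic_mass=float(row.atomic_mass),
                mean_excitation_energy=float(row.mean_excitation_energy),
            )
            for row in df.itertuples()
        }
    return dict(_ELEMENT_CACHE)


def load_tissues() -> dict[str, TissueSpec]:
    """Load the packaged phantom table: seven tissue specs keyed by name.

    Compositions, densities, measured RSP and mean excitation energies come
    from the packaged ``tissues.csv``; ingredient recipes (where the phantom
    was mixed from water/gelatin/lard/hydroxyapatite/SDS) from ``recipes.csv``.
    """
    with resources.as_file(_data_path("tissues.csv")) as p:
        df = pd.read_csv(p)
    with resources.as_file(_data_path("recipes.csv")) as p:
        rec = pd.read_csv(p).set_index("name")
    element_cols = [c for c in df.columns if c in load_elements()]
    specs: dict[str, TissueSpec] = {}
    for row in df.itertuples():
        fractions = {}
        for c in element_cols:
            val = float(df.loc[row.Index, c])
            if val > 0:
                fractions[c] = val / 100.0
        recipe = None
        if row.name in rec.index:
            recipe = {
                k: float(v) / 100.0 for k, v in rec.loc[row.name].items() if float(v) > 0
            }
        specs[row.name] = TissueSpec(
            name=row.name,
            mass_fractions=fractions,
            measured_density=float(row.measured_density),
            measured_rsp=float(row.measured_rsp),
            mean_excitation_energy=float(row.mean_excitation_energy),
            recipe=recipe,
        )
    return specs


def water_spec() -> TissueSpec:
    """Liquid water as a :class:`TissueSpec` (the reference medium)."""
    return TissueSpec(
        name="Water",
        mass_fractions=dict(WATER_COMPOSITION),
        measured_density=1.0,
        measured_rsp=1.0,
        mean_excitation_energy=75.0,
    )


def _records(spec: TissueSpec, elements: Mapping[str, ElementRecord] | None):
    table = elements if elements is not None else load_elements()
    out = []
    for sym, w in spec.mass_fractions.items():
        if sym not in table:
            raise UnknownElementError(
                f"unknown element symbol {sym!r} in composition of {spec.name!r}"
            )
        out.append((w, table[sym]))
    return out


def z_over_a(
    spec: TissueSpec, elements: Mapping[str, ElementRecord] | None = None
) -> float:
    """Mass-weighted mean Z/A of a mixture: ``sum_i w_i Z_i / A_i`` (mol/g scale)."""
    return sum(w * el.z_over_a for w, el in _records(spec, elements))


def relative_electron_density(
    spec: TissueSpec,
    density: float,
    elements: Mapping[str, ElementRecord] | None = None,
    water_z_over_a: float | None = None,
) -> float:
    """Electron density relative to water at 1.000 g/cm^3.

    ``rho_e = density * (Z/A)_material / (Z/A)_water``, so water at unit
    density maps to exactly 1.
    """
    if density <= 0:
        raise ValueError(f"density must be > 0, got {density}")
    wza = water_z_over_a if water_z_over_a is not None else _water_z_over_a()
    return density * z_over_a(spec, elements) / wza


def bragg_additivity_I(
    spec: TissueSpec, elements: Mapping[str, ElementRecord] | None = None
) -> float:
    """Mean excitation energy of a mixture by the Bragg additivity rule.

    ``ln I = sum_i(w_i Z_i/A_i ln I_i) / sum_i(w_i Z_i/A_i)`` — an
    electron-weighted log mean, invariant to uniform rescaling of the
    weights and bounded by the elemental I-values present.
    """
    recs = _records(spec, elements)
    denom = sum(w * el.z_over_a for w, el in recs)
    if denom <= 0:
        raise ValueError(f"{spec.name}: composition has no electrons")
    num = sum(w * el.z_over_a * math.log(el.mean_excitation_energy) for w, el in recs)
    return math.exp(num / denom)


def effective_atomic_number(
    spec: TissueSpec,
    exponent: float = 3.1,
    elements: Mapping[str, ElementRecord] | None = None,
) -> float:
    """Power-law effective atomic number of a mixture.

    ``Z_eff = (sum_i w_i (Z_i/A_i) Z_i^m / sum_i w_i Z_i/A_i)^(1/m)`` with
    ``m = 3.1`` by default (a common spectral-CT convention).
    """
    recs = _records(spec, elements)
    denom = sum(w * el.z_over_a for w, el in recs)
    num = sum(w * el.z_over_a * el.atomic_number**exponent for w, el in recs)
    return (num / denom) ** (1.0 / exponent)


def _bethe_log_term(I_ev: float, beam: BeamSpec) -> float:
    b2 = beam.beta_squared
    arg = 2.0 * ELECTRON_REST_ENERGY_MEV * 1e6 * b2 / (1.0 - b2)
    if I_ev <= 0 or I_ev >= arg:
        raise ValueError(
            f"mean excitation energy {I_ev} eV outside Bethe validity "
            f"(0, {arg:.1f}) eV at {beam.kinetic_energy} MeV"
        )
    return math.log(arg / I_ev) - b2


def theoretical_rsp(
    spec: TissueSpec,
    density: float,
    I_ev: float,
    beam: BeamSpec | None = None,
    elements: Mapping[str, ElementRecord] | None = None,
) -> float:
    """Bethe-ratio relative stopping power of a material versus water.

    ``RSP = rho_e * [ln(2 m_e c^2 beta^2 / (I (1-beta^2))) - beta^2]
    / [same with I_w]``; shell and density-effect corrections are neglected,
    which is adequate for therapeutic proton energies in soft tissue and
    bone mimics.
    """
    beam = beam if beam is not None else BeamSpec()
    rho_e = relative_electron_density(
        spec, density, elements, water_z_over_a=beam.water_z_over_a
    )
    return (
        rho_e
        * _bethe_log_term(I_ev, beam)
        / _bethe_log_term(beam.water_mean_excitation_energy, beam)
    )


def rsp_from_wet(wet: float, thickness: float) -> float:
    """RSP from a measured water-equivalent thickness: ``WET / thickness``."""
    if thickness <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    return wet / thickness
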