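"""Material definitions and composition arithmetic.

A material is defined either by elemental mass fractions (tissues, concrete,
air) or by an integer atom ratio (water H2O, Perspex C5O2H8); the other
representation is always derived.  Number densities feed the macroscopic
cross sections used by the transport kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "ElementSpec",
    "Material",
    "MaterialTable",
    "ELEMENTS",
    "N_AVOGADRO",
    "atom_fractions",
    "mass_fractions",
    "number_densities",
    "load_materials",
]

N_AVOGADRO = 6.02214076e23  # 1/mol

_FRACTION_TOL = 1e-9


class UnknownElementError(KeyError):
    """Composition references a chemical symbol absent from the element table."""


@dataclass(frozen=True)
class ElementSpec:
    """Chemical element: symbol, atomic number and standard atomic mass."""

    symbol: str
    Z: int
    A_r: float  # g/mol

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A_r <= 0:
            raise ValueError(f"A_r must be > 0, got {self.A_r}")


def _load_elements() -> dict[str, ElementSpec]:
    table = {}
    text = resources.files("neutronplan.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, z, ar = line.split("\t")
        table[sym] = ElementSpec(sym, int(z), float(ar))
    return table


ELEMENTS: dict[str, ElementSpec] = _load_elements()


def _check_symbols(composition: dict[str, float], elements: dict[str, ElementSpec]) -> None:
    unknown = set(composition) - set(elements)
    if unknown:
        raise UnknownElementError(f"unknown element symbol(s): {sorted(unknown)}")


def atom_fractions(
    composition: dict[str, float], elements: dict[str, ElementSpec] | None = None
) -> dict[str, float]:
    """Convert elemental mass fractions to atom (number) fractions.

    n_i = (w_i / A_i) / sum_j (w_j / A_j).  Input fractions must sum to one.
    """
    elements = ELEMENTS if elements is None else elements
    if not composition:
        raise ValueError("empty composition")
    _check_symbols(composition, elements)
    total_w = sum(composition.values())
    if abs(total_w - 1.0) > 1e-6:
        raise ValueError(f"mass fractions sum to {total_w}, expected 1")
    moles = {sym: w / elements[sym].A_r for sym, w in composition.items()}
    total = sum(moles.values())
    return {sym: m / total for sym, m in moles.items()}


def mass_fractions(
    atom_ratio: dict[str, float], elements: dict[str, ElementSpec] | None = None
) -> dict[str, float]:
    """Convert an atom ratio (e.g. H:2, O:1) to mass fractions.

    w_i = r_i A_i / sum_j r_j A_j.
    """
    elements = ELEMENTS if elements is None else elements
    if not atom_ratio:
        raise ValueError("empty composition")
    _check_symbols(atom_ratio, elements)
    if any(r <= 0 for r in atom_ratio.values()):
        raise ValueError("atom ratios must be positive")
    masses = {sym: r * elements[sym].A_r for sym, r in atom_ratio.items()}
    total = sum(masses.values())
    return {sym: m / total for sym, m in masses.items()}


@dataclass
class Material:
    """A transport material: density plus elemental composition.

    Exactly one of the two composition views is given at construction; the
    other is derived.  ``material_id`` is the integer label used in voxel
    phantoms and organ maps.
    """

    material_id: int
    name: str
    density: float  # g/cm^3
    state: str = "solid"
    mass_fraction: dict[str, float] = field(default_factory=dict)
    atom_fraction: dict[str, float] = field(default_factory=dict)
    atom_ratio: dict[str, float] | None = None

    @classmethod
    def from_mass_fractions(
        cls, material_id: int, name: str, density: float, w: dict[str, float], state: str = "solid"
    ) -> "Material":
        if density <= 0:
            raise ValueError("density must be > 0")
        m = cls(material_id, name, density, state, mass_fraction=dict(w))
        m.atom_fraction = atom_fractions(w)
        m._validate()
        return m

    @classmethod
    def from_atom_ratio(
        cls, material_id: int, name: str, density: float, r: dict[str, float], state: str = "solid"
    ) -> "Material":
        if density <= 0:
            raise ValueError("density must be > 0")
        w = mass_fractions(r)
        total_r = sum(r.values())
        m = cls(
            material_id,
            name,
            density,
            state,
            mass_fraction=w,
            atom_fraction={sym: ri / total_r for sym, ri in r.items()},
            atom_ratio=dict(r),
        )
        m._validate()
        return m

    @classmethod
    def vacuum(cls, material_id: int = 0, name: str = "vacuum") -> "Material":
        return cls(material_id, name, density=0.0, state="gas")

    @property
    def is_vacuum(self) -> bool:
        return not self.mass_fraction

    def _validate(self) -> None:
        for frac in (self.mass_fraction, self.atom_fraction):
            if abs(sum(frac.values()) - 1.0) > _FRACTION_TOL:
                raise ValueError(f"{self.name}: fractions do not sum to 1")

    def number_densities(self) -> dict[str, float]:
        """Per-element atom number densities N_i = rho w_i N_A / A_i (1/cm^3)."""
        if self.is_vacuum:
            return {}
        if self.density <= 0:
            raise ValueError(f"{self.name}: missing density")
        return {
            sym: self.density * w * N_AVOGADRO / ELEMENTS[sym].A_r
            for sym, w in self.mass_fraction.items()
        }

    def electron_density(self) -> float:
        """Electrons per cm^3 (for Compton macroscopic cross sections)."""
        return sum(n * ELEMENTS[sym].Z for sym, n in self.number_densities().items())


def number_densities(material: Material) -> dict[str, float]:
    """Functional alias for :meth:`Material.number_densities`."""
    return material.number_densities()


class MaterialTable:
    """Indexed collection of materials (by integer id and by name)."""

    def __init__(self, materials: list[Material]):
        self.by_id: dict[int, Material] = {m.material_id: m for m in materials}
        self.by_name: dict[str, Material] = {m.name: m for m in materials}
        if len(self.by_id) != len(materials):
            raise ValueError("duplicate material ids")

    def __getitem__(self, key: int | str) -> Material:
        return self.by_name[key] if isinstance(key, str) else self.by_id[key]

    def __contains__(self, key: int | str) -> bool:
        return key in (self.by_name if isinstance(key, str) else self.by_id)

    def __iter__(self):
        return iter(self.by_id.values())

    def __len__(self) -> int:
        return len(self.by_id)


def _parse_composition(text: str) -> dict[str, float]:
    comp = {}
    for item in text.split(","):
        sym, val = item.split(":")
        comp[sym.strip()] = float(val)
    return comp


def load_materials(path: str | Path | None = None) -> MaterialTable:
    """Load the packaged material table, or a user file in the same format.

    Tab-separated columns: id, name, density (g/cm^3), state, comp_type
    (``mass`` or ``atom``), composition as ``El:frac`` pairs joined by commas
    (``-`` for vacuum).
    """
    if path is None:
        text = resources.files("neutronplan.data").joinpath("materials.tsv").read_text()
    else:
        text = Path(path).read_text()
    mats: list[Material] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mid, name, rho, state, ctype, comp = line.split("\t")
        mid, rho = int(mid), float(rho)
        if comp == "-":
            mats.append(Material.vacuum(mid, name))
        elif ctype == "mass":
            mats.append(Material.from_mass_fractions(mid, name, rho, _parse_composition(comp), state))
        elif ctype == "atom":
            mats.append(Material.from_atom_ratio(mid, name, rho, _parse_composition(comp), state))
        else:
            raise ValueError(f"unknown composition type {ctype!r}")
    return MaterialTable(mats)
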