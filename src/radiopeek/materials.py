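"""Materials: chemical formulas, compositions, mixtures and the study set.

A :class:`Material` couples a named elemental composition (weight fractions)
with a bulk density.  Composites are described by a :class:`MixtureSpec`
(matrix + filler + filler weight fraction); the rule of mixtures

    rho_mix = f * rho_filler + (1 - f) * rho_matrix

is exposed as :func:`mixture_density`.  Note that the densities used for the
study composites are carried as authoritative inputs on the material
definitions themselves and do not all satisfy the rule of mixtures at
20 wt% — the rule is provided as a utility, not used to derive them.

The six study materials (cortical bone, pure PEEK, and PEEK with 20 wt%
hydroxyapatite, BaSO4, Bi2O3 or Ta) ship as a packaged YAML file and are
available through :func:`study_materials`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .elements import ELEMENTS, Element, get_element
from .errors import DomainError, FormulaError

__all__ = [
    "Composition",
    "Material",
    "MixtureSpec",
    "parse_formula",
    "weight_fractions",
    "atom_fractions",
    "mixture_density",
    "mix_compositions",
    "load_materials",
    "save_materials",
    "study_materials",
    "STUDY_MATERIAL_NAMES",
]

_SUM_TOL = 1e-9


class Composition(dict):
    """Mapping element symbol -> weight fraction, validated to sum to 1.

    Behaves as a plain ``dict`` with construction-time validation: every
    fraction must lie in (0, 1] and the fractions must sum to 1 within 1e-9.
    """

    def __init__(self, fractions: dict[str, float]):
        if not fractions:
            raise DomainError("composition must contain at least one element")
        for sym, w in fractions.items():
            get_element(sym)  # raises on unknown symbols
            if not (0.0 < w <= 1.0):
                raise DomainError(
                    f"weight fraction for {sym} must be in (0, 1], got {w}"
                )
        total = sum(fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise DomainError(f"weight fractions must sum to 1, got {total!r}")
        super().__init__(fractions)

    @property
    def elements(self) -> list[Element]:
        return [get_element(sym) for sym in self]


@dataclass(frozen=True)
class Material:
    """A named material: composition + bulk density (+ optional metadata)."""

    name: str
    composition: Composition
    density: float  # g/cm3
    elastic_modulus: float | None = None  # GPa, carried as metadata only

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError(f"density must be > 0, got {self.density}")


@dataclass(frozen=True)
class MixtureSpec:
    """A two-component mixture: matrix + filler at filler weight fraction f."""

    matrix: Material
    filler: Material
    filler_weight_fraction: float

    def __post_init__(self) -> None:
        f = self.filler_weight_fraction
        if not (0.0 <= f <= 1.0):
            raise DomainError(f"filler weight fraction must be in [0, 1], got {f}")


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Expand a chemical formula into integer element counts.

    Supports element symbols, digit multipliers and parenthesized groups,
    e.g. ``"Ca10(PO4)6(OH)2"`` -> ``{"Ca": 10, "P": 6, "O": 26, "H": 2}``.

    Raises
    ------
    FormulaError
        On unparsable tokens or unknown element symbols; the error names the
        offending character position.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula", 0)
    stack: list[dict[str, int]] = [{}]
    pos = 0
    n = len(formula)
    while pos < n:
        ch = formula[pos]
        if ch == "(":
            stack.append({})
            pos += 1
            continue
        if ch == ")":
            if len(stack) == 1:
                raise FormulaError("unmatched ')'", pos)
            group = stack.pop()
            pos += 1
            m = re.match(r"\d+", formula[pos:])
            mult = int(m.group(0)) if m else 1
            if m:
                pos += m.end()
            for sym, cnt in group.items():
                stack[-1][sym] = stack[-1].get(sym, 0) + cnt * mult
            continue
        m = re.match(r"([A-Z][a-z]?)(\d*)", formula[pos:])
        if not m:
            raise FormulaError(f"unparsable token {ch!r}", pos)
        sym = m.group(1)
        if sym not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r}", pos)
        cnt = int(m.group(2)) if m.group(2) else 1
        if cnt < 1:
            raise FormulaError(f"count must be >= 1 for {sym}", pos)
        stack[-1][sym] = stack[-1].get(sym, 0) + cnt
        pos += m.end()
    if len(stack) != 1:
        raise FormulaError("unmatched '('", n - 1)
    if not stack[0]:
        raise FormulaError("formula contains no elements", 0)
    return stack[0]


def weight_fractions(counts: dict[str, int]) -> Composition:
    """Convert stoichiometric counts to a weight-fraction composition.

    ``w_i = n_i A_i / sum_j n_j A_j``.
    """
    if not counts:
        raise DomainError("counts must be nonempty")
    masses = {sym: n * get_element(sym).A for sym, n in counts.items()}
    total = sum(masses.values())
    return Composition({sym: m / total for sym, m in masses.items()})


def atom_fractions(comp: Composition) -> dict[str, float]:
    """Number-of-atoms fractions ``f_i = (w_i/A_i) / sum_j (w_j/A_j)``."""
    per_mole = {sym: w / get_element(sym).A for sym, w in comp.items()}
    total = sum(per_mole.values())
    return {sym: v / total for sym, v in per_mole.items()}


def mixture_density(spec: MixtureSpec) -> float:
    """Rule-of-mixtures density: ``f*rho_filler + (1-f)*rho_matrix`` (g/cm3)."""
    f = spec.filler_weight_fraction
    return f * spec.filler.density + (1.0 - f) * spec.matrix.density


def mix_compositions(spec: MixtureSpec) -> Composition:
    """Weight-fraction composition of a matrix/filler mixture.

    ``w_e(mix) = f*w_e(filler) + (1-f)*w_e(matrix)``; preserves the sum-to-1
    invariant for any f in [0, 1].
    """
    f = spec.filler_weight_fraction
    out: dict[str, float] = {}
    for sym, w in spec.matrix.composition.items():
        out[sym] = out.get(sym, 0.0) + (1.0 - f) * w
    for sym, w in spec.filler.composition.items():
        out[sym] = out.get(sym, 0.0) + f * w
    # drop exact zeros (f = 0 or 1 endpoints)
    out = {sym: w for sym, w in out.items() if w > 0.0}
    return Composition(out)


# ---------------------------------------------------------------------------
# YAML schema: a list of entries
#   {name, density_g_cm3, formula | weight_fractions | mixture,
#    elastic_modulus_GPa?}
# where mixture = {matrix: <entry name>, filler_formula, filler_weight_fraction}
# resolved at load time so composite compositions keep full precision.
# ---------------------------------------------------------------------------


def _material_from_entry(entry: dict, resolved: dict[str, Material]) -> Material:
    name = entry["name"]
    density = float(entry["density_g_cm3"])
    modulus = entry.get("elastic_modulus_GPa")
    if "formula" in entry:
        comp = weight_fractions(parse_formula(entry["formula"]))
    elif "weight_fractions" in entry:
        comp = Composition({k: float(v) for k, v in entry["weight_fractions"].items()})
    elif "mixture" in entry:
        mx = entry["mixture"]
        matrix = resolved[mx["matrix"]]
        filler = Material(
            name=mx.get("filler_name", "filler"),
            composition=weight_fractions(parse_formula(mx["filler_formula"])),
            density=float(mx.get("filler_density_g_cm3", 1.0)),
        )
        spec = MixtureSpec(matrix, filler, float(mx["filler_weight_fraction"]))
        comp = mix_compositions(spec)
    else:
        raise DomainError(
            f"material entry {name!r} needs formula, weight_fractions or mixture"
        )
    return Material(name, comp, density,
                    float(modulus) if modulus is not None else None)


def load_materials(path_or_stream) -> dict[str, Material]:
    """Load materials from a YAML file (path or open stream)."""
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(path_or_stream)
    entries = doc["materials"] if isinstance(doc, dict) else doc
    out: dict[str, Material] = {}
    for entry in entries:
        mat = _material_from_entry(entry, out)
        out[mat.name] = mat
    return out


def save_materials(materials: dict[str, Material], path) -> None:
    """Write materials to YAML using explicit weight fractions."""
    entries = []
    for mat in materials.values():
        entry: dict = {
            "name": mat.name,
            "density_g_cm3": mat.density,
            "weight_fractions": {k: float(v) for k, v in mat.composition.items()},
        }
        if mat.elastic_modulus is not None:
            entry["elastic_modulus_GPa"] = mat.elastic_modulus
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump({"materials": entries}, fh, sort_keys=False)


STUDY_MATERIAL_NAMES = (
    "bone",
    "PEEK",
    "PEEK-HA",
    "PEEK-BaSO4",
    "PEEK-Bi2O3",
    "PEEK-Ta",
)


def study_materials() -> dict[str, Material]:
    """The six study materials, loaded from the packaged YAML definition."""
    ref = resources.files("radiopeek").joinpath("data/materials.yaml")
    with ref.open() as fh:
        return load_materials(fh)
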