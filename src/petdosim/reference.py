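"""Reference data: nuclide physics, phantom organ masses, S-value tables and
ICRP tissue-weighting schemes.

All reference data are shipped as versioned plain-text fixtures under
``petdosim/data`` and validated on load:

* ``nuclide.json`` -- decay data for the positron emitter (Ga-68 by default),
* ``phantom_<sex>.csv`` -- reference adult phantom organ masses (g),
* ``svalues_<sex>.csv`` -- S(target <- source) in mGy/(MBq.h); the shipped
  tables are approximate (generated by ``scripts/generate_svalue_fixtures.py``
  from the sphere self-dose formalism plus a uniform photon cross-dose bath);
  user-supplied tables in the same dialect can replace them,
* ``weights_icrp60.json`` / ``weights_icrp103.json`` -- tissue weighting
  factors, remainder rules and surrogate maps.

Organ names are lower-snake-cased phantom vocabulary ("uli_wall",
"lli_wall", ...); :func:`canonical_organ` maps common synonyms onto it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .constants import LN2

__all__ = [
    "Nuclide",
    "Phantom",
    "SValueTable",
    "WeightingScheme",
    "ReferenceBundle",
    "load_reference_bundle",
    "lookup_s",
    "canonical_organ",
    "REMAINDER_OF_BODY",
    "TOTAL_BODY",
]

REMAINDER_OF_BODY = "remainder_of_body"
TOTAL_BODY = "total_body"

#: organs present only in one sex's phantom
SEX_SPECIFIC_ORGANS = {"testes", "prostate", "ovaries", "uterus"}

_ALIASES = {
    "whole_body": TOTAL_BODY,
    "body": TOTAL_BODY,
    "uli": "uli_wall",
    "upper_large_intestine": "uli_wall",
    "lli": "lli_wall",
    "lower_large_intestine": "lli_wall",
    "stomach": "stomach_wall",
    "heart": "heart_wall",
    "gallbladder": "gallbladder_wall",
    "bone_surfaces": "osteogenic_cells",
    "bone_surface": "osteogenic_cells",
    "bladder": "urinary_bladder_contents",
    "urinary_bladder": "urinary_bladder_contents",
    "bladder_wall": "urinary_bladder_wall",
    "bone_marrow": "red_marrow",
    "marrow": "red_marrow",
    "breast": "breasts",
    "lung": "lungs",
    "kidney": "kidneys",
    "choroid_plexus": "choroid_plexuses",
}


def canonical_organ(name: str) -> str:
    """Map an organ name or common synonym onto the canonical vocabulary."""
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    return _ALIASES.get(key, key)


class ReferenceDataError(ValueError):
    """Raised when a reference fixture fails validation."""


@dataclass(frozen=True)
class Nuclide:
    """Decay data for a positron-emitting nuclide.

    ``delta_np_mev`` is the mean non-penetrating energy emitted per decay
    (beta+ spectrum mean plus Auger/conversion electrons); ``photon_lines``
    are (yield per decay, energy MeV) pairs including the annihilation
    photons; ``beta_plus_branches`` are (yield, endpoint MeV) pairs used by
    the sphere model's spectrum-weighted electron absorbed fraction.
    """

    name: str
    half_life_h: float
    lambda_phys: float
    delta_np_mev: float
    photon_lines: tuple = ()
    beta_plus_branches: tuple = ()

    def __post_init__(self):
        if self.half_life_h <= 0:
            raise ReferenceDataError("half-life must be positive")
        if abs(self.lambda_phys * self.half_life_h - LN2) > 1e-12 * LN2:
            raise ReferenceDataError(
                "lambda_phys inconsistent with half-life (lambda*T != ln 2)"
            )
        for y, e in tuple(self.photon_lines) + tuple(self.beta_plus_branches):
            if y <= 0 or e <= 0:
                raise ReferenceDataError("yields and energies must be positive")

    @classmethod
    def from_json(cls, payload: dict) -> "Nuclide":
        half_life = float(payload["half_life_h"])
        lam = float(payload.get("lambda_phys_per_h", LN2 / half_life))
        return cls(
            name=payload["name"],
            half_life_h=half_life,
            lambda_phys=lam,
            delta_np_mev=float(payload["delta_np_mev"]),
            photon_lines=tuple((float(y), float(e)) for y, e in payload["photon_lines"]),
            beta_plus_branches=tuple(
                (float(y), float(e)) for y, e in payload.get("beta_plus_branches", ())
            ),
        )


@dataclass(frozen=True)
class Phantom:
    """Reference adult phantom: organ masses in grams."""

    name: str
    organ_masses: dict = field(default_factory=dict)
    total_body_mass: float = 0.0

    def __post_init__(self):
        if self.total_body_mass <= 0:
            raise ReferenceDataError("total body mass must be positive")
        for organ, mass in self.organ_masses.items():
            if mass <= 0:
                raise ReferenceDataError(f"non-positive mass for {organ}")
        explicit = sum(m for o, m in self.organ_masses.items() if o != TOTAL_BODY)
        if explicit >= self.total_body_mass:
            raise ReferenceDataError("sum of organ masses must be below total body mass")

    def mass(self, organ: str) -> float:
        organ = canonical_organ(organ)
        if organ == TOTAL_BODY:
            return self.total_body_mass
        try:
            return self.organ_masses[organ]
        except KeyError:
            raise ReferenceDataError(f"no mass entry for organ {organ!r} in {self.name}")

    @property
    def sex(self) -> str:
        return "female" if self.name.endswith("female") else "male"


@dataclass(frozen=True)
class SValueTable:
    """S(target <- source) matrix in mGy/(MBq.h) for one phantom."""

    phantom: str
    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        for (target, source), s in self.entries.items():
            if s < 0:
                raise ReferenceDataError(f"negative S value for ({target} <- {source})")

    @property
    def targets(self) -> set:
        return {t for t, _ in self.entries}

    @property
    def sources(self) -> set:
        return {s for _, s in self.entries}


def lookup_s(table: SValueTable, target: str, source: str) -> float:
    """Exact S-value lookup (no interpolation).

    ``remainder_of_body`` is not stored: its corrected S value depends on
    which sources are explicit and is computed by the dose engine
    (:func:`petdosim.mird.remainder_svalue`).
    """
    target = canonical_organ(target)
    source = canonical_organ(source)
    try:
        return table.entries[(target, source)]
    except KeyError:
        if source == REMAINDER_OF_BODY:
            raise KeyError(
                "remainder_of_body S values are derived, not stored; "
                "use petdosim.mird.remainder_svalue"
            )
        raise KeyError(f"no S value for ({target} <- {source}) in {table.phantom}")


@dataclass(frozen=True)
class WeightingScheme:
    """ICRP tissue weighting factors with remainder and surrogate rules."""

    name: str
    weights: dict
    remainder_tissues: tuple
    remainder_rule: str
    surrogate_map: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ReferenceDataError(
                f"{self.name}: tissue weights sum to {total!r}, expected 1.0"
            )
        if self.remainder_rule not in ("mass_weighted", "arithmetic_mean"):
            raise ReferenceDataError(f"unknown remainder rule {self.remainder_rule!r}")

    @property
    def named_tissues(self) -> tuple:
        return tuple(t for t in self.weights if t != "remainder")

    @classmethod
    def from_json(cls, payload: dict) -> "WeightingScheme":
        return cls(
            name=payload["name"],
            weights={k: float(v) for k, v in payload["weights"].items()},
            remainder_tissues=tuple(payload["remainder_tissues"]),
            remainder_rule=payload["remainder_rule"],
            surrogate_map=dict(payload.get("surrogate_map", {})),
        )


@dataclass(frozen=True)
class ReferenceBundle:
    nuclide: Nuclide
    phantoms: dict          # sex -> Phantom
    svalue_tables: dict     # sex -> SValueTable
    weighting_schemes: dict # name -> WeightingScheme


#: composite scheme tissues resolved by the effective-dose module
_COMPOSITE_TISSUES = {"colon", "gonads", "remainder"}


def _tissue_resolves(tissue: str, scheme: WeightingScheme, phantoms: dict) -> bool:
    if tissue in _COMPOSITE_TISSUES:
        return True
    target = scheme.surrogate_map.get(tissue, tissue)
    return any(target in p.organ_masses for p in phantoms.values())


def load_reference_bundle(path: str | Path | None = None) -> ReferenceBundle:
    """Load and cross-validate the full reference bundle.

    ``path`` defaults to the packaged fixtures.  Any unresolved cross
    reference (organ named in an S table without a phantom mass, scheme
    tissue that resolves to nothing) is an error.
    """
    if path is None:
        base = resources.files("petdosim") / "data"
    else:
        base = Path(path)
        if not base.is_dir():
            raise ReferenceDataError(f"reference bundle directory not found: {base}")

    def _read_text(name: str) -> str:
        f = base / name
        try:
            return f.read_text()
        except (FileNotFoundError, OSError):
            raise ReferenceDataError(f"missing reference fixture: {name}")

    nuclide = Nuclide.from_json(json.loads(_read_text("nuclide.json")))

    phantoms = {}
    for sex in ("male", "female"):
        masses = {}
        total = None
        for row in csv.DictReader(_read_text(f"phantom_{sex}.csv").splitlines()):
            organ = canonical_organ(row["organ"])
            mass = float(row["mass_g"])
            if organ == TOTAL_BODY:
                total = mass
            else:
                masses[organ] = mass
        if total is None:
            raise ReferenceDataError(f"phantom_{sex}.csv lacks a total_body row")
        phantoms[sex] = Phantom(name=f"adult_{sex}", organ_masses=masses, total_body_mass=total)

    tables = {}
    for sex in ("male", "female"):
        entries = {}
        for row in csv.DictReader(_read_text(f"svalues_{sex}.csv").splitlines()):
            key = (canonical_organ(row["target"]), canonical_organ(row["source"]))
            entries[key] = float(row["S_mGy_per_MBqh"])
        table = SValueTable(phantom=f"adult_{sex}", entries=entries)
        phantom = phantoms[sex]
        for organ in table.targets | table.sources:
            if organ != TOTAL_BODY and organ not in phantom.organ_masses:
                raise ReferenceDataError(
                    f"organ {organ!r} in svalues_{sex}.csv has no mass in phantom_{sex}.csv"
                )
        tables[sex] = table

    schemes = {}
    for stem in ("weights_icrp60", "weights_icrp103"):
        scheme = WeightingScheme.from_json(json.loads(_read_text(stem + ".json")))
        for tissue in scheme.named_tissues + scheme.remainder_tissues:
            if not _tissue_resolves(tissue, scheme, phantoms):
                raise ReferenceDataError(
                    f"{scheme.name}: tissue {tissue!r} resolves to no phantom organ or surrogate"
                )
        schemes[scheme.name] = scheme

    return ReferenceBundle(
        nuclide=nuclide, phantoms=phantoms, svalue_tables=tables, weighting_schemes=schemes
    )


def write_reference_bundle(bundle: ReferenceBundle, path: str | Path) -> None:
    """Write a bundle back to the fixture dialect (round-trip safe)."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    nuclide = bundle.nuclide
    (base / "nuclide.json").write_text(
        json.dumps(
            {
                "name": nuclide.name,
                "half_life_h": nuclide.half_life_h,
                "lambda_phys_per_h": nuclide.lambda_phys,
                "delta_np_mev": nuclide.delta_np_mev,
                "photon_lines": [list(x) for x in nuclide.photon_lines],
                "beta_plus_branches": [list(x) for x in nuclide.beta_plus_branches],
            },
            indent=1,
        )
    )
    for sex, phantom in bundle.phantoms.items():
        lines = ["organ,mass_g"]
        for organ, mass in phantom.organ_masses.items():
            lines.append(f"{organ},{mass!r}")
        lines.append(f"total_body,{phantom.total_body_mass!r}")
        (base / f"phantom_{sex}.csv").write_text("\n".join(lines) + "\n")
    for sex, table in bundle.svalue_tables.items():
        lines = ["target,source,S_mGy_per_MBqh"]
        for (target, source), s in table.entries.items():
            lines.append(f"{target},{source},{s!r}")
        (base / f"svalues_{sex}.csv").write_text("\n".join(lines) + "\n")
    for scheme in bundle.weighting_schemes.values():
        stem = "weights_icrp60" if scheme.name == "ICRP60" else "weights_icrp103"
        (base / f"{stem}.json").write_text(
            json.dumps(
                {
                    "name": scheme.name,
                    "weights": scheme.weights,
                    "remainder_tissues": list(scheme.remainder_tissues),
                    "remainder_rule": scheme.remainder_rule,
                    "surrogate_map": scheme.surrogate_map,
                },
                indent=1,
            )
        )
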