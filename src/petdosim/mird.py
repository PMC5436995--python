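"""MIRD-schema dose engine: residence times x S values -> organ absorbed doses.

Absorbed dose to target T per unit administered activity:

    D_T = sum_S tau_S * S(T <- S)  +  tau_rob * S(T <- rob)

where activity not assigned to any explicit source region forms the
"remainder of body" (rob).  Its residence time is the whole-body residence
time minus the explicit organ sum, and its S value follows the standard
total-body correction

    S(T <- rob) = [ M_TB * S(T <- TB) - sum_S M_S * S(T <- S) ] / M_rob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reference import Phantom, SValueTable, TOTAL_BODY, canonical_organ, lookup_s
from .tac import ResidenceTimeSet

__all__ = [
    "DoseReport",
    "remainder_tau",
    "remainder_svalue",
    "organ_doses",
    "rank_targets",
]


@dataclass(frozen=True)
class DoseReport:
    """Per-target absorbed doses (mGy/MBq) with provenance."""

    phantom: str
    per_target: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for organ, dose in self.per_target.items():
            if dose < 0:
                raise ValueError(f"negative dose for {organ}")
            clean[canonical_organ(organ)] = float(dose)
        object.__setattr__(self, "per_target", clean)

    def __getitem__(self, organ: str) -> float:
        return self.per_target[canonical_organ(organ)]

    def __contains__(self, organ: str) -> bool:
        return canonical_organ(organ) in self.per_target


def remainder_tau(taus: ResidenceTimeSet) -> float:
    """Residence time of activity not assigned to an explicit source organ."""
    if TOTAL_BODY not in taus.taus:
        raise ValueError("whole-body residence time is required for the remainder")
    tau_wb = taus.taus[TOTAL_BODY]
    explicit = sum(t for o, t in taus.taus.items() if o != TOTAL_BODY)
    rob = tau_wb - explicit
    if rob < -1e-12 * max(tau_wb, 1.0):
        raise ValueError(
            f"explicit organ residence times ({explicit:.4g} h) exceed the "
            f"whole-body value ({tau_wb:.4g} h)"
        )
    return max(rob, 0.0)


def remainder_svalue(
    table: SValueTable, phantom: Phantom, target: str, sources
) -> float:
    """Corrected S(target <- remainder_of_body) for a given explicit source set."""
    target = canonical_organ(target)
    sources = [canonical_organ(s) for s in sources if canonical_organ(s) != TOTAL_BODY]
    m_tb = phantom.total_body_mass
    m_rob = m_tb - sum(phantom.mass(s) for s in sources)
    if m_rob <= 0:
        raise ValueError("source organ masses exhaust the total body mass")
    num = m_tb * lookup_s(table, target, TOTAL_BODY)
    for s in sources:
        num -= phantom.mass(s) * lookup_s(table, target, s)
    return max(num / m_rob, 0.0)


def organ_doses(
    taus: ResidenceTimeSet,
    table: SValueTable,
    phantom: Phantom,
    provenance: dict | None = None,
) -> DoseReport:
    """Apply the MIRD schema to a residence-time set.

    Every target in the S table receives a dose.  If the set carries a
    whole-body residence time, unassigned activity is treated as the
    remainder of body; otherwise only explicit sources contribute.
    """
    sources = [o for o in taus.taus if o != TOTAL_BODY]
    for s in sources:
        if s not in table.sources:
            raise KeyError(f"source region {s!r} has no S entries in {table.phantom}")
    tau_rob = remainder_tau(taus) if TOTAL_BODY in taus.taus else 0.0

    doses = {}
    for target in sorted(table.targets):
        d = sum(taus.taus[s] * lookup_s(table, target, s) for s in sources)
        if tau_rob > 0.0:
            d += tau_rob * remainder_svalue(table, phantom, target, sources)
        doses[target] = d
    prov = dict(provenance or {})
    prov.setdefault("s_table", table.phantom)
    prov.setdefault("sources", sorted(sources))
    prov.setdefault("remainder_tau_h", tau_rob)
    return DoseReport(phantom=phantom.name, per_target=doses, provenance=prov)


#: rows excluded from the standard-organ ranking
_NON_STANDARD = {"choroid_plexuses", TOTAL_BODY}


def rank_targets(report: DoseReport, standard_only: bool = True) -> list:
    """Targets ordered by decreasing dose; ties broken lexicographically.

    ``standard_only`` drops sphere-model extras (choroid plexuses) and the
    total-body row, mirroring the "standard organs" ranking convention.
    """
    if not report.per_target:
        raise ValueError("empty dose report")
    items = [
        (organ, dose)
        for organ, dose in report.per_target.items()
        if not (standard_only and organ in _NON_STANDARD)
    ]
    return sorted(items, key=lambda od: (-od[1], od[0]))
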