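"""ICRP60 / ICRP103 effective dose from organ-dose reports.

For photon/positron emitters the radiation weighting factor is 1, so organ
equivalent doses H_T (mSv/MBq) equal absorbed doses D_T (mGy/MBq).  The
effective dose is ED = sum_T w_T * H_T with scheme-specific rules:

* colon: mass-weighted combination of ULI and LLI wall doses;
* tissues absent from the phantom resolve through a documented surrogate
  map (esophagus <- thymus; salivary glands and oral mucosa <- brain);
* ICRP60 remainder: mass-weighted mean of the remainder tissues, with the
  splitting rule (if one remainder tissue exceeds every named tissue, half
  the remainder weight goes to it and half to the mass-weighted rest);
* ICRP103 remainder: arithmetic mean of the remainder tissues available in
  the phantom (sex-specific organs enter only for the matching sex);
* reference person: per-tissue sex average of male and female equivalent
  doses (gonads average testes and ovaries), then the weighted sum.

Sex-specific EDs under ICRP103 are non-standard (the quantity is defined
for the reference person only) but are reported for comparability and
labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mird import DoseReport
from .reference import Phantom, WeightingScheme, canonical_organ
from .tac import ResidenceTimeSet

__all__ = [
    "EDResult",
    "equivalent_doses",
    "effective_dose",
    "extrapolate_female",
    "reference_person_ed",
    "ed_increment",
    "total_ed_for_administration",
]


class TissueResolutionError(KeyError):
    pass


@dataclass(frozen=True)
class EDResult:
    """Effective dose (mSv/MBq) and its per-tissue contributions w_T * H_T."""

    scheme: str
    sex: str
    ed: float
    per_tissue_contributions: dict = field(default_factory=dict)
    voiding_interval_h: float | None = None

    def __post_init__(self):
        if self.ed < 0:
            raise ValueError("effective dose must be non-negative")
        total = sum(self.per_tissue_contributions.values())
        if abs(total - self.ed) > 1e-12 * max(self.ed, 1.0):
            raise ValueError("per-tissue contributions do not sum to the ED")


def _colon_dose(report: DoseReport, phantom: Phantom) -> float:
    m_uli, m_lli = phantom.mass("uli_wall"), phantom.mass("lli_wall")
    return (m_uli * report["uli_wall"] + m_lli * report["lli_wall"]) / (m_uli + m_lli)


def _gonad_organ(phantom: Phantom) -> str:
    return "ovaries" if phantom.sex == "female" else "testes"


def _resolve(tissue: str, report: DoseReport, phantom: Phantom, scheme: WeightingScheme):
    """Equivalent dose of one scheme tissue, or None if unavailable in this sex."""
    tissue = canonical_organ(tissue)
    if tissue == "colon":
        return _colon_dose(report, phantom)
    if tissue == "gonads":
        tissue = _gonad_organ(phantom)
    organ = scheme.surrogate_map.get(tissue, tissue)
    if organ in report:
        return report[organ]
    if organ in {"testes", "ovaries", "uterus", "prostate"}:
        return None  # sex-specific organ absent from this phantom
    raise TissueResolutionError(
        f"tissue {tissue!r} resolves to {organ!r}, absent from the dose report"
    )


def equivalent_doses(
    report: DoseReport, phantom: Phantom, scheme: WeightingScheme
) -> dict:
    """Map scheme tissue -> equivalent dose H_T (mSv/MBq).

    Includes both the named tissues and the remainder tissues available in
    this phantom; the "remainder" entry itself is composed later by
    :func:`effective_dose` (its rule needs organ masses).
    """
    if not report.per_target:
        raise ValueError("empty dose report")
    h = {}
    for tissue in scheme.named_tissues + scheme.remainder_tissues:
        val = _resolve(tissue, report, phantom, scheme)
        if val is not None:
            h[tissue] = val
    return h


def _remainder_dose(
    h: dict, scheme: WeightingScheme, phantom: Phantom
) -> tuple[float, bool]:
    """(remainder equivalent dose, whether the ICRP60 splitting rule fired)."""
    avail = [t for t in scheme.remainder_tissues if t in h]
    if not avail:
        raise TissueResolutionError("no remainder tissue available")
    if scheme.remainder_rule == "arithmetic_mean":
        return sum(h[t] for t in avail) / len(avail), False

    def mass_of(t):
        return phantom.mass(scheme.surrogate_map.get(t, t))

    def mass_weighted(tissues):
        mtot = sum(mass_of(t) for t in tissues)
        return sum(mass_of(t) * h[t] for t in tissues) / mtot

    named_max = max(h[t] for t in scheme.named_tissues if t in h)
    hottest = max(avail, key=lambda t: h[t])
    if h[hottest] > named_max and len(avail) > 1:
        # ICRP60 footnote: split the remainder weight between the single
        # hottest remainder tissue and the mass-weighted rest
        rest = [t for t in avail if t != hottest]
        return 0.5 * h[hottest] + 0.5 * mass_weighted(rest), True
    return mass_weighted(avail), False


def effective_dose(
    h: dict,
    scheme: WeightingScheme,
    phantom: Phantom,
    sex: str | None = None,
    voiding_interval_h: float | None = None,
) -> EDResult:
    """Weighted sum of equivalent doses under one ICRP scheme."""
    contributions = {}
    for tissue in scheme.named_tissues:
        if tissue not in h:
            raise TissueResolutionError(f"named tissue {tissue!r} missing from map")
        contributions[tissue] = scheme.weights[tissue] * h[tissue]
    h_rem, _split = _remainder_dose(h, scheme, phantom)
    contributions["remainder"] = scheme.weights["remainder"] * h_rem
    ed = sum(contributions.values())
    return EDResult(
        scheme=scheme.name,
        sex=sex or phantom.sex,
        ed=ed,
        per_tissue_contributions=contributions,
        voiding_interval_h=voiding_interval_h,
    )


def extrapolate_female(
    taus_male: ResidenceTimeSet,
    table_female,
    phantom_female: Phantom,
    provenance: dict | None = None,
) -> DoseReport:
    """Push male residence times through the female phantom's S table.

    Male-only organs disappear from the target list and female organs
    (ovaries, uterus) appear, as dictated by the female table's vocabulary.
    """
    from .mird import organ_doses

    prov = dict(provenance or {})
    prov["extrapolated_from"] = "male residence times"
    return organ_doses(taus_male, table_female, phantom_female, provenance=prov)


def reference_person_ed(
    h_male: dict,
    h_female: dict,
    scheme: WeightingScheme,
    phantom_male: Phantom,
    phantom_female: Phantom,
    voiding_interval_h: float | None = None,
) -> EDResult:
    """ICRP103 reference-person ED: sex-averaged equivalent doses, then weights."""
    contributions = {}
    for tissue in scheme.named_tissues:
        vals = [m[tissue] for m in (h_male, h_female) if tissue in m]
        if not vals:
            raise TissueResolutionError(f"tissue {tissue!r} missing from both sexes")
        contributions[tissue] = scheme.weights[tissue] * sum(vals) / len(vals)
    rem_m, _ = _remainder_dose(h_male, scheme, phantom_male)
    rem_f, _ = _remainder_dose(h_female, scheme, phantom_female)
    contributions["remainder"] = scheme.weights["remainder"] * 0.5 * (rem_m + rem_f)
    ed = sum(contributions.values())
    return EDResult(
        scheme=scheme.name,
        sex="reference",
        ed=ed,
        per_tissue_contributions=contributions,
        voiding_interval_h=voiding_interval_h,
    )


def ed_increment(ed_a: float, ed_b: float) -> float:
    """Percent change from ``ed_a`` to ``ed_b`` (reports round to integers)."""
    if ed_a <= 0:
        raise ValueError("baseline effective dose must be positive")
    return 100.0 * (ed_b - ed_a) / ed_a


def total_ed_for_administration(ed_coeff_msv_per_mbq: float, activity_mbq: float) -> float:
    """Total effective dose (mSv) for an administered activity."""
    if ed_coeff_msv_per_mbq < 0 or activity_mbq < 0:
        raise ValueError("inputs must be non-negative")
    return ed_coeff_msv_per_mbq * activity_mbq
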