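"""Regenerate the packaged S-value fixture tables.

The shipped ``svalues_<sex>.csv`` fixtures are approximate, generated from
first principles so the repository carries no proprietary dose kernels:

* self-dose S(T <- T): unit-density sphere of the organ mass
  (spectrum-weighted electron absorbed fraction + photon self-absorption);
* urinary bladder wall <- contents: the standard hollow-organ convention,
  wall-surface dose = half the equilibrium dose inside the contents;
* cross-dose S(T <- S), T != S: a uniform photon-bath approximation, the
  annihilation/gamma energy absorbed in the whole body spread uniformly
  over the total-body mass;
* S(T <- total_body): activity-mass-weighted mixture of self and bath terms,
  which makes the standard remainder-of-body correction exactly consistent;
* S(total_body <- S): all non-penetrating energy plus the body-absorbed
  photon fraction over the total-body mass.

Run from the repository root:  python scripts/generate_svalue_fixtures.py
"""

import csv
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from petdosim.reference import Nuclide, TOTAL_BODY  # noqa: E402
from petdosim.spheres import (  # noqa: E402
    _unchecked_self_svalue,
    electron_absorbed_fraction,
    photon_absorbed_fraction,
)
from petdosim.constants import MEV_PER_DECAY_TO_MGY  # noqa: E402

DATA = ROOT / "src" / "petdosim" / "data"

WALLED = {"urinary_bladder_wall": "urinary_bladder_contents"}


def load_masses(sex):
    masses = {}
    with open(DATA / f"phantom_{sex}.csv") as fh:
        for row in csv.DictReader(fh):
            masses[row["organ"]] = float(row["mass_g"])
    return masses


def build_table(sex, nuclide):
    masses = load_masses(sex)
    m_tb = masses.pop(TOTAL_BODY)
    delta_p = sum(y * e for y, e in nuclide.photon_lines)
    phi_tb = photon_absorbed_fraction(m_tb, 0.511)
    s_bath = delta_p * phi_tb * MEV_PER_DECAY_TO_MGY / m_tb
    s_uniform = (nuclide.delta_np_mev + delta_p * phi_tb) * MEV_PER_DECAY_TO_MGY / m_tb

    organs = sorted(masses)
    targets = [o for o in organs if o != "urinary_bladder_contents"] + [TOTAL_BODY]
    sources = organs + [TOTAL_BODY]

    self_s = {o: _unchecked_self_svalue(masses[o], nuclide) for o in organs}
    # hollow-organ wall dose from contents: half the contents equilibrium dose
    phi_cont = electron_absorbed_fraction(masses["urinary_bladder_contents"], nuclide.beta_plus_branches)
    phi_cont_g = photon_absorbed_fraction(masses["urinary_bladder_contents"], 0.511)
    s_wall_from_contents = (
        0.5
        * (nuclide.delta_np_mev * phi_cont + delta_p * phi_cont_g)
        * MEV_PER_DECAY_TO_MGY
        / masses["urinary_bladder_contents"]
    )

    entries = {}
    for t in targets:
        for s in sources:
            if t == TOTAL_BODY:
                val = s_uniform
            elif s == TOTAL_BODY:
                frac = masses[t] / m_tb
                val = frac * self_s[t] + (1.0 - frac) * s_bath
            elif t == s:
                val = self_s[t]
            elif t in WALLED and s == WALLED[t]:
                val = s_wall_from_contents
            else:
                val = s_bath
            entries[(t, s)] = val
    return entries


def main():
    nuclide = Nuclide.from_json(json.loads((DATA / "nuclide.json").read_text()))
    for sex in ("male", "female"):
        entries = build_table(sex, nuclide)
        out = DATA / f"svalues_{sex}.csv"
        with open(out, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["target", "source", "S_mGy_per_MBqh"])
            for (t, s), val in sorted(entries.items()):
                writer.writerow([t, s, f"{val:.6e}"])
        print(f"wrote {out} ({len(entries)} entries)")


if __name__ == "__main__":
    main()
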