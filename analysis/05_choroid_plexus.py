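"""Sphere-model dosimetry of the choroid plexuses.

The plexuses of the lateral ventricles are absent from the reference
phantoms; their mass is estimated from bilateral cylindrical segments
(body/atrial/temporal parts) and their self-dose from the unit-density
sphere model.  Uses both the synthetic cohort's fitted residence time and
the published cohort value (3.08e-4 h) for comparison.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import json

from petdosim import load_reference_bundle, sphere_dose, sphere_self_svalue
from petdosim.io import choroid_sphere_targets, format_sci, load_clinical_reference

OUT = ROOT / "results"
bundle = load_reference_bundle()
clinical = load_clinical_reference()["summary"]["choroid_plexuses"]
tau_published = clinical["residence_time_h"]

synthetic = json.loads((OUT / "sphere_doses.json").read_text())
payload = {}
for sex, target in choroid_sphere_targets().items():
    s = sphere_self_svalue(target, bundle.nuclide)
    dose_pub_tau = sphere_dose(target, tau_published, bundle.nuclide)
    payload[sex] = {
        "cylinder_mass_g": target.mass_g,
        "self_svalue_mgy_per_mbqh": s,
        "dose_at_published_tau": dose_pub_tau,
        "dose_at_synthetic_tau": synthetic[sex]["dose_mgy_per_mbq"],
        "published_dose": clinical[f"dose_{sex}_mgy_per_mbq"],
    }
    print(f"{sex}: cylinder mass {target.mass_g:.2f} g, S = {s:.1f} mGy/(MBq.h)")
    print(f"  dose at published tau {format_sci(tau_published)} h: "
          f"{format_sci(dose_pub_tau)} mGy/MBq "
          f"(published {format_sci(clinical[f'dose_{sex}_mgy_per_mbq'])})")

(OUT / "choroid_plexus_doses.json").write_text(json.dumps(payload, indent=1))
print(f"wrote {OUT / 'choroid_plexus_doses.json'}")
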