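"""How the three claim rules differ on hand-built claim histories."""

from bonemet.datamodel import Claim
from bonemet.phenotype import Window, classify_patient

WINDOW = Window(anchor="2005-06")  # diagnosis month 2005-06

histories = {
    "inpatient, BM code 5th position": [
        Claim("P1", "inpatient", "2005-06-10", ("185", "401.9", "428.0", "250.00", "198.5")),
    ],
    "single carrier E&M visit with BM code": [
        Claim("P2", "carrier", "2005-07-02", ("198.5",), "em_visit", is_physician_em=True),
    ],
    "one unpaired outpatient BM claim": [
        Claim("P3", "outpatient", "2005-06-09", ("185", "198.5"), "other"),
    ],
    "two outpatient BM claims 79 days apart": [
        Claim("P4", "outpatient", "2005-05-02", ("198.5",), "other"),
        Claim("P4", "outpatient", "2005-07-20", ("198.5",), "other"),
    ],
    "two PSA/imaging tests, no BM code at all": [
        Claim("P5", "outpatient", "2005-06-05", ("185",), "psa_test"),
        Claim("P5", "outpatient", "2005-06-25", ("185",), "bone_joint_imaging"),
    ],
    "BM claim 14 months after diagnosis": [
        Claim("P6", "inpatient", "2006-08-10", ("198.5",)),
    ],
}

print(f"{'history':45s} a1    a2    a3    a3x   ever")
for label, claims in histories.items():
    s = classify_patient(claims[0].patient_id, claims, WINDOW.anchor)
    print(
        f"{label:45s} "
        + "  ".join(str(v)[0].ljust(4) for v in (s.a1, s.a2, s.a3, s.a3_expanded, s.bm_ever))
    )

# The generous rule (a1) accepts any BM-coded claim in the 3-month window;
# the restrictive rule (a3) needs an inpatient claim or two dated outpatient
# claims; the expanded variant (a3x) also accepts paired PSA/imaging tests
# that carry no BM diagnosis code; "ever" has no upper time bound.
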