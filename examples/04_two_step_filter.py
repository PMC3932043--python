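"""Two-step filtering of diagnostic claims.

Claims for services used to rule bone metastasis *out* should not carry the
BM diagnosis code, so diagnostic-test claims are trustworthy only when a
BM-coded claim follows soon after.  The filter keeps a diagnostic claim iff
a BM claim occurs within the next 90 days.
"""

from bonemet.datamodel import Claim
from bonemet.phenotype import two_step_diagnostic_filter

claims = [
    Claim("P1", "outpatient", "2005-06-01", ("185",), "bone_scan"),
    Claim("P1", "inpatient", "2005-07-15", ("198.5",)),  # confirms the scan (44 d)
    Claim("P1", "outpatient", "2006-01-10", ("185",), "bone_scan"),  # never confirmed
    Claim("P1", "outpatient", "2005-06-20", ("185",), "psa_test"),  # not diagnostic
]

kept = two_step_diagnostic_filter(claims)
for claim in claims:
    mark = "kept" if claim in kept else "dropped"
    print(f"{claim.service_date}  {claim.service_category:18s} {mark}")

# Only the June bone scan survives among the diagnostic claims: a BM-coded
# claim follows it within 90 days.  The January scan has no confirmation and
# is dropped; the PSA test is not a diagnostic-category claim and passes.
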