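# Code-set configuration consumed by `CodeSet.from_yaml` and the CLI's
# --codesets option.  These are the defaults; edit to swap code variants
# (e.g. undotted ICD-9) or tighten the pairing/expanded category sets.
bm_dx_codes:
  - "198.5"
pairing_categories:
  - bone_scan
  - bone_biopsy
  - iv_bisphosphonate
expanded_categories:
  - psa_test
  - bone_joint_imaging
diagnostic_categories:
  - bone_scan
  - bone_joint_imaging
  - bone_biopsy
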