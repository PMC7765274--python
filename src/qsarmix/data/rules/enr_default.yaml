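# Default screening cascade for ENR derivatives.
#
# Stage 1 keeps derivatives whose SOD (1B06) docking score increased and whose
# PPEP-2 (6FPC) score did not drop by more than 6% — a reverse-engineered
# tolerance: the published survivor set includes a derivative at -5.57% and
# excludes the next candidate at -7.90%.  Adjust `threshold` to probe it.
# Stage 2 keeps derivatives with reduced bioaccumulation (logKow) and soil
# adsorbability (logKoc).  Stage 3 keeps those whose cyanobacteria docking
# score increased (bloom-control capability).
name: enr_default
stages:
  - name: docking
    rules:
      - {property: lds_1b06_change, op: gt, threshold: 0.0}
      - {property: lds_6fpc_change, op: gt, threshold: -6.0}
  - name: environment
    rules:
      - {property: logkow_change, op: lt, threshold: 0.0}
      - {property: logkoc_change, op: lt, threshold: 0.0}
  - name: cyanobacteria
    rules:
      - {property: cyano_lds_change, op: gt, threshold: 0.0}
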