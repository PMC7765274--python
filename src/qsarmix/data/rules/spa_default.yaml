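# Default screening cascade for SPA derivatives.
#
# Both enzyme scores must strictly increase (failed docking, "/", fails the
# stage); the environment stage mirrors the ENR cascade.  No cyanobacteria
# stage is applied on this branch — the published workflow stops at the
# environment filter for SPA.
name: spa_default
stages:
  - name: docking
    rules:
      - {property: lds_1b06_change, op: gt, threshold: 0.0}
      - {property: lds_6fpc_change, op: gt, threshold: 0.0}
  - name: environment
    rules:
      - {property: logkow_change, op: lt, threshold: 0.0}
      - {property: logkoc_change, op: lt, threshold: 0.0}
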