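# Needle insertion into the small gel cylinder (lengths mm, moduli Pa).
geometry:
  kind: cylinder
  radius: 15.0
  height: 17.0
  target_nodes: 3000
materials:
  - name: sylgard-gel
    model: ogden
    a: -1.3
    mu: 722.0
    D: 5.57738e-5
needle:
  diameter: 1.6
  depth: 15.0
  eps_p: 1.0e-5
  cd: 0.4
solver:
  snapshot_depths: [5.0, 15.0]
outputs:
  directory: mtled_out
  csv: true
  vtk: true
seed: 1
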