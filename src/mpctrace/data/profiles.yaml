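paper_brain_keto:
  cv: 0.1
  diet: keto
  fold_changes:
    aspartate: 1.3
    lactate: 1.3
  kind: brain
  n_per_group: 4
paper_brain_normal:
  cv: 0.1
  diet: normal
  fold_changes:
    aspartate: 2.5
    citrate: 0.4
    fumarate: 2.0
    gaba: 0.45
    glutamate: 0.45
    glutamine: 0.45
    glutathione: 0.5
    lactate: 2.2
    malate: 2.0
    naag: 2.2
    phosphocreatine: 0.35
    proline: 2.0
    pyruvate: 2.0
    syn_0001: 2.0
    syn_0002: 0.5
    syn_0003: 2.0
    syn_0004: 0.5
    syn_0005: 2.0
    syn_0006: 0.5
    syn_0007: 2.0
    syn_0008: 0.5
    syn_0009: 2.0
    syn_0010: 0.5
    syn_0011: 2.0
    syn_0012: 0.5
    syn_0013: 2.0
    syn_0014: 0.5
    syn_0015: 2.0
    syn_0016: 0.5
    syn_0017: 2.0
    syn_0018: 0.5
    syn_0019: 2.0
    syn_0020: 0.5
    syn_0021: 2.0
    syn_0022: 0.5
    syn_0023: 2.0
    syn_0024: 0.5
    syn_0025: 2.0
    syn_0026: 0.5
    syn_0027: 2.0
    syn_0028: 0.5
    syn_0029: 2.0
    syn_0030: 0.5
    syn_0031: 2.0
    syn_0032: 0.5
    syn_0033: 2.0
  kind: brain
  n_per_group: 4
paper_mef_targeted:
  baselines:
    2_3_phosphoglycerate: 0.8
    alpha_ketoglutarate: 0.6
    aspartate: 5.0
    citrate_isocitrate: 3.0
    fumarate: 1.0
    lactate: 20.0
    malate: 2.5
    phosphoenolpyruvate: 0.3
    pyruvate: 2.0
    succinate: 1.5
  cv: 0.1
  diet: normal
  fold_changes:
    2_3_phosphoglycerate: 2.0
    alpha_ketoglutarate: 1.1
    aspartate: 4.0
    citrate_isocitrate: 0.05
    fumarate: 1.8
    lactate: 2.5
    malate: 2.0
    phosphoenolpyruvate: 2.0
    pyruvate: 3.0
    succinate: 1.2
  kind: targeted
  n_per_group: 3
paper_qpcr:
  baseline_cq:
    MPC1: 22.0
    MPC2: 21.0
  kind: qpcr
  n_per_group: 4
  noise_sd: 0.15
  reference_cq: 15.0
  reference_gene: 28S
  relative_expression:
    gt:
      MPC1: 0.05
      MPC2: 1.0
    het:
      MPC1: 0.5
      MPC2: 1.0
    wt:
      MPC1: 1.0
      MPC2: 1.0
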