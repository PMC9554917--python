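# Bundled end-to-end fixture: a small synthetic membrane-receptor system
# with programmed ground truth for every stage.
seed: 7

generate:
  system:
    n_helices: 4
    beads_per_helix: 10
    n_lipids_per_leaflet: 20
    lipid_tail_length: 6
    n_waters: 20
    box: [56.0, 56.0, 64.0]
  schedule:
    n_frames: 300
    noise_sigma: 0.05
    hbond_programs:
      - donor: {name: LN1}                 # ligand ring nitrogen
        acceptor: {name: O, residue_id: 4} # backbone carbonyl O
        target_occupancy: 0.65
    water_site_programs:
      - site_atoms: [{name: O, residue_id: 2}]
        target_occupancy: 0.51
    lipid_enrichment:
      region_lo: [4.0, 2.0, -5.0]
      region_hi: [14.0, 12.0, 5.0]
      ratio: 2.0

stages:
  rmsd: {}
  rmsf: {}
  hbonds:
    pairs:
      - label: ligand_N_to_backbone_O
        donors: [{name: LN1}]
        acceptors: [{name: O, residue_id: 4}]
  water:
    site_atoms: [{name: O, residue_id: 2}]
    mode: any
  energy:
    shell: 5.0
    cutoff: 10.0
  gfe:
    temperature: 310.0
    gfe_max: 3.0
    spacing: 2.0
    region:
      lo: [4.0, 2.0, -5.0]
      hi: [14.0, 12.0, 5.0]
  cavity:
    spacing: 0.8
    probe: 1.4
    lipid_margin: 6.0
  sasa:
    shell: 6.0
  sapt:
    fragments: synthetic_fragments.tsv
    qct: synthetic_qct.tsv
    ratios:
      - label: amides_vs_Y210_side_chain
        group: ["F154:backbone_amide", "A120:backbone_amide", "W199:backbone_amide"]
        reference: "Y210:side_chain"
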