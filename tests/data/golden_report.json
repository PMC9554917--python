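{
  "seed": 7,
  "stages": {
    "cavity": {
      "receptor_only": {
        "enclosed": false,
        "volume": 0.0
      },
      "receptor_plus_lipids": {
        "enclosed": false,
        "volume": 0.0
      }
    },
    "energy": {
      "cutoff": 10.0,
      "lipid_head_contacts": 1,
      "lipid_tail_contacts": 0,
      "n_shell_residues": 1,
      "total_mean_elec": 1.13424,
      "total_mean_vdw": 14.3334
    },
    "gfe": {
      "bulk_reference": 0.027595,
      "gfe_max": 3.0,
      "iso": -1.2,
      "region_mean_gfe": -0.360192,
      "region_rho_hat": 1.79444,
      "spacing": 2.0,
      "temperature": 310.0
    },
    "hbonds": {
      "criteria": {
        "angle_cut": 150.0,
        "d_cut": 3.2,
        "require_hydrogen": true
      },
      "pairs": {
        "ligand_N_to_backbone_O": 0.65
      }
    },
    "rmsd": {
      "ligand": {
        "kind": "rmsd",
        "mean": 0.115281,
        "n": 300,
        "reference": "frame 0",
        "sd": 0.0156295
      },
      "protein": {
        "kind": "rmsd",
        "mean": 0.117564,
        "n": 300,
        "reference": "frame 0",
        "sd": 0.0100363
      }
    },
    "rmsf": {
      "fragments": {
        "ligand": 0.083092
      },
      "protein": {
        "kind": "rmsf",
        "mean": 0.0946308,
        "n": 120,
        "reference": "time-average",
        "sd": 0.088151
      }
    },
    "sapt": {
      "best_efficiency": -1.97,
      "electrostatic_ratios": {
        "amides_vs_Y210_side_chain": {
          "percent": 170.047,
          "percent_rounded": 170
        }
      },
      "n_fragments": 5,
      "qct": {
        "A120:(O-H)Csp3": "optimal",
        "W213:N(H-Nsp2)": "optimal",
        "Y210:O(H-Nsp2)": "weak"
      }
    },
    "sasa": {
      "n_atoms": 4,
      "nonpolar_fraction": 0.30963,
      "polar_fraction": 0.69037,
      "total_sasa": 236.045
    },
    "water": {
      "mode": "any",
      "occupancy": 0.51
    }
  },
  "version": "0.1.0"
}
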