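# lipsite

Analysis toolkit for molecular-dynamics studies of **lipid-exposed
(extrahelical) allosteric sites** in membrane receptors — binding
pockets on the outer, lipid-facing surface of a helical bundle, where
negative allosteric modulators of receptors such as PAR2, C5aR1 and GCGR
bind in the middle of the bilayer.

Characterizing such a site from a trajectory requires a specific battery
of measurements, and `lipsite` packages all of them behind one library
and CLI:

- **Stability**: RMSD time series and per-atom/per-fragment RMSF after
  Kabsch superposition (receptor Cα fit; ligand heavy atoms measured).
- **Polar contacts**: geometric hydrogen-bond detection (donor–acceptor
  ≤ 3.2 Å, D–H···A ≥ 150°) and exact frame-fraction occupancies,
  including water-in-site occupancy.
- **Energetics**: pairwise Lennard-Jones + Coulomb interaction energies
  (Amber 12-6 form, k = 332.0636 kcal·Å·mol⁻¹·e⁻², hard 10 Å cutoff),
  decomposed per residue over a 5 Å shell, plus a census of lipid tails
  and head groups engaged with the ligand.
- **Lipid maps**: lipid-carbon occupancy grids converted to a grid free
  energy (GFE), written as OpenDX:

  ```
  GFE = min( −R·T · ln(occ / occ_bulk),  GFE_max )
  ```

  with T = 310 K, GFE_max = 3 kcal/mol, and occ_bulk the mean occupancy
  of membrane cells ≥ 10 Å from the protein. Maps are conventionally
  rendered at the −1.2 kcal/mol isovalue.
- **Pocket geometry**: probe-excluded voxel cavity volume computed
  receptor-only vs receptor-plus-lipids (lipid atoms within 6 Å of the
  site), which captures how lipids wall off and enlarge an otherwise
  open groove; Shrake–Rupley SASA with polar/nonpolar fractions.
- **Quantum-chemistry bookkeeping**: post-processing of tabulated
  fragment SAPT decompositions (fragment efficiency = total energy per
  heavy atom, grouped electrostatic ratios) and natural-population
  charge-transfer descriptors Q_CT classified against per-bond-class
  references (classical H-bond ≈ 0.05 au, nonclassical 10× lower).

A first-class synthetic-data module generates membrane–protein–ligand
toy systems with *programmed* ground truth — exact hydrogen-bond
occupancy schedules, prescribed lipid density enrichment ρ (so the
regional GFE has the analytic expectation −RT·ln ρ), Gaussian positional
noise — so every stage is testable against known answers. See
`docs/methods.md` for the models, conventions and limitations.

## Worked example

The bundled configuration generates a small receptor-in-membrane system
(7 bead rods, 40 lipids, 300 frames) with a 65% hydrogen-bond program
between the ligand ring nitrogen and a backbone carbonyl, a 51%
water-visit program, and 2× lipid enrichment at the pocket, then runs
every stage:

```
lipsite all --config examples/fixture.yaml --outdir out/
```

`out/report.json` then contains (abridged, as printed by the run):

```json
"hbonds":  {"pairs": {"ligand_N_to_backbone_O": 0.65}},
"water":   {"mode": "any", "occupancy": 0.51},
"gfe":     {"bulk_reference": 0.027595, "region_mean_gfe": -0.360192,
            "region_rho_hat": 1.79444, "spacing": 2.0, "temperature": 310.0},
"rmsd":    {"protein": {"mean": 0.117564, "sd": 0.0100363}},
"sapt":    {"best_efficiency": -1.97,
            "electrostatic_ratios": {"amides_vs_Y210_side_chain":
                                     {"percent": 170.047, "percent_rounded": 170}}}
```

Reading the numbers: the programmed occupancies come back exactly (0.65
and 0.51 — events are deterministic frame assignments, so recovery is
an identity check on the detector); the 300-frame lipid map estimates
the programmed 2× enrichment as ρ̂ ≈ 1.79 (regional mean GFE −0.36
kcal/mol vs the analytic −0.427 at ρ = 2; short runs carry small-count
bias, and the 2000-frame acceptance run below lands within 3 standard
errors); the protein RMSD of ~0.12 Å is pure programmed noise; and the
fragment table reproduces the published arithmetic — the three backbone
amides carry 170% of the tyrosine side chain's electrostatics, and the
most efficient fragment is a 5-heavy-atom amide at −1.97 kcal/mol per
atom.

The same numbers are available through the library:

```python
from lipsite.sapt import electrostatic_ratio
pct, pct_int = electrostatic_ratio([-5.5, -5.37, -3.72], -8.58)
# pct_int == 170
```

Every run writes a `manifest.json` with resolved parameters, input
checksums and per-stage timings; fixed config + seed reproduce all
analysis outputs byte-for-byte.

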