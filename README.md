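# sh2fp

Interaction fingerprints for SH2-domain / phosphopeptide molecular-dynamics
trajectories.

SH2 domains recognize short phosphotyrosine (pY) peptide motifs; which STAT
(or other SH2 protein) a given pY site activates is decided by a handful of
residue-level contacts around the binding groove. `sh2fp` turns a multi-frame
structure of such a complex — one PDB `MODEL` per saved MD snapshot — into a
compact, testable interaction table: which peptide residue touches which
receptor residue, through what kind of interaction, in what fraction of the
simulation, and in which part of the interface.

## What it computes

For every frame, three kinds of cross-chain contacts are detected between
the peptide (ligand chain) and the receptor chain:

| kind        | criterion                                                   |
|-------------|-------------------------------------------------------------|
| salt bridge | anionic O ··· cationic N distance ≤ 3.2 Å                   |
| hydrogen bond | donor ··· acceptor heavy atoms ≤ 3.0 Å **and** D–H···A angle ≥ 120° (distance only if the structure has no hydrogens) |
| hydrophobic | apolar heavy atoms ≤ 5.0 Å                                  |

Atomic events are collapsed to residue pairs and an **occupancy** — the
fraction of frames in which the pair is in contact. Only pairs present in
strictly more than 30 % of the frames survive the stability filter. Each
stable pair gets a single class label, ligand side first:

* `m` — only main-chain atoms involved,
* `s` — a polar side-chain atom involved (fully apolar side chains such as
  Val/Leu/Ile also report `s`),
* `hs` — only the hydrophobic part of a side chain that *has* a polar part
  (e.g. the Gln methylenes).

Peptide windows are pY-anchored: 9 residues from pY−1 to pY+7 written as
one-letter strings with a lower-case `y` for the phosphotyrosine (e.g.
`GyRPQNVLT`, residues 113–121). Ligand residues map to interface regions —
**I** (pY, pY+1), **II** (pY+2, pY+3), **III** (pY+4 …) — so the rendered
table shows at a glance whether a peptide engages only the pY pocket or the
whole groove.

A small `quant` module covers the matching wet-lab readouts: the relative
response ratio `((sample − neg)·100)/(pos − neg)` for luciferase reporters,
per-well renilla normalization, and the (phospho/total)/loading immunoblot
ratio.

Because real MD trajectories are large and rarely shareable, the package
ships a synthetic-trajectory generator (`sh2fp.synth`) that plants contacts
with known schedules, occupancies and class labels and returns the exact
ground truth alongside the coordinates — every pipeline stage is testable
without external data.

## Worked example

`examples/01_profile_synthetic_complex.py` generates a 100-frame synthetic
complex with one planted contact per interface region and profiles it:

```
flank  I         I     II    II        III   III       III   III
G113   pY114     R115  P116  Q117      N118  V119      L120  T121
-----  --------  ----  ----  --------  ----  --------  ----  ----
       K591 s-s              Y657 s-s        M648 s-s

stable interactions per region: {'I': 1, 'II': 1, 'III': 1}

  PTR114 <-> LYS591: saltbridge, class s-s, occupancy 0.90, region I
  GLN117 <-> TYR657: hbond, class s-s, occupancy 0.60, region II
  VAL119 <-> MET648: hydrophobic, class s-s, occupancy 0.45, region III
```

Reading it: the phosphotyrosine 114 forms a side-chain/side-chain salt
bridge with Lys591 in 90 % of frames (region I, the pY pocket); the pY+3
glutamine hydrogen-bonds a receptor tyrosine (region II); and the pY+5
valine makes a hydrophobic contact with a methionine (region III). Contacts
in all three regions are the signature of a tight binder. The other
examples demonstrate the detector geometry, per-pair distance time series,
and the reporter/blot quantifications.

The same pipeline is available from a shell:

```bash
sh2fp fixtures --table1-style --out-prefix demo
sh2fp profile --input demo.pdb --py-number 114 --sequence GyRPQNVLT \
      --out-table demo_table.tsv --out-summary demo_regions.tsv
sh2fp timeseries --input demo.pdb --ligand-res 117 --receptor-res 657 --out ts.csv
sh2fp quant --input wells.csv --mode reporter_rrr --out wells_rrr.csv
```

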