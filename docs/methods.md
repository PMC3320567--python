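# Methods

## Scope and model

`sh2fp` analyzes solute-only, imaged/unwrapped multi-frame structures of a
receptor chain (an SH2 domain) plus a short phosphopeptide ligand chain
containing a phosphotyrosine (residue code `PTR`). Frames are assumed evenly
spaced; the frame spacing `dt` (default 1 ps) is used only for axis labels —
occupancies are always fractions of *frames*, never of nanoseconds.

The pipeline is: per-frame geometric contact detection → aggregation to
residue-pair occupancies → strict stability filter → single-class labelling
→ region-annotated table.

## Contact detection

All comparisons are against heavy atoms and are inclusive at the boundary; a
guard of 1e-9 absorbs the binary rounding of decimal coordinates so that a
pair placed exactly at a cutoff on a 0.01 Å grid is always admitted.
Only cross-chain (ligand ↔ receptor) pairs are evaluated.

* **Salt bridge** — anionic oxygen to cationic nitrogen at ≤ 3.2 Å.
  Anionic oxygens: Asp OD1/OD2, Glu OE1/OE2, and the PTR phosphate oxygens
  including the bridging oxygen (O1P/O2P/O3P/OH; the OP1-style aliases are
  accepted on input). Cationic nitrogens: Lys NZ and Arg NE/NH1/NH2
  (guanidinium charge is delocalized, so NE counts). Histidine is neutral by
  default — its ring nitrogens are donor/acceptor — and is promoted to a
  cation only by the `protonated_his` switch, because His-mediated pairs in
  this family of complexes are typically stacking rather than ionic.
* **Hydrogen bond** — donor to acceptor heavy atoms at ≤ 3.0 Å. When the
  donor carries at least one hydrogen in the structure, the largest
  donor–H–acceptor angle (vertex at H, 180° = linear) must be ≥ 120°;
  structures without hydrogens fall back to the distance criterion alone and
  record no angle, so both hydrogen-full and hydrogen-free snapshots work.
  Hydrogens are attached to donors geometrically (element H within 1.25 Å of
  the donor heavy atom, same residue) rather than through name tables, which
  makes the angle test robust to naming variants. One event is emitted per
  unordered atom pair if either donor→acceptor assignment passes. A pair
  already reported as a salt bridge in the same frame is not double-reported
  as a hydrogen bond.
* **Hydrophobic contact** — apolar to apolar heavy atoms at ≤ 5.0 Å.

The three cutoffs, the angle threshold and `protonated_his` live in
`DetectionParams` and are settable from the CLI (`--saltbridge-cutoff`,
`--hbond-cutoff`, `--hbond-angle-min`, `--hydrophobic-cutoff`,
`--protonated-his`) or a TOML config file.

### Atom chemistry

Roles are table-driven (`data/chemistry.tsv`: residue, atom, backbone flag,
polarity; user-overridable) covering the 20 standard amino acids, PTR and
the ACE/NME caps. Main chain is {N, CA, C, O, OXT} plus their hydrogens.
"Apolar" means a carbon or sulfur atom not covalently bonded to N or O in
the residue's standard topology. There is no universally agreed atom-level
definition of "hydrophobic atoms"; this package's choices are: aromatic
ring carbons of Phe/Tyr/Trp/His are apolar (so 5 Å contacts approximate
stacking interactions), and Cys SG / Met SD are apolar (so methionine
sulfur participates in hydrophobic patches). Unknown residue or atom names
raise — nothing is silently classified.

## Occupancy and the stability filter

A frame counts toward a kind for a residue pair if at least one event of
that kind occurs in it; atom-level multiplicity is collapsed. Occupancy is
|frames with contact| / |frames analyzed|.

Per frame and kind, each residue participates through one *side*:

* any polar side-chain atom involved → `s`;
* otherwise any apolar side-chain atom involved → `hs` if the side chain
  possesses polar atoms, else `s` (fully apolar side chains — Gly, Ala,
  Val, Leu, Ile, Phe, Met, Cys — can never be `hs`);
* otherwise (main chain only) → `m`.

The filter keeps a pair when its best single (kind, ligand side, receptor
side) combination exceeds the threshold **strictly** (default 0.30, i.e.
"more than 30 %"; an occupancy of exactly 0.30 is dropped). One class label
is reported per pair: among qualifying combinations, polar kinds (salt
bridge, then hydrogen bond) take precedence over hydrophobic, then higher
occupancy, then a fixed side ordering — a deterministic tie-break.

With a peptide definition given, every stable ligand residue must lie inside
the pY−1..pY+7 window (anything else is an error) and records carry region
labels; `stable_interactions(profiles, peptide=None)` skips both, which is
how non-peptide systems (e.g. the occupancy-sweep validation fixture with
100 ligand residues) run through the same pipeline.

## Peptide windows and regions

Windows are 9 residues, pY−1 to pY+7, with `start_number = py_number − 1`.
Region assignment is purely offset-based: I = {0, +1}, II = {+2, +3},
III = {+4 … +8}. pY−1 is reported as `flank` rather than forced into
region I, since the interface dissection starts at the phosphotyrosine.
The +8 slot exists for generality although pY−1..pY+7 windows never
populate it.

## Structure I/O

Multi-model PDB reading/writing is backed by gemmi; a light pre-scan adds
line-numbered diagnostics for truncated ATOM/HETATM records and rejects
insertion codes (not present in any in-scope structure). Alternate-location
indicators other than blank/`A` are dropped. Author residue numbers are
preserved verbatim — all outputs are keyed by them. Topology identity
across frames is enforced on load and never silently repaired. PTR is
accepted as ATOM or HETATM. The auxiliary `frame_table` CSV
(`frame,chain,resnum,resname,atomname,x,y,z`) exists because multi-model
PDB is awkward for hand-built tests. Round trips preserve identifiers
exactly and coordinates to PDB precision (3 decimals); frame tables keep
full precision.

## Synthetic data

The generator plants contacts with exact schedules:

* `deterministic` — round(occupancy × n_frames) evenly spaced on-frames,
  so occupancy recovery is exact;
* `bernoulli` — i.i.d. per frame from a substream keyed by (seed, contact
  index), so recovered occupancies follow binomial statistics.

In "on" frames the key-atom pair sits at `on_distance` (defaults 2.8 / 2.9 /
4.5 Å per kind), otherwise at `off_distance` (default 8 Å). Residues are
built from schematic axis-oriented templates: the key atom forms the tip
facing the opposing chain and all other heavy atoms sit ≥ 3.5 Å behind it
along the contact axis; ligand residues occupy lanes 14 Å apart and
unplanted residues are kept ≥ 8 Å from the opposing chain. These templates
are deliberately not physically realistic residue geometries (realism is a
non-goal); their purpose is a provable property: the planted contacts are
the only cross-chain contacts of any kind, so the ground truth returned
with the trajectory is exact. Spec validation rejects conflicting
placements (one ligand residue with two key atoms, one receptor residue in
two contacts), chemically wrong key atoms (e.g. a planted "hydrogen bond"
between a charged pair, which the detector would classify as a salt
bridge), on/off distances on the wrong side of the cutoff, and jitter large
enough to threaten any distance margin (margin ≥ 4·jitter_sigma required).

Gaussian jitter (`jitter_sigma`, Å, isotropic per atom per frame) makes
coordinates fluctuate without flipping any frame's contact state at the
validated margins. Hydrogens are placed on planted hydrogen-bond donors
(toggleable) along the donor→acceptor axis, exercising the angle path; all
other atoms are heavy.

What passing tests on this data do **not** show: behavior on real
trajectories with correlated motions, water-mediated or bifurcated
interactions, transient secondary contacts between flanking atoms, or
imperfect protonation — the generator produces none of these by design.

## Numerical choices and degenerate inputs

* Cutoff/angle comparisons: inclusive, with a 1e-9 guard (see above).
* D–H–A angle: vertex at the hydrogen; maximum over the donor's hydrogens.
* `arccos` arguments are clipped to [−1, 1].
* Occupancy threshold: strict `>`; 30/100 frames is excluded exactly.
* Replicate statistics: sample SD (ddof = 1), the convention for triplicate
  wells.
* Blot normalization divides by the raw loading-control intensity, not by
  loading relative to a reference lane (simplest reading; documented here).
* Reporter normalizations (protein-level vs renilla) are offered as separate
  operations and never chained implicitly.
* Degenerate inputs error loudly: empty trajectories, unknown chains (the
  message lists available chains), events referencing out-of-range frames,
  empty time-series windows, equal positive/negative controls,
  non-positive denominators.
* `detect_all` on a trajectory lacking the requested chain warns and
  returns an empty event list (so batch pipelines degrade gracefully);
  the CLI `profile` command instead validates chains up front and exits
  non-zero.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on generated data chosen
to exercise every code path at desk scale: grid scans of 91–201 points,
100-frame trajectories for occupancy semantics (100 planted pairs for the
integer-percent sweep), 500-frame trajectories across 200 seeds for the
binomial-recovery property, and ≤ 200-atom random frames across 200 seeds
for brute-force oracle equivalence.

## Known limitations

* No periodic-boundary handling; inputs must be imaged/unwrapped.
* No explicit π–π or cation–π ring-geometry criteria; stacking is captured
  only insofar as apolar atoms come within 5 Å.
* No water-mediated bridges, no protonation-state prediction.
* Insertion codes and mmCIF/DCD/XTC formats are unsupported.
* The m/s/hs legend is applied consistently: a fully apolar side chain
  reports `s` even where historical tables occasionally print `hs` for
  such residues.
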