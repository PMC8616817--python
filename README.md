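# rpfdp

Model-versus-data validation for protein NMR:

* **RPF-DP scores** — recall, d⁻⁶-weighted precision, F-measure and the
  Discriminating Power (DP) of a structure model (or multi-conformer
  ensemble) against unassigned NOESY peak lists plus chemical-shift
  assignments.  DP rescales F between a freely-rotating-chain lower bound
  (DP = 0) and a data-completeness upper bound estimated from 2-/3-bond
  proton pairs (DP = 1).
* **RDC Q scores** — SVD alignment-tensor fits and quality factors
  Q = rms(W·ΔD) / √(2·Da²·(4 + 3·Rh²)/5), per conformer and as
  ensemble mean ± sd; per-vector-type or joint fits.
* **Ambiguous contact lists** — every candidate proton-pair assignment per
  NOESY peak under shift-match tolerances, as used for data-assisted
  structure prediction.
* **Synthetic benchmark** — a procedurally folded helical-hairpin toy
  protein with shifts, NOESY peaks (dropout / artifact / jitter knobs),
  coordinate-noise decoys and forward-calculated RDCs, closing the loop
  around every scorer with zero external data.

## Command line

One entry point, `rpf`, with subcommands (exit codes: 0 ok, 2 usage/config
error, 3 data error):

```bash
# synthetic fixture set (PDB, shift TSV, 2D + 13C-edited peak TSVs, RDC TSV)
rpf synth --out fixtures/ --seed 17 --nres 40

# RPF-DP scoring of a model or ensemble
rpf score --model fixtures/model.pdb --shifts fixtures/shifts.tsv \
          --peaks fixtures/noesy_2d.tsv --dmax 5.0 --tolh 0.03 \
          --json-out report.json --per-residue-out violations.tsv

# RDC alignment-tensor fit + Q scores (grouped by vector type)
rpf rdc --model fixtures/model.pdb --rdc fixtures/rdc_nh.tsv --type N-H

# ambiguous contact list from peaks + shifts
rpf contacts --shifts fixtures/shifts.tsv --peaks fixtures/noesy_2d.tsv \
             --model fixtures/model.pdb --out contacts.tsv

# render a JSON report as text
rpf report report.json
```

Settings merge as defaults < flat `key=value` config file (`-c run.cfg`;
keys: `d_max, tol_h, tol_c, tol_n, seed, free_chain_size, mode`) < flags.
All randomness (free-chain null model, synthetic generators) flows from the
single recorded seed, so machine-readable reports are byte-reproducible for
an identical configuration.

## File formats

* **Coordinates** — PDB, single model or MODEL/ENDMDL ensembles; hydrogens
  optional (an ideal-geometry builder adds missing ones; pre-protonated
  input is preserved).  Altlocs resolve to highest occupancy, ties → 'A'.
* **Shift tables** — TSV with columns
  `chain residue_number residue_name atom_name shift ambiguity`, or a
  minimal NMR-STAR v3 `Atom_chem_shift` loop (`Comp_index_ID, Comp_ID,
  Atom_ID, Val, Ambiguity_code`).  Proton names are normalized to
  IUPAC/BMRB conventions (`1HB → HB1`, `HN → H`).
* **Peak lists** — in-house TSV (`#dimension_types:` header + one row per
  peak), XEASY `.peaks` and Sparky `.list`; dimension types are
  `H_acq, H_indirect, C_edit, N_edit` (supply `--dims` for header-poor
  dialects).
* **RDC tables** — TSV:
  `chain residue_a residue_name_a atom_a residue_b residue_name_b atom_b d_obs weight`.
* **Contact lists** — TSV with stable column order
  `peak_id  dim_positions  candidate_rank  atom_a  atom_b`, one line per
  candidate pair, atoms encoded `chain.resnum.resname.name` at pseudoatom
  resolution (e.g. `A.15.LEU.QQD`); candidate rank is assigned from a
  deterministic sort, so rewrites are byte-stable.

## Scoring conventions

* Pseudoatoms: methyls always group; prochiral pairs, Phe/Tyr ring pairs
  and Leu/Val isopropyls group when their shifts coincide or carry
  NMR-STAR ambiguity code 2.  Group distances are r⁻⁶ summation distances,
  `(Σ r⁻⁶)^(-1/6)`; ensembles average per-pair r⁻⁶ over conformers before
  summation.
* Default cutoff d_max = 5.0 Å (use 7.0 Å for perdeuterated data); default
  tolerances 0.03 / 0.4 / 0.4 ppm (¹H / ¹³C / ¹⁵N).
* Peaks with no candidate within tolerance are reported separately and
  excluded from R/P (they indicate assignment incompleteness, not model
  error); near-diagonal peaks — and model edges that could only produce
  near-diagonal peaks — are excluded symmetrically.
* Distances below 0.5 Å floor at 0.5 Å with a warning so physically
  unreasonable prediction models still receive (very low) scores.

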