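# fibrilsolv

Solvation energetics of amyloid fibril atomic models: per-residue
stabilization energies from buried surface area × atomic solvation
parameters, helical stack generation and rise/twist recovery, polyanion
charge-compensation bookkeeping, segment superposition RMSDs, and the
two-axis fibril stability landscape (ΔG° per chain vs ΔG° per residue).

## What it computes

1. **Buried areas.** For a chain inside a fibril stack, per-atom
   solvent-accessible surface area (Shrake–Rupley, deterministic spiral
   point lattice, probe 1.4 Å) is compared against a reference state — the
   residue extracted in situ with its two covalent neighbours — giving the
   area each atom buries on fibril formation.
2. **Energies.** Each residue contributes `-Σ σ(class) · buried_area` over
   its atoms, with a five-class atomic solvation parameter table
   (apolar C, polar N/O, carboxylate O⁻, charged N⁺, S); stable chains come
   out negative. Chain totals and per-ordered-residue values follow.
3. **Charge compensation.** A bound polyanion (e.g. RNA) is modelled by
   zeroing the destabilizing burial terms of designated charged nitrogens:
   Lys NZ (1), Arg NE/NH1/NH2 (3), His ND1/NE2 (2). Builtin residue lists
   ship for the analyzed deposited structures (`builtin:9o8e`, `builtin:7sp1`,
   `builtin:9o8h`).
4. **Geometry.** N-layer stacks are generated from one layer by helical
   rise/twist about the fibril axis (the input layer ends up centred, so the
   middle chain is occluded from both sides); rise/twist are recovered from
   multi-layer stacks by Kabsch superposition of consecutive layers and
   screw decomposition. Energies are always evaluated on central chains.
5. **Comparison & landscape.** Residue segments are superposed with
   positional pairing (Kabsch, Cα default) for RMSD reporting; computed and
   externally tabulated structures are merged into a stability map and
   classified against the ex vivo band (default [-47, -29] kcal/mol per
   chain).

A synthetic-fibril generator (`fibrilsolv.synthetic_fibrils`) builds
full heavy-atom stacks along straight/C-/S-shaped paths — with paired
protofilaments and surface-exposed charged residues — so every stage is
testable without downloads, and provides independent brute-force oracles
for SASA and the compensation bookkeeping.

## CLI

```bash
fibril simulate --sequence LKLLKL --shape c_shape --rise 4.8 --twist -1.0 \
                --layers 5 --seed 7 --out toy.pdb
fibril params    --in toy.pdb                       # recover rise/twist
fibril io        --in model.cif --select A:341-449 --atoms CA --out seg.pdb
fibril expand    --in layer.pdb --rise 4.839 --twist -1.03 --layers 5 --out stack.pdb
fibril sasa      --in stack.pdb --chain C --probe 1.4 --points 960 --out areas.tsv
fibril energy    --in stack.pdb --chain C --compensate builtin:9o8e --out energy.tsv
fibril superpose --a 9o8e.cif --ra A:359-383 --b 5o3l.cif --rb A:318-342 --atoms CA
fibril landscape --computed out/summary.json --atlas atlas.csv --out map.json
fibril run       --config analysis.yaml            # full pipeline + manifest
```

A `run` config lists structures (either a file path or a synthetic recipe),
a compensation spec per structure, SASA settings and an output directory;
reruns are byte-identical.

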