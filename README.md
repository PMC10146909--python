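# klhlkit

Comparative conservation analysis of Kelch-like (KLHL) protein families, with
the Keap1/Nrf2 redox sensor as the motivating case.

Keap1 (KLHL19) represses the transcription factor Nrf2 and is itself switched
off by modification of specific cysteine residues — its "cysteine code".
Which cysteines matter is written into the family's evolutionary record:
a cysteine conserved across all KLHL proteins is probably structural, one
conserved only in Keap1 orthologs is probably a Keap1-specific sensor, and a
cysteine flanked by basic residues (His/Lys/Arg, which lower the thiol pKa)
is a candidate reactive site.  `klhlkit` turns that reasoning into a tested,
reusable pipeline:

- **family selection** — keep proteins whose domain architecture is
  BTB + BACK + ≥1 Kelch repeat (hits read from HMMER3 `--domtblout` or TSV),
  with isoform deduplication;
- **phylogeny** — neighbor-joining on pairwise maximum-likelihood distances
  under the JTT amino-acid model (uniform rates, pairwise deletion), on
  automatically selected conserved blocks, with bootstrap support;
- **conservation statistics** — per-column rank and class
  (ultra ≥ 66%, conservative ≥ 50%, weak ≥ 33%, else excluded),
  consensus, frequency-weighted divergence penalties, and bimodal positions
  where two clades fix different residues;
- **cysteine code** — a per-reference-cysteine report with conservation at
  the ortholog-group / clade / family levels (`Yes` ≥ 0.9, `Partially` ≥ 0.5,
  `No`, or `NotAlignable`), basic-flank flags, motif scans (`KRR`, `YxxGG`,
  `GG`, phi-x-E), and the family cysteines the reference lost;
- **structure** — distances from each Cys SG atom to the basic side-chain
  nitrogens of nearby His/Lys/Arg residues in a PDB structure;
- **simulator** — clade-structured families evolved under the same JTT model
  with *planted* conservation classes, cysteine patterns, flanks and motifs,
  so every stage can be tested against exact ground truth.

## Worked example

Simulate a 5-clade, 40-taxon family with the default planted cysteine code
and run the pipeline on it:

```sh
klhlkit simulate --seed 1 --out-prefix demo/fam
klhlkit run --alignment demo/fam.aln.fasta --clades demo/fam.clades.tsv \
            --skip-tree --out demo/out --seed 1
```

`demo/out/cysteine_report.tsv` (columns abridged):

```
position  column  domain  conserved_in_reference_group  conserved_in_clade  conserved_in_family  basic_flank  flanking_basics
40        40      NTR     Yes                           Yes                 Yes                  False
80        80      BTB     Yes                           Yes                 No                   False
120       120     BTB     Yes                           No                  No                   True         K121
200       200     BACK    Yes                           Partially           Partially            False
```

Reading it: the cysteine at position 40 is conserved family-wide (a
structural cysteine); position 80 only within the reference's clade; position
120 only in the reference group *and* it carries a basic neighbour (K121) —
the signature of a protein-specific reactive sensor cysteine, exactly as
planted.  A cysteine the reference lost shows up in the companion section,
`demo/out/cysteine_missing.tsv`:

```
column  reference_position  reference_residue  family_label  presence_family  clades_conserved
160     160                 N                  No            0.150000         clade2:Partially
```

and `demo/out/penalties.tsv` quantifies each row's divergence from the
consensus and from the reference row:

```
seq_id      penalty_vs_consensus  mismatches_vs_consensus  penalty_vs_reference  mismatches_vs_reference
clade1_t01  15.600000             26                       0.000000              0
clade1_t02  18.050000             29                       8.075000              23
```

(The reference row itself scores 0 against itself; every mismatch elsewhere
is charged the column frequency of the target residue, so losing conserved
positions costs more.)  Domain labels come from a supplied coordinate table
(the built-in default uses the human reference protein's intervals, e.g. BTB
at residues 67–178).  The library API additionally accepts a multi-row
reference ortholog group (`build_cysteine_report(..., reference_group=...)`);
the CLI scores the reference row alone.

Real data run the same way: `klhlkit filter` on your domain-hit table,
`klhlkit tree` on your alignment, `klhlkit cyscode` with your clade
assignments, and `klhlkit struct --pdb ... --chain A` for the spatial
cysteine–basic contacts.

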