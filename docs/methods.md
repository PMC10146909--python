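# Methods

## Scope and model of the analysis

`klhlkit` implements a comparative-conservation pipeline for the Kelch-like
(KLHL) protein family, with the ubiquitin-ligase adapter Keap1 (KLHL19) as the
canonical reference.  The pipeline answers three linked questions:

1. **Which proteins belong to the family?**  Membership is defined purely by
   domain architecture: a BTB domain, a BACK domain, and at least one Kelch
   repeat, each detected at or below an e-value threshold.  Domain hits are
   consumed from external profile searches (HMMER3 `--domtblout` or a plain
   TSV); the package never runs the searches itself.
2. **How are the members related?**  A neighbor-joining tree built from
   pairwise maximum-likelihood distances under the JTT amino-acid model, on a
   selected set of well-aligned conserved columns, with bootstrap support.
3. **Which residues are conserved where, and what is the cysteine code?**
   Column-level conservation statistics, frequency-weighted divergence
   penalties, clade-informative "bimodal" positions, and a per-cysteine report
   combining conservation at three phylogenetic depths with the basic-residue
   context that governs thiol reactivity.

## Substitution model and distances

The JTT (Jones–Taylor–Thornton, 1992) general time-reversible rate matrix is
embedded as constants (the published exchangeability table and equilibrium
frequencies) and normalised to one expected substitution per site per unit
time at equilibrium.  Pairwise distances maximise

    ll(t) = sum_sites log( pi_a * P_ab(t) ),   P(t) = expm(Q t)

over `t in [1e-8, t_max]` (default `t_max = 10`), using a bounded
derivative-free scalar search with tolerance 1e-6.  `P(t)` is evaluated
through a one-time symmetric eigendecomposition of `Q`, which makes the many
evaluations required by bootstrapping cheap.  Rates are uniform across sites
(no gamma heterogeneity).  Columns containing a gap or the ambiguity residue
`X` in either row are removed pairwise; a pair with no comparable columns is
an error, and a pair whose optimum reaches `t_max` is reported as saturated
at `t_max` with a warning.  Identical rows return exactly 0.

The estimator is validated against an independent brute-force oracle: a grid
search of the same log-likelihood using `scipy.linalg.expm` directly, with a
coarse 0.01 pass over [0, 5] followed by a 1e-4 grid inside the bracket.
Implementation and oracle agree to ~3e-5, well inside the 1e-3 test
tolerance.

## Tree construction

Neighbor joining follows the Saitou–Nei agglomeration with the Q criterion.
Negative branch-length estimates are clamped to zero.  Ties in Q are broken
by the lexicographically smallest pair of cluster keys (a cluster's key is its
smallest leaf name), so the topology is independent of input row order.  The
final three clusters are joined at a trifurcating root (the conventional
unrooted representation).  On additive matrices the recovery is exact: path
lengths match the generating matrix to 1e-10 and every generating bipartition
is recovered (checked up to 12 taxa), and the topology agrees with
scikit-bio's independent NJ implementation on perturbed matrices.

Bootstrap support resamples the selected columns with replacement, recomputes
distances and the NJ tree per replicate, and maps the percentage of
replicates containing each bipartition onto the point-estimate tree (a
majority-rule consensus is not built).  Replicates in which some pair loses
all comparable columns are skipped and counted, and the effective denominator
is reported.

Conserved-block selection is an automated stand-in for manual curation: keep
columns with gap fraction <= `max_gap_fraction` (default 0.2) and top-residue
rank >= `min_rank` (default 0.5), then drop runs shorter than `min_block_len`
(default 3).

Clade definitions are an input (a TSV of row -> clade), not a claim of the
pipeline; when none is supplied the tree is cut at its `k - 1` longest
internal edges as a convenience.

## Conservation statistics

A column's *rank* is the frequency of its most common residue among non-gap
rows (an all-rows denominator is available behind a flag; `X` counts in the
denominator but can never be the top residue).  Classes: ultraconservative at
rank >= 0.66, conservative in [0.50, 0.66), weakly conserved in [0.33, 0.50),
excluded below 0.33 — each interval closed at its lower bound so the classes
are disjoint.  Consensus ties are broken alphabetically and logged.

The divergence penalty of a row over a selected column set charges, for every
mismatch against the target residue (column consensus, or a reference row's
residue), the within-column frequency of that target — losing a conserved
residue costs more than losing a variable one.  A gap in the scored row
counts as a mismatch (this choice is one of two defensible readings; the
mismatch counts are printed so the other can be reconstructed).  Columns
where the target is undefined (all-gap, or reference gapped) are skipped and
excluded from the scored-column count.

Bimodal positions report columns where one clade fixes residue X and another
clade fixes a different residue Y, both at within-clade frequency >= theta
(default 0.8, theta must exceed 0.5 so at most one residue per clade
qualifies).  Within-clade frequencies count gaps in the denominator so a
mostly-gapped clade cannot qualify.

## The cysteine-code report

For each cysteine of the reference row: its alignment column (via a
position-to-column map covering exactly the reference's non-gap columns), a
domain label from a supplied coordinate table, and conservation labels at the
reference-ortholog-group, clade, and family levels.  A group at a column is
`NotAlignable` if fewer than 50% of its rows are non-gap there; otherwise the
presence fraction p of cysteine (gaps counting as absence) maps to `Yes`
(p >= 0.9), `Partially` (0.5 <= p < 0.9), `No` (p < 0.5).  The 0.9/0.5
thresholds are configurable and the raw fractions are always printed, so any
re-thresholding is transparent.  A separate section lists columns whose
cysteine is conserved at the family or some clade level while the reference
residue there is not cysteine — the family cysteines the reference lost.

The basic-flank scan flags cysteines with at least one H/K/R within ±window
residues in sequence (default window 1, i.e. immediate neighbours); windows
truncate at the termini.  Spatial proximity is deliberately separate: the
structure module measures, for each Cys SG atom of a PDB chain, the minimum
distance to the charge-carrying side-chain nitrogens of each His/Lys/Arg
residue (Arg NE/NH1/NH2; Lys NZ; His ND1/NE2), with an all-atom mode behind a
flag and a default neighbour cutoff of 8 Å.  PDB parsing takes the first
model only and resolves alternate locations to the highest-occupancy
conformer; HETATM records are ignored by default.

Motif scans use a small pattern language (exact residues, `x` wildcard,
bracketed residue classes); built-ins cover the arginine-triad mimic `KRR`,
the propeller-blade `YxxGG` and double-glycine `GG` motifs, and the
Cullin-interacting `[FILMV]xE` (phi-x-E) motif.  All overlapping matches are
reported; when a reference position map is supplied, matches on any row are
also reported in reference numbering.  An exploratory cysteine-spacing
histogram is emitted; no periodicity is asserted.

The `studied` column of the report is literature metadata read from an
annotations TSV, never computed.

## The synthetic-family generator

The generator is the source of ground truth for every recovery test.  Its
defaults define the study conditions: 5 clades x 8 taxa, sequence length 300,
inter-clade branch length 0.8 and intra-clade 0.05 expected
substitutions/site, a reference ortholog group of 3 taxa inside clade 1,
10% of columns planted in each conservation class, a five-column cysteine
plan spanning the characteristic patterns (family-wide conserved;
clade-specific; reference-group-only with a planted basic flank — the
pattern of a reactive sensor cysteine; partially conserved in another clade;
partially conserved family-wide), and two planted motifs (`KRR` in one
non-reference clade, phi-x-E family-wide).

Sequences evolve down a star-of-clades tree under the same embedded JTT model
used for distance estimation, so distances on simulated alignments are
model-consistent.  Three deliberate departures from a plain simulation keep
the planted truth *exact* rather than statistical:

- the substitution kernel is conditioned to never visit cysteine, so
  cysteines occur only where the plan places them;
- basic residues are scrubbed from the flanking window of planted cysteine
  columns unless a flank is planted there, so the flank truth is exact;
- planted presence fractions are realised as exact row counts
  (`round(p * n)`), and planted conservation-class columns receive an
  i.i.d. background (no clade correlation), so the realised rank always falls
  in the planted class.

Consequences worth stating: the emitted families have no background
cysteines, planted-class columns carry no phylogenetic signal, and there is
no indel process (the true alignment is the simulated matrix; gaps are
injected afterwards by `corrupt_alignment`, which returns the exact gap
mask).  Passing recovery tests therefore demonstrate that the analysis code
recovers what a generator of this structure plants — they do not demonstrate
robustness to alignment error, indels, compositional heterogeneity, or
rate variation in real data.

Class-presence levels (0.90 / 0.58 / 0.41) sit at least 0.05 inside their
class intervals; cysteine presence levels 1.0 and 0.7 map to `Yes` and
`Partially` under the 0.9/0.5 thresholds with margin.

## Numerical and design choices

- Public coordinates (residue positions, alignment columns, domain intervals)
  are 1-based inclusive; 0-based indices appear only at numpy boundaries.
- Non-standard residues (B, Z, U, O, J) map to `X` with a logged warning; `X`
  never matches a consensus, a motif's non-wildcard token, or a planted
  residue.
- Gap characters `-` and `.` are both accepted on input and normalised to `-`.
- The domain-hit reader supports the hmmscan orientation of `--domtblout`
  (target = profile, query = protein) and uses the per-domain independent
  e-value and alignment coordinates.
- Isoform deduplication keeps the longest sequence per gene, ties to the
  lexicographically smallest id; outputs are sorted by id so results are
  independent of input order.
- The architecture rule applies one configurable e-value threshold per domain
  (defaults 0.1, the loose architecture-check value); overlapping Kelch hits
  count separately.
- The acceptance script sizes its experiments to desk scale: 100 simulated
  families for clade recovery, 100 bootstrap replicates on one family, 3
  mutated pairs against the grid oracle, 5 random 10-taxon additive trees.

## Known limitations

- Sequence input is FASTA only (no Stockholm/PHYLIP), uncompressed.
- The NJ/JTT machinery reproduces the method class, not any particular
  program's numeric path; distances from other implementations may differ in
  the last digits.
- The structure module parses PDB only (no mmCIF) and performs generic
  distance analysis; pKa prediction and binding energetics are out of scope.
- Clade-level conclusions inherit whatever clade definitions the user
  supplies; the tree-cutting helper is a heuristic, not an inference.
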