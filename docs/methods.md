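# Methods

## Model

The predictor treats MHC II–peptide binding as a rigid-body threading
problem. A scaffold fixes all backbone coordinates: chains A and B are
the α/β heterodimer, and one or more peptide backbone conformations
(length 9, 11, 13 or 15 with a designated 9-mer core window) sit in the
groove. Threading a sequence means assigning its residues to
conformation positions and summing pre-compiled pair energies at the
scaffold's distances — no refinement, side-chain modelling or dynamics.
The assumptions are therefore: (i) backbone geometry is transferable
across peptides binding the same allotype, (ii) Cα/Cβ pair distances
carry enough signal to rank sequences, and (iii) small backbone
variability is adequately covered by averaging over a few alternative
conformations.

### Statistical scoring functions

Energies come from Boltzmann inversion of distance histograms,
`ΔE_ab(r) = −kT ln(f_ab(r)/f(r))`, with the reference state `f(r)`
pooled over all pairs of the same atom type and contact class. The
additive constant from the partition function is dropped: scores are
only ever compared, never interpreted as physical energies (hence
kT = 1 score unit).

Choices that the inversion itself does not fix:

- **Binning**: half-open 1.0 Å bins up to a 15 Å cutoff; beyond the
  cutoff pairs are non-interacting (energy 0). A distance exactly on an
  interior edge belongs to the right-hand bin.
- **Smoothing**: pair histograms are shrunk toward the reference with a
  pseudocount weight m = 50, `f̃_ab = (n_ab f_ab + m f)/(n_ab + m)`, so
  rare pairs get finite energies that vanish as data vanish. Bins where
  the reference itself is empty score 0.
- **Contact classes**: inter-chain potentials score peptide–MHC pairs,
  intra-chain potentials score within-peptide pairs with sequence
  separation ≥ k_min = 2 (adjacent-residue distances are covalently
  constrained and carry no preference signal).
- **Glycine**: a virtual Cβ is constructed from N/Cα/C (1.53 Å bond,
  tetrahedral angles, L-configuration side) so the Cβ potential is
  defined for all 210 amino-acid pairs.
- **Training-set filter**: potentials aimed at interface contacts are
  compiled from multimers containing at least one chain of 5–20
  residues — complexes with a short, peptide-like partner.

All of these are configurable on `SSFConfig`; the defaults above are
the package's declared conventions.

### Threading and scoring

For each (model, conformation) combination, every alignment offset for
which the 9-mer core lies fully inside the query sequence is evaluated;
flank positions extending past the sequence ends stay unoccupied and
contribute nothing. The lowest-energy placement per combination is
kept (ties resolve to the smallest window start, for determinism), and
the binding score is the unweighted arithmetic mean over combinations.
The default scaffold selection is the two best models by meta-score
with five conformations each; the meta-score is consumed from scaffold
metadata, since it aggregates external model-quality tools that are out
of scope here. All MHC residues are scored, not only pocket residues —
the distance cutoff already makes remote residues irrelevant.

### Rank, IC50, classification

Raw scores live on an arbitrary scale, so a query is ranked against a
background peptide set: rank = (#background strictly better + ½·ties)/N,
the normalised Wilcoxon–Mann–Whitney statistic, with midrank tie
handling (the standard WMW convention). The rank is invariant under any
monotone rescaling of scores. Background scores are computed once per
scaffold set and cached; the default background is 1,000 uniform random
peptides from the synthetic generator (a stand-in for a large
non-redundant structure-derived sample, which at full scale would be
~11,000 peptides).

Ranks map to IC50 through a linear model on the saturating transform
`y = 1 − log(IC50)/log(50000)` (log-base-free; IC50 values above
50,000 nM clamp to 50,000, below 1 nM to y = 1):

    IC50_pred = 50000^(1 − (slope·rank + intercept))

with default coefficients slope = −0.4265748, intercept = 0.51225.
This form is the algebraic inverse of the transform, is strictly
increasing in rank for negative slope, and crosses the 500 nM binder
cutoff at rank ≈ 0.203. `fit_ic50_model` refits both coefficients by
ordinary least squares on (rank, IC50) calibration pairs. Binder
classification is strict: IC50 < cutoff (default 500 nM; 1000 nM
supported as an alternative convention).

### Evaluation and consensus

ROC AUC uses midrank tie handling with an explicit orientation flag for
methods whose scores decrease with binding. The optimal classification
threshold scans midpoints between adjacent distinct scores (plus
sentinels), maximising accuracy with ties resolved toward the lower
threshold — the package's own criterion, declared because published
optimal-threshold tools do not document theirs. An outlier is a record
whose predicted class is wrong *and* whose absolute IC50 error exceeds
500 nM. The contradiction filter keeps records where the qualitative
label (any Positive sublevel vs Negative) agrees with the quantitative
IC50 at the cutoff. Consensus over k ≥ 2 methods is the median of their
predicted IC50 values (central mean for even k), which tolerates a
minority of grossly wrong components.

## Synthetic study conditions

The generator produces every input the pipeline needs, with idealized
geometry: extended strands at 3.8 Å Cα spacing, groove strands (chains
A and B) parallel to the peptide at 5 Å, Cβ atoms offset uniformly by
1.53 Å. This is deliberate — the scoring machinery only ever sees
distances and residue identities, so planted distance preferences
exercise every code path that real structures would, while keeping
every expected value computable in closed form.

Default planted condition: pair (F, L) favoured with energy −ln 2 over
the 4–10 Å band, all other pairs uniform. The band is wide by design:
a pair's density must normalise to 1, so a planted favourable band
necessarily makes out-of-band bins repulsive relative to the pooled
reference, and in the parallel-strand geometry each core position has
10 contacts inside the 4–10 Å band versus 4 outside it — wide enough
that favourable in-band contacts dominate. Binder peptides carry the
groove-complementary residue across their centred 9-mer core; binders,
non-binders and the background set are otherwise uniform random. The
discrimination experiment uses 200 binders and 200 non-binders (seed
17), a 1,000-peptide background, and potentials compiled from 41 pairs
× 5,000 observations; larger inversion-recovery measurements use 100
pairs × 50,000 observations. These sizes were chosen so each expected
effect stands several standard errors clear of its assertion while the
whole study remains desk-scale.

Two systematic effects make the *compiled* in-band energy differ from
the nominal planted value: band normalisation (above) and contamination
of the pooled reference by the planted pairs themselves. The exact
expected energy, including pseudocount shrinkage, is available in
closed form (`PlantedPotential.expected_energies`) and is the oracle
the tests compare against; for a narrow 1 Å band among ≥100 pairs the
distortion is under 0.07 score units, so recovery is also asserted
against the nominal value there.

What passing these tests does **not** show about real data: the toy
geometry has no groove pockets, no fold-specific contact topology, no
backbone diversity beyond jitter, and the planted potential has no
relationship to real amino-acid contact statistics. The synthetic
results validate the machinery (inversion, enumeration, normalisation,
calibration, evaluation logic), not the biological accuracy of any
particular potential.

## Numerical choices and degenerate inputs

- Superposition is least-squares rigid alignment with a proper rotation
  (det = +1); fewer than 3 points or collinear point sets raise a
  geometry error. Pocket frames are explicit metadata, paired
  point-for-point.
- Equal-energy threading placements resolve to the smallest window
  start; equal meta-scores resolve lexicographically by source id.
- Potential files are self-describing text with a format version and a
  CRC32 payload checksum; version or checksum mismatches are load
  errors, and full-precision float repr makes save→load→save
  byte-stable.
- PDB input: first MODEL only, altloc ' '/'A' only, HETATM ignored
  except MSE→M and SEC→C, residues without Cα dropped with a log line.
- Empty backgrounds, single-class label sets, constant correlation
  inputs, non-positive IC50s, ranks outside [0, 1] and antigens shorter
  than 9 residues all raise typed errors rather than returning NaN.

## Limitations

- Scaffolds are consumed as input files; homology modelling, model
  quality scoring and template search are upstream and out of scope.
- No side-chain representation beyond Cβ, no solvation or torsion
  terms, no backbone relaxation.
- The rank→IC50 coefficients are global, not per-allele; per-allele
  recalibration would require measured binding data.
- Benchmark ingestion covers tabular records (allele, peptide, IC50,
  qualitative label, per-method predictions); no database client is
  included.
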