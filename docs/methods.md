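# Methods

## Model and rationale

Purifying selection removes deleterious alleles from a population, so
protein regions essential to function accumulate fewer missense variants in
population exome data than the rest of the protein. `missensemap` treats the
set of *neutral* missense variants observed in a large cohort as a probe of
that constraint: residues never hit by a neutral missense variant are
candidates for functional importance, and a domain whose density of
missense-variable residues falls below the whole-protein density is a
candidate essential domain.

The pipeline makes three modelling commitments:

1. **Neutrality by annotation.** A variant is treated as neutral if its VEP
   consequence class is missense (`missense_variant`, with `missense`
   accepted as an alias) and it carries no ClinVar classification in the
   excluded classes {pathogenic, likely pathogenic, conflicting
   interpretations of pathogenicity, uncertain significance}. Benign-class
   and unannotated variants are kept: most rare alleles have no ClinVar
   record, and excluding them would empty the data. ClinVar matching is
   case- and whitespace-insensitive; multi-valued cells
   (`Pathogenic/Likely pathogenic`) are excluded if *any* token matches an
   excluded class — the filter targets annotation classes, not exact
   strings. Rows with no VEP annotation at all fail the VEP requirement and
   are excluded (counted separately in the filter report).

2. **Disjoint-event aggregation.** Distinct substitutions at one residue are
   (to excellent approximation) disjoint events on distinct haplotypes, so
   their allele frequencies add. The per-residue sum is capped at 1 (it is a
   probability; the cap can only bind on adversarial synthetic input, and is
   counted when it does). The summed frequency is then binned on a base-10
   log scale into 6 bins with half-open-left, closed-right intervals:
   bin 1 collects everything ≤ 10⁻⁵ (there is no meaningful resolution below
   the cohort's detection floor of one allele), bins 2–6 are
   (10^(k−6), 10^(k−5)]. Closed-right edges make AF = 1 binnable and give
   exact powers of ten a deterministic home. The raw summed frequency is
   stored; the log scale is implicit in the bin edges.

3. **Positions, not counts.** Vd/Vp is computed over distinct variable
   residue positions, not variant counts, so multiallelic sites are not
   double-counted:

   Vd/Vp = (n_var_domain / L_domain) / (n_var_protein / L_protein).

   A whole-protein domain therefore scores exactly 1, and the ratio is
   invariant to any uniform rescaling of allele frequencies. When the
   protein has no variable positions (Vp = 0) the ratio is reported as
   explicitly undefined rather than raising a division error — legal on
   sparse synthetic input. Protein length is the UniProt canonical sequence
   length supplied by the caller, not the length of any analysed structure
   fragment.

## 3D mapping

A profile position *p* maps to structure residue *p + offset* on one chain
(one chain per invocation; multi-copy structures are handled by repeated
runs). A position is reported unmapped, with a reason, when the residue is
absent from the structure (`absent_residue`), lacks a Cα atom (`no_CA`), or
— when confidence masking is enabled — its B-factor, which carries the
per-residue pLDDT in AlphaFold-style models, is ≤ the threshold
(`plddt_below_threshold`). The default threshold is 70, the conventional
boundary for a generally correct backbone; masking is off by default for
experimental structures. Chains using insertion codes are rejected rather
than silently mis-mapped, since an integer offset cannot address them.

The PyMOL script emitter writes one named selection per populated bin plus
one for pathogenic positions, with sphere radii 0.8–2.8 Å (non-decreasing
with bin) and a 6-step light-to-dark blue ramp; pathogenic positions are
red, radius 2.0 Å. Only monotonicity of size and shade is semantically
meaningful; the exact values are configurable. Emission is a pure function
of (annotation, style, structure path): residues are sorted ascending and
no timestamps are written, so reruns are byte-identical — which also makes
the script parseable as a machine-checkable record of the mapping.

The 1D plot encodes position only (uniform tick height), matching the
convention of lollipop/track plots for variant positions; an option scales
tick height by bin. Domain rectangles sit on a thin baseline bar with each
domain's Vd/Vp printed above it to 2 decimal places.

## Synthetic data: what it emulates, and what it does not

The generator emulates a per-gene gnomAD v2 browser export: each residue is
independently variable with a region-dependent density; variable residues
receive one substitution (two at rate `multiallelic_rate` = 0.15); allele
frequencies are log-uniform over 10⁻⁶..10⁰ so all six bins are populated,
with allele counts integerised against AN = 251,496 (2 × 125,748 exomes) so
AF = AC/AN holds exactly and the realistic frequency floor of ~4 × 10⁻⁶
emerges naturally; 25% of rows are non-missense decoys
(synonymous/stop-gained) and 1.5% carry excluded ClinVar classes (the
approximate proportion such classes make up of a real constrained-gene
export); 15% of neutral rows carry benign-class ClinVar labels to exercise
the keep-side of the filter. Default background density is 0.35, the centre
of the variant-density range typical of well-covered constrained human
genes (≈ 0.29–0.42). A point-mass frequency mode exists for bin-edge tests.
All randomness flows from one integer seed; output CSVs are byte-identical
per seed.

The sidecar ground truth (true variable positions with region label, summed
frequency and bin) equals, by construction, what the filter + aggregation
pipeline must recover, which gives the end-to-end tests an exact oracle.

Deliberately **not** emulated: codon structure and mutability (CpG
hypermutability skews real missense density along the sequence — the
pipeline does not normalise for it, so neither does the generator),
linkage between sites, sequencing-depth variation, and clustered
multiallelicity. Passing tests therefore demonstrate correctness of the
bookkeeping and the estimator on idealised data, not robustness to
mutational-rate heterogeneity in real exomes.

## Statistical behaviour of the Vd/Vp estimator

With per-residue variability an independent Bernoulli event, the number of
variable positions in a domain of length L at density d is Binomial(L, d),
so the estimator's relative standard error scales as sqrt((1−d)/(dL)). For
a 200-residue domain at d = 0.1 this is ≈ 21% — a short domain's ratio is
a noisy estimate, and single-domain ratios should be read with that
granularity in mind (the published-figure convention of 2 decimal places
overstates the precision for short domains). Recovery of a generating
ratio within ±15% is reliable only once the domain holds a few thousand
residues; the convergence test uses a 5,000-residue domain (relative SE
≈ 4%) for that reason. The acceptance suite also measures the recovery
fraction for the 200-residue case and reports it as observed.

## Numerical and interface choices

- Allele frequency is recomputed as AC/AN at parse time (the export's AF
  column is a rounded rendition); a mismatch beyond 0.1% relative marks the
  row malformed. Rows with AN = 0 or AF outside [0, 1] are rejected with a
  count, zero-frequency records are dropped before aggregation (log-binning
  is undefined at 0), and positions beyond the stated protein length are
  skipped with a warning count — numbering mismatches are common in real
  exports and must not kill a batch run.
- HGVS `p.` parsing accepts simple substitutions only (three-letter codes,
  `Ter` = stop); frameshifts, indels, duplications, extensions and unknown
  effects return a typed parse-failure value rather than raising, and are
  counted as skipped rows.
- Duplicate rows are retained by default (deduplication is an explicit
  flag keyed on genomic locus), since repeated loci can be legitimate
  multi-nucleotide exports.
- Filtering preserves input order and is idempotent; aggregation is
  permutation-invariant. Bin assignment uses edge comparisons
  (bisection), not floating-point logarithms, so exact powers of ten are
  handled without rounding surprises.
- The CLI exits 0 on success, 2 on configuration errors and 3 on data
  errors, validates inputs before writing anything, and records every run
  (inputs, counts, seed, version) in `run_report.json`.

## Problem sizes used in the test and acceptance runs

Property and oracle tests use proteins of length ≤ 500 with ≤ 50-record
random instances (hundreds to a thousand repetitions); the convergence and
recovery experiments use length 10,000 at densities 0.4/0.1 (the recovery
experiment over 100 seeds); end-to-end fixtures use proteins of length
60–400 with toy Cα-helix structures of up to 300 residues. These sizes were
chosen so the full suite and the acceptance script each complete in well
under a minute and ~25 seconds respectively on one core, while keeping
binomial counting noise small relative to the tolerances tested.

## Known limitations

- No codon-mutability normalisation: regions rich in hypermutable codons
  can look misleadingly variable.
- Vd/Vp depends entirely on user-supplied domain boundaries; poorly chosen
  boundaries over- or under-estimate depletion, and short motifs yield
  noisy ratios (see above). Small depleted sites inside an otherwise
  variable domain are invisible to the ratio and require 3D inspection.
- Cohort size bounds sensitivity: genes with little data (e.g. on sex
  chromosomes, with half or quarter the autosomal allele number) yield
  depressed variant densities that mimic constraint.
- The consequence annotations of the input table are trusted as-is; no
  liftover, transcript selection or re-annotation is attempted.
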