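# Methods

## Scope and model

`mqlibra` post-processes a MaxQuant project directory. It treats the
`combined/txt` tables as the authoritative identification evidence and adds
four things on top: minimum protein reporting, protein N-terminal
modification site tables, Libra-style isobaric reporter quantification, and
descriptive statistics with an organized report bundle. It does not run or
re-score searches, and it does not model MS1-level (label-free or isotope
pair) quantification.

## Pipeline order

The quantification pipeline order is frozen as: isotope-impurity correction
→ channel calibration → low-intensity filter → per-spectrum normalization →
grouping by entity and replicate → outlier rejection → median/mean/SD
summary. Each step's definition:

* **Correction.** Observed reporter vector **y** relates to true intensities
  **x** by **y** = *M***x**, with *M* the vendor isotope-impurity matrix
  (columns = true channel, rows = observed channel). We solve the linear
  system exactly rather than applying one-pass subtraction, because vendor
  matrices are diagonally dominant and the exact solution is stable there.
  Negative components — numerically possible near zero — are clamped to 0
  to preserve non-negativity; clamp counts are logged. A singular matrix is
  a fatal configuration error. Matrices whose columns sum above 1 are taken
  to be percent-style vendor sheets and rescaled to unit column sum with a
  warning; the orientation is stated in the shipped file headers because
  vendor sheets disagree and guessing silently is worse than documenting.
* **Calibration.** Factors *f<sub>c</sub>* = mean over channels of channel
  totals / total of channel *c*, computed globally over all corrected
  spectra, equalize overall per-channel totals. The mean is used as the
  equalization target so no channel is privileged as a reference — the same
  motivation that drives reporting per-channel expression instead of
  reference ratios. Factors are exported in the statistics block. A channel
  with zero overall intensity has no defined factor and aborts with a
  message naming the channel. Calibration is global, not per replicate: one
  overall factor per channel is exported, and replicates are quantified
  separately only downstream of it.
* **Low-intensity filter.** Spectra whose calibrated total is at or below
  `low_intensity_threshold` are excluded (counted, not an error). The
  default is 0 — only non-positive totals are dropped — because any other
  cutoff is instrument-dependent; the threshold is exposed in the
  configuration.
* **Normalization.** Fractions *x<sub>c</sub>* / Σ*x* per spectrum; sums are
  1 to within 1e-9 by construction.
* **Grouping.** Protein-level grouping honors `use_unique_peptides_only`
  (default true): scans whose peptide maps to more than one surviving group
  are skipped, so proteins with only shared peptides stay unquantified.
  Site-level grouping uses specific sites only — ambiguous sites have an
  undetermined position and would mix evidence across candidate residues.
  Each replicate (raw-file assignment from `summary.txt`, overridable by a
  template file) is quantified separately and merged by entity id with a
  full outer join; no cross-replicate averaging is done.
* **Outlier rejection.** Per channel independently: values deviating from
  the channel mean by more than `outlier_sigma` (default 1.96) population
  standard deviations are dropped. σ is the population SD (divide by *n*),
  and groups with fewer than 3 spectra, or zero spread, are kept whole —
  with 2 values any asymmetric pair would otherwise be self-outlying. If a
  channel ends up empty (mathematically impossible at k = 1.96 but guarded),
  it falls back to the pre-rejection values and is flagged.
* **Summary.** Median, mean and population SD of retained fractions per
  channel, plus spectrum and removal counts.

## Identification reporting

Column selection uses exact (string equality) and keyword (case-sensitive
substring) title rules, because MaxQuant column titles vary across versions
and experiments. Keyword matching is deliberately case-sensitive — MaxQuant
titles are consistently cased and case-folding risks false positives. An
exact rule with no match warns instead of failing, so one rule set covers
several version dialects; the shipped default uses the keyword `ontaminant`
to match both `Contaminant` and `Potential contaminant`.

Group minimization retains the accessions maximizing (unique peptides, total
peptides) lexicographically; all tie-breaks (equal counts, equal group
scores) use original table order so output is deterministic and diffable.
Reverse/contaminant detection honors both the `+` marker columns and the
`REV__`/`CON__` accession prefixes, which vary across MaxQuant versions.
Peptides, scans and sites whose candidate groups were all filtered out are
dropped, keeping the four reported levels referentially closed.

N-terminal sites are recognized at protein positions 1 and 2 only; position
2 covers initiator-methionine cleavage, and other internal matches of the
peptide never create an N-terminal site. When `ile_eq_leu` is set, peptide
location treats I and L as equal during matching only — stored sequences
and reported windows are never mutated. Site positions are 1-based on the
protein sequence; windows are `2*flank+1` residues (default flank 6, so 13)
padded with `_` beyond termini, extracted from the best-scored group's lead
accession. Classification is strict: specific iff p > `loc_prob_threshold`
(default 0.5); a site at exactly the threshold is ambiguous, and a site with
no probability (position fixed by the peptide termini) is specific.

## Synthetic projects

The generator (`mqlibra.synthetic`) emulates a TMT-style experiment: each
protein has a per-channel abundance profile; a spectrum's reporter vector is
profile × lognormal base abundance (σ = 0.3 around 10⁶) × per-channel
multiplicative lognormal noise with the requested CV (default 10%, the
realistic reporter-level scatter at usable intensities). Noise is per
channel, not a per-spectrum scalar — a scalar would cancel in
sum-normalization and make outlier rejection vacuous. Channels planted at 0
write exact zeros.

`balanced_background_proteins` adds a constant background whose common
profile is computed so the project's overall per-channel loading is equal.
This emulates the equal-total-loading design of real isobaric experiments
(and of spike-in standards, where a handful of spiked proteins sit in a
large constant proteome) and is the validity condition of channel
calibration: without it, a profile shared by *all* proteins is
indistinguishable from labelling bias and is flattened by calibration.

The generator plants grouping ambiguity (weaker isoform accessions), decoy
and contaminant groups, replicate layouts over raw files, N-terminal
modification evidence with localization probabilities, and an internal
oxidation site table. It does **not** emulate chromatography, charge
states, missing channels from sampling, interference/ratio compression, or
realistic score distributions — so passing tests demonstrate the
correctness of the reporting and quantification arithmetic on well-formed
inputs, not robustness to every pathology of real instrument data. A fixed
seed yields a byte-identical project directory.

The test and acceptance problem sizes (a 12-protein feature-rich project;
a 20-spike + 80-background quantification project at 30 spectra/protein,
3,000 spectra total) are desk-scale by design: large enough for stable
medians and meaningful calibration, small enough to regenerate from scratch
in seconds.

Statistical note on spike-in recovery: at CV 10% and 30 spectra/protein the
standard error of a per-protein ratio of channel medians is ≈ 3.3%, so
individual proteins land within ±5% of the planted ratio roughly 90% of the
time; ensemble medians are far tighter (the acceptance script reports both
the median recovered ratio and the per-protein in-band percentage).

## Output bundle

All tables are written as full-precision TSV; the combined workbook mirrors
them with NaN-like placeholders as empty cells, sheet names truncated to 31
characters and deduplicated. Charts are rendered to SVG with a same-named
TSV data series next to each; the TSV is the data contract and tests assert
only on it. The index page always has the same six sections (input
parameters; identification; statistics; isobaric quantification;
miscellaneous; log), with the quantification section stating "not performed"
when no reporter columns exist. The log records timestamped INFO/WARN/ERROR
lines inside the output folder; on failure the ERROR line is written and no
index page is produced, so a missing index is the failure signal.

## Known limitations

* Per-accession peptide counts absent from `proteinGroups.txt` degrade
  minimization to retaining all accessions (with a warning).
* Sites from `<PTM>Sites.txt` whose accession/position cannot be resolved
  against the FASTA catalog keep an empty window rather than being dropped.
* Ratio compression from co-isolation interference — a property of MS2
  reporter data itself — is out of scope; recovered ratios on real data
  underestimate extreme true ratios.
* The experimental-design template has no notion of fractions or conditions;
  it maps raw files to replicate labels only.
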