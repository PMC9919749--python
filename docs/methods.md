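# Methods

This note documents the models, conventions, and design choices behind
`sipscreen`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Gradient model

An rRNA-SIP gradient is collected as 13 fractions of known buoyant
density (g ml⁻¹) with RT-qPCR 16S transcript copy numbers and, for the
selected fractions, amplicon count tables. The analysis uses one
representative **heavy** and one **light** fraction per gradient.

* **Windows.** Defaults are heavy 1.851–1.872 and light
  1.805–1.819 g ml⁻¹, treated as closed intervals (printed ranges are
  read inclusively). Windows are configurable per run; they must not
  overlap, and a gradient whose densities never enter a window fails
  loudly (`WindowEmptyError` naming the gradient and window) rather
  than silently widening.
* **Representative fraction.** The selection criterion for a
  "representative" fraction is genuinely open; two deterministic
  policies are exposed. `max_copies` (default) picks the in-window
  fraction carrying the most rRNA — the most informative fraction for
  sequencing — with ties broken by density closest to the window
  midpoint, then by lowest fraction index. `mid_density` picks the
  fraction closest to the window midpoint and serves as a sensitivity
  check. Neither is asserted to be the original study's choice.
* **Copy distribution.** Per-gradient copy proportions are computed
  with compensated summation and sum to 1 within 1e-12; an all-zero
  gradient is a degenerate-input error, not a silent NaN.

## 2. Enrichment factor and labeling calls

`EF = r13H/r13L − r12H/r12L`, computed per taxon per (prey, timepoint)
group from the four selected fractions. Conventions:

* **Pseudocount.** Relative abundances add 0.5 reads to every taxon of
  the fraction's taxon universe before normalization (default). This
  keeps EF finite for detected taxa without inventing signal for absent
  ones; with pseudocount 0 a zero light-fraction abundance yields
  status `undefined_ratio` and no labeling call instead of a division
  error. At the default sequencing depths the pseudocount perturbs
  abundances by ≤ 1e-5 and is immaterial to any threshold decision.
* **Abundance filter.** A taxon is evaluated only if it strictly
  exceeds 1% (genus) or 0.1% (ASV) relative abundance in at least one
  ¹³C heavy fraction across treatments × timepoints. The filter is
  evaluated on ¹³C heavy fractions only (incorporators are defined by
  their presence there); an option includes ¹²C heavy fractions for
  sensitivity analysis. All printed thresholds (">1%", ">0.1%",
  "EF > 0.1") are strict inequalities, matching the printed ">"; the
  predator-identity threshold (§3) is inclusive, matching "at least".
* **Missing ¹²C data.** Groups whose ¹²C gradient is absent, or has an
  empty heavy/light window, produce records with status `missing_12C`
  and no EF — they are reported, never imputed. This mirrors dropping
  experimental groups whose ¹²C heavy fractions yielded no usable
  sequencing data.
* **Averaging.** EF is never averaged across groups implicitly. The
  reporting step `summarize_ef` takes the arithmetic mean over
  status-ok records only, because any broader averaging set would
  require imputing missing groups.
* **Display floor.** For log-scale visualization exports, negative and
  small positive EFs are clipped to 10^−1.5 ≈ 0.0316. The floor is a
  display convention only and never feeds a labeling call.
* **Genus aggregation.** ASV counts sum exactly into genus buckets via
  a taxonomy map; semicolon-ranked lineages resolve to the genus entry
  when six ranks are present, otherwise to
  `unclassified:<highest resolved rank>`; unmapped ASVs go to
  `unclassified:unknown`. Column sums are conserved exactly.

## 3. Percent identity and the predator call

Queries are compared to a reference set of 16S sequences from
experimentally verified predatory isolates. A best-hit identity of
≥ 94.5% — genus-level similarity, inclusive — flags a potential
predator.

* **Alignment.** Semi-global Needleman–Wunsch: match +1, mismatch −1,
  linear gap −2, terminal gaps free. This suits near-full-length 16S
  comparisons whose trimmed ends may differ in length. Scoring is
  configurable.
* **Identity denominator.** Matching columns divided by alignment
  columns, excluding columns inside terminal-gap overhangs. Whether the
  original analysis used full-length or common-region denominators is
  unknowable from the text; this convention is documented and
  configurable via the alignment scores.
* **Determinism and symmetry.** The optimal score is unique, but
  co-optimal alignments can differ in identity. The implementation
  fixes: canonical (lexicographic) ordering of the two sequences before
  alignment, end-cell selection by scanning the last row then the last
  column for the first maximum, and traceback preference
  diagonal → gap-in-second → gap-in-first. Identity is therefore a
  deterministic, symmetric function of the sequence pair.
* **Known property.** With free terminal gaps and the
  overhang-excluded denominator, a sequence fully contained in another
  scores 100% identity even though the sequences differ in length; for
  degenerate inputs (e.g. runs of ambiguity codes) a short anchor
  alignment can likewise reach 100%. This is inherent to the
  convention, not a bug; identity 100 guarantees that every counted
  column matches. Near the 94.5% boundary on full-length sequences —
  the regime the screen operates in — the behavior is exact (tests pin
  planted 94.5% accepted, 94.3% rejected on 2 kb sequences).
* **Ambiguity codes.** U→T and case folding are applied before
  alignment; IUPAC ambiguity codes are accepted but never score or
  count as matches.

## 4. Ecology screen

* **Activity ratio** = rRNA-based relative abundance / rRNA-gene-based
  relative abundance; undefined (NaN) when the gene-based abundance is
  zero.
* **Spearman correlation** uses mid-ranks; the two-sided p-value is an
  exhaustive permutation p for n ≤ 10 (exact; worst case 10! ≈ 3.6M
  permutations takes seconds and applies only to small inputs) and the
  t approximation otherwise. Constant vectors have undefined
  correlation and are skipped with a logged reason.
* **FDR control** is Benjamini–Hochberg, by default per variable: each
  performance metric is corrected across taxa, because metrics have
  different sample counts under pairwise-complete-case handling and are
  displayed per metric. A global family is available. Significance is
  `p_adj < alpha` (strict), alpha = 0.05.
* **Group comparisons** use the exact null distribution for n ≤ 12
  tie-free data (Mann–Whitney U unpaired, Wilcoxon signed-rank paired)
  and a normal approximation with tie/continuity corrections otherwise;
  the switch is logged. Identical paired vectors return p = 1
  (no non-zero signed ranks). These delegate to scipy.stats behind the
  module surface; tests verify them against full-enumeration oracles.
* **Pairwise completeness.** Each (taxon, variable) pair uses its own
  complete-case sample set and reports its n, mirroring per-metric
  sample counts in field datasets.

## 5. Synthetic data generator

The simulator defines the study conditions under which the pipeline is
validated.

* **Density model.** Each taxon's rRNA mass distributes over an
  equal-width 13-bin grid (1.780–1.900 g ml⁻¹; fraction density = bin
  midpoint; Gaussian mass is integrated over bin edges) as
  `(1−α)·N(μ₀, σ_bd) + α·N(μ₀ + a·Δ, σ_bd)` with μ₀ = 1.812,
  Δ = 0.045, σ_bd = 0.008 g ml⁻¹ and label purity a = 0.97. μ₀ and Δ
  are calibration parameters chosen so unlabeled mass sits inside the
  light window and ~97 atom%-labeled mass inside the heavy window; they
  are not claims about CsTFA/formamide physics, which is out of scope.
* **Reads.** Each fraction receives exactly `reads_per_fraction`
  multinomial reads with probabilities ∝ baseline abundance × bin mass,
  renormalized within the fraction — the equal-depth-per-sample
  property of amplicon sequencing. Default depth is 100 000 reads per
  fraction, a typical NovaSeq per-sample amplicon yield; at this depth
  the EF noise for a 1%-abundance taxon has SD ≈ 0.06, which sets the
  false-labeling rate of the EF > 0.1 rule under the null at a few
  percent. qPCR copies equal total fraction mass times log-normal noise
  (CV 0.15, unit mean).
* **Community.** Baselines are log-normal (heavy-tailed), roles
  predator/cross-feeder/inactive by largest-remainder apportionment
  (default 5/5/90%). Predators are planted at 1–5% baseline with
  α ∈ [0.5, 1]; cross-feeders get α ∈ [0.1, 0.3] to exercise the
  caveat that labeling can arise indirectly through cross-feeding —
  they are ground-truth-flagged so tests can distinguish direct
  incorporators. The prey spike carries α = 1 and 40–50% of reads at
  amendment time, decaying to ~1% for incubated-timepoint scenarios
  (the default), consistent with the spike contributing nearly half of
  all sequences at amendment and under 1% after early incubation.
* **Diagnostics convention.** Because sequencing depth is fixed per
  fraction, raw read totals are flat across a gradient; the
  across-gradient mass profile lives in the qPCR copies. Density
  diagnostics therefore weight by within-fraction read share × fraction
  copies, which recovers the closed-form mixture means (μ₀ for α = 0;
  μ₀ + 0.97·Δ ≈ 1.8557 for α = 1).
* **What it does not emulate.** Chimeras, primer bias, denoising
  artifacts, variable per-sample depth, compositional spike decay
  dynamics, or respiration kinetics. Passing tests demonstrate the
  statistical machinery is correct and calibrated under the generative
  model, not that the model captures every feature of real gradients.
* **Reproducibility.** All draws derive from a single integer seed via
  spawned generator streams; identical configuration yields
  byte-identical tables.

## 6. Pipeline and I/O

TSV is the canonical interchange (inspectable fixtures); FASTA for
sequences. Count cells must be integers; parse errors name row and
column. Every output table carries `# key: value` headers with the run
seed and a hash of the full configuration; the JSON manifest records
config, inputs, outputs, missing-¹²C groups, and labeled taxa, without
timestamps, so a rerun with identical inputs and configuration is
byte-identical. Paths are recorded as given (use run-relative paths for
location-independent manifests).

## 7. Problem sizes in the test and acceptance runs

Simulation-based checks use 20 seeds at the default study conditions
(150 taxa, 100 000 reads/fraction, 13 fractions); EF-formula agreement
uses 100 randomized four-fraction tables; alignment agreement uses 200
random pairs of length ≤ 30 plus 2 kb boundary sequences; the
correlation-screen null uses 50 taxa × 5 variables × 50 samples per
seed. These sizes give stable pass/fail behavior for the calibration
bounds checked (e.g. ≤ 5% false labeling under the null) while the full
suite runs in well under a minute of simulation time.

## 8. Known limitations

* EF is a ratio statistic; its sampling noise grows quickly below ~0.5%
  taxon abundance, which is why the abundance filter precedes labeling.
* Quantitative isotope-incorporation estimation (qSIP-style
  excess-atom-fraction modeling) is out of scope; EF orders taxa by
  enrichment but its magnitude is depth- and composition-dependent.
* Cross-feeders genuinely acquire label; the pipeline flags them as
  labeled (correctly), and distinguishing direct predation requires the
  simulator's ground truth or experimental controls.
* The predator call is a sequence-similarity inference; 94.5% identity
  to a verified predator is evidence of genus-level relatedness, not
  proof of predatory behavior.
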