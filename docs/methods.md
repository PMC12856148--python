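# Methods

## Ground-truth model

The benchmark treats mouse peptides in a mixed human/mouse sample as
surrogates for substitution-containing peptides. Two proteomes are digested
in silico with the same rules the search engines use — cleavage C-terminal
to K or R except before proline, up to 2 missed cleavages, peptide length
6–61 — and, for every orthologous gene pair, all equal-length
(human peptide, mouse peptide) combinations at Hamming distance exactly 1
become *cognate pairs*. The pair's single mismatch is the ground-truth
SAAV, oriented human→mouse. Equal length + distance 1 is the operational
definition throughout: a single substitution cannot change peptide length,
and indels are out of scope. Protein N-terminal methionine is not specially
removed; the digestion parameters define no N-terminal processing, and the
length filter is applied after enumeration so missed-cleavage products face
the same bounds. Positions are 1-based everywhere.

Gold-standard PSMs are the closed-search PSMs (against the concatenated
two-species database) whose peptide is the mouse member of a cognate pair,
matched by exact string equality — the closed search assigns database
sequences, so I and L are disambiguated there. For dependent-peptide-style
tools, a stricter gold set additionally requires the cognate human peptide
in the same sample, since such tools can only explain a spectrum as a
modified form of an already-identified base peptide. Because neither
closed-search tool is perfect, a *mixed* gold standard uses the per-sample
intersection of the two tools' gold sets as the denominator for
sensitivity (strict ground truth) and their union for precision (lenient —
a candidate that either tool supports should not count as false).

## SAAV assignment from mass shifts

The caller considers every ordered residue substitution, with Leu/Ile
destinations collapsed to one isobaric class 'X' per origin (362 entries;
for origins I and L the 'X' entry is the zero-shift I↔L exchange). A PSM
with base peptide, observed shift and a single localized site is accepted
when (1) the candidate pair minimizes the absolute difference between
observed and theoretical shift, (2) that minimum is below 0.1 Da (strict
inequality, configurable), and (3) the pair's origin equals the base
residue at the site. The criteria apply in that order: a nearer pair with
the wrong origin blocks a farther correct one, deliberately reproducing the
conjunction even though it discards some recoverable calls. Exact ties in
the minimal difference (the +CH2 family and other isomass pairs) are
resolved by the origin criterion; with the standard mass table at most one
entry per origin can survive, and a residual tie under a custom table is
rejected rather than guessed. Engine-specific localization policies gate
entry to the caller: exactly one site with probability strictly > 0.5
(dependent-peptide style), exactly one resolved site (open-search style),
or any non-null site (generic). Pre-assigned substitutions from engines
that output SAAVs directly bypass the nearest-pair search but are still
validated against the origin criterion, with destinations collapsed to 'X'.

Masses are standard monoisotopic residue masses stored to 5 decimals
(cross-checked in the tests against pyteomics' `std_aa_mass`); proton
1.00728 Da, water 18.01056 Da.

## Evaluation

All scoring is at the PSM level. A candidate is a true positive when its
(sample, spectrum) key is in the gold set and its variant peptide equals
the gold mouse peptide with 'X' matching I or L at the variant site — so a
true positive implies SAAV identity up to I/L ambiguity, not merely
spectrum overlap. Metrics with empty denominators are reported as missing,
never coerced to zero, and are excluded from the median aggregation across
samples (medians match how per-sample box-plot summaries are usually
reported; the aggregation function is configurable). Percentages appear on
the 0–100 scale in outputs; fractions internally. Per-SAAV stratification
scores each substitution type separately (sensitivity over gold PSMs with
that true SAAV, precision over candidates calling it), and multi-tool
combination keys candidates by (sample, spectrum, variant under I/L
equivalence), taking per-sample unions or intersections. The misassignment
census cross-tabulates called vs true SAAVs for false candidates together
with the theoretical mass-shift difference per cell; cells at Δ≈0 with a
shifted site diagnose mislocalization — the failure mode in which a
preset-substitution closed search absorbs an isobaric true SAAV at the
wrong position.

Tool comparisons over per-sample metric vectors use a two-sided rank-sum
test; the quality separation check is one-sided (correct calls should have
smaller RT deviation and larger spectral angle).

## Quality metrics

`RT_delta = |RT_observed − RT_predicted|`; smaller is better. The
normalized spectral angle is `SA = 1 − 2·arccos(⟨ŝ₁, ŝ₂⟩)/π` with
unit-L2-normalized intensity vectors over matched peaks; unmatched peaks
contribute zero to the counterpart, making SA 1 for identical and 0 for
disjoint spectra. Peak matching is greedy nearest-m/z within ±0.02 Da,
each peak used at most once — simple, deterministic, and adequate for
stick spectra. The fragment generator produces singly charged b/y ions
with unit intensities (b_i = Σ residues 1..i + proton; y_i = Σ last i
residues + water + proton); higher charge states, neutral losses and
isotope envelopes are out of scope. Deep-learning RT/spectrum predictors
are likewise out of scope: the simulator supplies predictions from its own
devices (below) so the quality metrics are testable end to end.

## Synthetic-data generator

The generator emulates the statistical structure of a mixed-species
benchmark experiment; all randomness flows through one seeded NumPy
generator, so identical (config, seed) reproduce outputs exactly.

* **Proteomes.** Residues are sampled with K and R enriched to 10% each
  (others uniform) so tryptic peptides of in-range length are common even
  at small gene counts. Mouse orthologs copy the human sequence with
  per-residue substitution probability `saav_rate`; with probability
  `same_category_bias` the destination is drawn uniformly within the
  origin's biochemical category (excluding self), otherwise uniformly
  among residues of other categories, making the injected same-category
  fraction exactly Bernoulli(bias) — the property the census recovery
  check relies on. Peptides acquiring ≥2 substitutions simply never enter
  the catalog (the distance-1 filter), mirroring reality.
* **Closed search.** Per sample, each spectrum draws a mouse peptide with
  probability `mouse_psm_fraction`, else a human peptide. Gold-eligible
  PSMs appear in both simulated tools with probability `tool_overlap`,
  else in exactly one (uniformly); non-gold PSMs appear in both, modeling
  confidently identified species-typical peptides.
* **Open search.** Each gold PSM is detected with probability
  `detection_rate` and emitted with the human cognate as base, the true
  shift and site, then corrupted: `misloc_rate` moves the site elsewhere,
  `wrong_shift_rate` offsets the shift by ±0.2–2.0 Da (always beyond the
  0.1 Da tolerance, so such rows can never be "accidentally correct").
  Human PSMs spawn spurious candidates with probability `background_rate`
  (random site, exact shift of a random substitution whose origin matches,
  so background rows pass the caller and stress precision). Labels record
  the error mode per emitted row; only uncorrupted gold detections are
  `correct`, which gives exact label-bookkeeping identities: pipeline TP
  count equals the number of correct labels, so measured precision and
  sensitivity can be checked against configured rates.
* **RT and spectra.** Predicted retention time is a linear function of
  summed Kyte–Doolittle hydropathy (slope 0.3 min/unit, intercept 30 min) —
  a device, not a chromatographic claim. Observed values follow the *true*
  peptide (Gaussian noise, `rt_noise_sd`); predictions use the *called*
  variant, so incorrect calls separate on both metrics. Experimental
  spectra are the true peptide's b/y sticks with log-normal intensity
  jitter; 'X' residues render as Leu (isobaric, so fragment m/z are
  unaffected; only the small I-vs-L hydropathy difference leaks into RT).

### Defaults (the emulated study conditions)

| parameter | default | rationale |
|---|---|---|
| `n_genes` / `protein_length_mean±sd` | 200 / 350±100 aa | typical protein length; enough genes for ~7,500 cognate pairs |
| `saav_rate` | 0.05 per residue | approximates human–mouse protein divergence |
| `same_category_bias` | 0.575 | observed same-category fraction of cross-species SAAVs |
| `mouse_psm_fraction` | 0.30 | median mouse PSM share in xenograft closed searches |
| `n_psms_per_sample` / `n_samples` | 5,000 / 4 | desk-scale stand-in for tens of thousands of PSMs over ~24 samples |
| `tool_overlap` | 0.67 | median gold-PSM overlap between two closed-search tools |
| `detection_rate` | 0.5 | typical open-search sensitivity on gold PSMs |
| `misloc_rate` / `wrong_shift_rate` / `background_rate` | 0.2 / 0.05 / 0.05 | dominant, minor and spurious error modes |
| `rt_noise_sd` | 0.5 min | chromatographic reproducibility scale |
| tolerance | 0.1 Da, strict < | the SAAV-calling mass window |

The problem sizes above (and the smaller ones some tests use) were chosen
as the package's own desk-scale defaults; metrics stabilize well below
these sizes.

### What the generator does *not* model

Real spectra (chimeras, co-isolation, intensity structure), search-engine
score distributions and FDR behavior, isotope errors, PTMs that mimic
substitutions (e.g. methylation vs D→E — mass alone cannot distinguish
them, a caution that applies to any mass-shift SAAV caller), correlated
detection between tools, TMT quantification, and paralog ambiguity beyond
the one-to-one ortholog map. Passing tests therefore demonstrate the
*bookkeeping and statistical machinery* are correct under a known model,
not that any particular engine achieves these numbers on real data.

## Numerical choices and degenerate inputs

Theoretical-shift ties are detected with a 1e-9 Da slack on the minimal
difference, far below the 5-decimal mass resolution. Census ranking breaks
count ties lexicographically. Chimeric closed-search rows (several peptides
per spectrum) keep the best-scoring row. Duplicated human symbols in the
ortholog map keep the first mapping with a warning; malformed lines are
errors with line numbers. Empty gold intersections are valid (warned);
empty candidate sets leave precision undefined. Records with non-standard
residues (X, U, B, Z...) are retained on read but skipped by digestion with
a logged count. Every output table carries a header comment with the
package version and a hash of the resolved configuration, and reruns under
a fixed config and seed are byte-identical.

## Known limitations

The biochemical five-category partition (nonpolar/aromatic/polar-uncharged/
positive/negative) is one of several defensible schemes; it is configurable,
and category-dependent results should be read relative to it. The
union/intersection machinery is implemented for the two-closed-tool design;
more tools combine pairwise. I/L ambiguity is resolved only where sequence
evidence exists (catalog and gold sides); mass-based calls always report
'X'. The statistical utilities are rank-based only; no multiple-testing
correction is applied across per-SAAV strata.
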