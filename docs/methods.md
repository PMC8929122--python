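# Methods

## The screening model

The package treats bioactive-peptide discovery as a staged decision
procedure over a peptide pool. Each stage is a pure function of per-peptide
inputs, so the funnel is deterministic and auditable: the report records,
for every input peptide, the stage at which it left the funnel and why.

1. **Rank filter.** An external general-bioactivity predictor assigns each
   peptide a score in [0, 1]; peptides with score strictly above a threshold
   (default 0.4) proceed. The default is deliberately below the predictor
   authors' suggested 0.5, reflecting the observation that many known
   DPP-IV inhibitors score in the 0.4–0.5 band. The threshold is strict
   ("above 0.4"), so a score of exactly 0.4 is excluded. A record with no
   score is excluded with its own removal reason — the predictor not having
   been run is not a pass. Setting `rank_threshold=None` skips the stage
   for pools rank-screened upstream.
2. **Binding filter.** An external active-site binding predictor assigns a
   p-value in (0, 1]; peptides strictly below the threshold (default 0.01)
   proceed. Strict again; missing values are excluded, not passed. If an
   upstream tool reports several p-values per peptide, the caller should
   take the minimum (the most confident prediction) before building the
   record — the record type holds a single value.
3. **Novelty partition.** Survivors are looked up in the known-bioactivity
   reference by exact, case-insensitive, full-length identity. Exact
   matching is the only defensible reading for a table dominated by
   di-peptides: substring matching would make almost every pool member
   "known". Peptides already annotated with the target activity are set
   aside as known; the rest are novel and proceed.
4. **SAR selection.** Novel peptides are matched against the feature
   catalog (below); those with at least `min_features` (default 2)
   selection-eligible matches become validation candidates.

Stage counts are monotonically non-increasing, known + novel equals the
binding-filter survivors, and the selected set is a subset of the novel
set; these identities are enforced by property tests over random pools.

## SAR feature catalog

The catalog encodes positional residue features reported for potent
(IC50 < 100 μmol/L) DPP-IV-inhibitory food peptides:

| id | feature | applies to |
|---|---|---|
| F1_HYDRO_NTERM | I/L/V/A/F/W at the N-terminus | length ≥ 2 |
| F2_PA_POS2 | P or A in second position | length ≥ 2 |
| F3_Q_NTERM | Q at the N-terminus | tri-peptides only |
| F4_HYDRO_CTERM | A/I/L/G/M/F at the C-terminus | tri-peptides only |
| F5_PLR_CTERM | P/L/R at the C-terminus | length ≥ 4 |
| F6_AVGP_POS3 | A/V/G/P in third position | length ≥ 4 |
| S_NTERM_NOVEL | S at the N-terminus | annotation only |

Design choices that were genuinely open:

- **Selection rule.** The literature states that selected candidates "met
  the structural characteristics" without giving combinatorial logic. The
  ≥2-eligible-features rule is the minimal rule that reproduces the known
  accept/reject pattern on the six bundled novel candidates (the three
  selected tetra-peptides each match exactly two eligible features; the
  rejected FT and FV match one, PR none). It is exposed as `min_features`.
- **"Third position" vs "penultimate position".** The two formulations
  coincide for tetra-peptides, which is where the rule was derived. For
  longer peptides the engine tests position 3 from the N-terminus (the
  formulation the rule set states) and logs a warning that the readings
  diverge.
- **S at the N-terminus** is a proposed marker, not an established rule;
  it is reported in results but never counted toward selection, so adding
  it cannot change any verdict.
- No tetra-peptide length requirement is imposed: the ≥2 rule alone
  reproduces the selection outcome, and longer peptides may legitimately
  match F5/F6.

## In silico digestion

The digestion simulator is a pool *generator*, not a kinetic model of
gastric emptying or enzyme saturation: every bond permitted by a rule is
cut, optionally leaving up to `missed_cleavages` internal sites uncut.
Rules use PeptideCutter-style specificity — cleave C-terminal of a P1
residue unless the P1' residue blocks:

- pepsin (pH > 2): after F/L/W/Y, blocked by P — the gastric phase;
- trypsin: after K/R, blocked by P;
- chymotrypsin (high specificity): after F/Y/W, blocked by P.

Pancreatin is represented by trypsin + chymotrypsin acting jointly (union
of sites) in the intestinal phase; elastase and the carboxypeptidases are
omitted as their specificity is broad and poorly captured by P1 rules.
Phases apply sequentially: gastric rules to the intact protein, intestinal
rules to every gastric fragment. A fragment untouched by a later phase
keeps its earlier phase label. Coordinates are 1-based inclusive on the
precursor; every fragment equals the precursor substring at its
coordinates, single-phase zero-missed fragments tile the protein exactly,
and the fragment set grows monotonically in `missed_cleavages` (all three
are property-tested on random proteins). Fragments shorter than two
residues are kept in the digest result but excluded from screening pools.

## Dose–response model

Inhibition follows a Hill curve with asymptotes pinned by the assay
definition (0% inhibition at zero inhibitor, 100% at saturation):

    inh(c) = 100 · cʰ / (IC50ʰ + cʰ)

with IC50 > 0 (μmol/L) and slope h > 0. Fixing the asymptotes leaves two
free parameters, appropriate for the 8-level designs typical of microplate
assays; a four-parameter logistic would be under-determined at the noise
levels simulated here and can drift to non-physical asymptotes.

**Estimation.** The default estimator is nonlinear least squares over all
replicate points, parameterized as (log₁₀ IC50, h) for conditioning,
initialized at h = 1 and the geometric mean of the two concentrations
bracketing 50% mean inhibition (median concentration as fallback);
convergence tolerances are 1e-10 (xtol) and 1e-12 (ftol). The standard
error of IC50 is obtained from the covariance of log₁₀ IC50 by the delta
method. The alternative `interpolation` estimator log-linearly interpolates
mean inhibition between the two levels bracketing 50% — the closest literal
reading of "plot log concentration against inhibition and read off 50%" —
and reports no slope or uncertainty. An IC50 outside the tested
concentration range is flagged `extrapolated` rather than rejected.

**Simulator.** One simulated assay is 8 log-spaced concentration levels
spanning 1–1000 μmol/L in triplicate (mirroring the triplicate structure of
the wet assay), with independent Gaussian noise of SD 3 percentage points
added to the model mean. Values are not clamped to [0, 100]: truncation
would bias the fit, and plate readers do report slightly negative or
super-100% inhibition. All randomness comes from one explicitly seeded
`numpy` generator per dataset; identical configurations are bit-for-bit
reproducible. For the weakest candidate potency (480.6 μmol/L) the grid is
extended to 1–5000 μmol/L so that 50% inhibition is bracketed by the
design; fitting an unbracketed curve is possible but needlessly fragile.

**What the simulations do and do not show.** Parameter recovery (100
seeded assays per potency; mean estimate within 5% of the generating IC50,
verified in the acceptance suite at well under a minute of CPU) shows the
estimator is unbiased under the stated noise model. It does not validate
the wet-lab potencies themselves — those are measurements, not model
outputs — nor does the Gaussian-noise model capture plate-position
effects, serial-dilution errors (which correlate across levels), or
substrate depletion at long incubation times.

## Bundled fixtures and their limits

The package ships two desk-scale fixtures transcribed from a published
screen of in vitro-digested pinto bean protein: the 37-entry
known-bioactivity reference and the 15-peptide screening pool with binding
p-values. They make the funnel reproducible end-to-end without network
access. They are not a general bioactivity database: lookups against them
answer "was this peptide in that screen's reference set", and real
screening should point `--reference` at a current BIOPEP-style export.
The full 95-peptide peptidome and its upstream rank scores are not
published, so the rank-filter stage (21-of-95 retained) cannot be
reproduced from the fixtures; the bundled pool enters the funnel with the
rank stage skipped.

## Known limitations

- Isobaric residues (I vs L) are taken at face value from the input; MS
  cannot distinguish them, so pool sequences inherit that ambiguity.
- No post-translational or chemical modifications; the canonical
  20-letter alphabet only.
- The digestion rules are a deliberately minimal dialect; real digests
  show partial cleavage kinetics the simulator does not model.
- The SAR catalog is fixed to the DPP-IV feature set; other activities
  need their own catalogs.
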