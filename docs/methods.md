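# Methods

## Model and assumptions

`urinpep` infers protease activity changes indirectly, from the abundance
trends of naturally occurring peptides. The chain of assumptions is:

1. a peptide terminus inside its parent protein (start > 1, or stop short of
   the parent's C-terminus) was produced by an in vivo cleavage;
2. a curated table of experimentally observed cleavage sites identifies
   which protease(s) could have made that cut;
3. if the peptides attributable to a protease are predominantly more
   abundant in cases than controls, the protease was more active (and
   conversely).

None of these steps is exact — proteases share substrates, peptide
abundance also reflects filtration and further degradation, and the site
table is incomplete — so the output is a ranked hypothesis list, not a
measurement. The score deliberately has no statistical uncertainty attached;
external evidence (transcriptomics, protein expression) is consumed as
direction calls for concordance annotation only.

## Coordinates and conventions

Peptide coordinates are 1-based inclusive throughout (the UniProt
convention); an N-terminal cleavage event has P1 = start − 1, a C-terminal
event P1 = stop, and a terminus flush with the parent's own end is not an
event. An absent abundance cell means "not detected" and is read as 0.0, with
no imputation — this matches how CE-MS peptide profiles report absence of
signal. Modified peptide sequences carry their modifications as free-text
annotation; positions and lengths always use the plain residue string (how
modified peptides should be positioned for site lookup is not standardised;
plain-sequence coordinates are the conservative choice).

## Differential testing

* **Test.** Two-sided Mann–Whitney U. The exact null distribution is
  enumerated when the combined sample size is ≤ 12 and the data are tie-free;
  otherwise the normal approximation with midranks and the tie-corrected
  variance is used, *without* continuity correction, so that identical
  groups give p = 1 exactly and the statistic is antisymmetric. The
  approximation is accurate to a few hundredths at the cutoff (checked
  against enumeration in the tests); at realistic cohort sizes (tens per
  group) the difference is negligible.
* **Multiplicity.** Benjamini–Hochberg step-up adjustment across all tested
  peptides; no detection-frequency pre-filter is applied, so the adjustment
  spans the full detected list.
* **Gates.** Regulation requires adjusted p < `alpha` (default 0.05) *and* a
  fold-change gate: mean(case)/mean(control) > 1.5 for up, < 0.66 for down.
  The asymmetric pair (1.5, 0.66) is kept verbatim rather than symmetrised
  to 1/1.5 = 0.667, since the asymmetric form is how such gates are commonly
  published. Fold change uses group means of raw (not log) abundances:
  "change in abundance" is a statement about means of signal. A control mean
  of 0 with case signal gives +inf (up if significant); both means 0 is
  undefined and never regulated.

## Protease matching

Cleavage events from regulated peptides are matched to the site table in two
modes: exact (substrate accession, P1) identity, and cross-substrate octamer
identity — the event's P4..P1|P1′..P4′ context (padded with `-` at protein
ends) equals the octamer of a table entry on a different protein. Exact
octamer equality with a 4+4 window is the strictest defensible reading of
"observed in different substrate" evidence; the window is configurable.
N- and C-terminal events are pooled against the same table, and matches are
deduplicated to unique (protease, peptide) pairs — so downstream occurrence
counts are numbers of peptides, not termini — with the same-substrate mode
recorded when both occur.

## Activity score

Definitions (per protease, over regulated peptides only):

    occ(up), occ(down)  its up-/down-regulated associated peptides (unique)
    n(up), n(down)      totals of up-/down-regulated associations over all
                        predicted proteases, with multiplicity, before the
                        minimum-peptide filter
    weight              occ(down)/n(down) + occ(up)/n(up)
    %freq               (occ(up) − occ(down)) / (occ(up) + occ(down)) · 100
    Score               %freq · weight

The compound freq%(up)/freq%(down) form in the module docstring simplifies
to the %freq expression above; both are computed and their equality is a
test invariant, together with sign coupling (sign(Score) = sign(occ(up) −
occ(down))), antisymmetry under swapping up↔down, and invariance of %freq
under common scaling. Using association totals (not unique-peptide or
cohort-wide regulated totals) as denominators is what makes the bundled
published count table reproduce its published scores exactly; the bundled
totals are n(up) = 93, n(down) = 42, which sum to that study's 135
protease–peptide associations. Reported values are rounded for display
(score to 2 decimals, %freq to integer); full precision is kept in the JSON
output. Reporting requires ≥ 3 associated regulated peptides (default);
ranking lists activated proteases by descending score, then deactivated by
ascending score, ties broken alphabetically for determinism.

Degenerate inputs: scoring aborts when there are no associations at all, or
when either association total is zero (every regulated association pointing
one way leaves the weight's other denominator undefined); the pipeline then
reports an empty protease table rather than inventing a convention.

## Concordance

`agree` ⟺ (activated ∧ increase) ∨ (deactivated ∧ decrease); `oppose` for
crossed directions; `no_change` and `inconclusive` evidence pass through as
their own verdicts (neither agreement nor opposition); absent evidence is
`missing`. How conflicting external datasets are collapsed into a single
`inconclusive` call is editorial, not algorithmic — the label is accepted as
input.

## Synthetic cohorts

The generator emulates a two-group CE-MS study at desk scale. Abundances
are log-normal — positive, right-skewed, like CE-MS signal intensities —
with a multiplicative case/control fold (`effect_size`) applied to the
peptides of non-null proteases. Defaults: 30 cases vs 30 controls; 6
activated + 6 deactivated + 5 null proteases with 2 planted sites each and
5 peptides per site (10 peptides per protease); effect 4×; noise σ = 1.0 on
the natural-log scale (a broad, realistic spread for urinary peptide
signal); 48 background peptides (⅓ up, ⅓ down, ⅓ null) on proteins without
site entries; protein lengths 200–400 over the 20-residue alphabet. Planted
sites are spaced ≥ 40 residues apart and each peptide is anchored to its
site on exactly one terminus, the free terminus kept clear of other sites,
so the planted protease–peptide associations are exactly what a correct
matcher recovers and occ counts stay interpretable.

What the simulation does *not* model: CE migration/calibration, PTMs,
correlated peptides from shared parents, missingness structure, batch
effects, or realistic cleavage-site sequence specificity. Passing recovery
tests therefore demonstrates the pipeline's correctness and power under a
clean generative model, not performance on real cohorts.

Problem sizes in the test suite (218 peptides per cohort, 20 seeds for the
recovery and null checks) were chosen as the smallest cohorts at which the
planted 4× effect is comfortably detectable at n = 30/30 — desk-scale
stand-ins, since the original 239-patient CE-MS dataset is not publicly
deposited.

## Known limitations

* The score is a descriptive index; no null distribution or FDR is defined
  for it.
* Cross-substrate matching by exact octamer identity misses near-identical
  sites; a looser similarity threshold would trade specificity for recall.
* One-sided regulation (no down-regulated associations at all, or no up)
  leaves the score undefined rather than falling back to a pseudo-count.
* The bundled published count table includes only the 17 reported proteases;
  the remaining 13 predicted proteases' counts are folded into the totals
  (93/42) but are not listed individually in the source.
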