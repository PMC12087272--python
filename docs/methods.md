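# Methods

## Model and assumptions

The toolkit operates entirely on condensed (per-atom) quantities obtained
from three single-point electronic-structure calculations at a fixed
geometry: the N-electron reference, the cation (N−1) and the anion (N+1).
It performs no electronic-structure work itself; partial charges and total
energies are inputs. The descriptors assume:

- the three charge states share one atom set and one geometry (vertical
  differences);
- per-state charges sum to the state's net molecular charge — this is what
  makes each condensed Fukui flavour (f⁻, f⁺ and their average f⁰) sum to
  exactly one over the whole molecule, and it is validated at load time
  (default tolerance 1e-3 e, matching tables rounded to 3–4 decimals);
- for aromatic C–H sites, the hydrogen's charge belongs to its carbon:
  `sum_hydrogens` folds each hydrogen into its mapped heavy atom before the
  finite differences are taken. The summing conserves per-state totals
  exactly and is idempotent.

The R-GPRI ranks sites by Ξ = (κ+1)q⁰ − ΔN(κ−1)f⁰ (equation 1; the
all-signs-flipped equation 2 serves the electrophile-like case). It inherits
the usual early-transition-state assumptions of interaction-energy
indicators: the attacking radical enters only through the scalars κ and ΔN,
and the smallest Ξ marks the attacked site. The identity
Ξ₂(q, f; ΔN) = Ξ₁(−q, f; −ΔN) means the two equations are mirror images;
this is why the ΔN windows of the two radical roles mirror each other.

Which equation applies is decided by comparing Mulliken electronegativities
χ = (I + A)/2 with I = E(N−1) − E(N), A = E(N) − E(N+1): a radical more
electronegative than the substrate accepts electrons (electrophilic radical,
equation 1 on the substrate). χ equality is a hard error rather than a
silent default — the decision procedure is a strict comparison and a tie
carries no information; callers must then state the role explicitly. A
negative electron affinity is legal and only logged.

## Grids, regions and votes

The paper-derived region bounds are, for electrophilic radical attack,
κ ∈ [−1.0, −0.4] with ΔN ∈ [−0.8, 0.2] ("black box", electron-transfer
control), κ ∈ [−1.4, −1.2] with the same ΔN window ("pink box", stronger
electron-transfer control), and their union (ERRC). For nucleophilic attack
the ΔN window mirrors to [−0.2, 0.8]. Interval bounds printed in descending
order are normalized to [min, max]; the ΔN windows are taken exactly as
printed even though they cross zero (a mirrored variant is available via
`mirror_delta_n` for sensitivity checks). No grid step is prescribed by the
source material; the default is 0.2 with inclusive endpoints, giving a
6 × 6 (κ × ΔN) RTT of which the black box covers 24 cells and the pink box
12. Both the grid and the regions are configurable.

Numerical choices:

- Per-cell ties in Ξ are grouped at an absolute tolerance of 1e-12; every
  member of a tied choice is recorded and credited one vote, which keeps the
  tally deterministic and order-independent.
- The cell (κ = −1, ΔN = 0) lies inside the default black box and is
  degenerate: both terms of Ξ vanish, every site ties, and the cell ranks
  nothing. Cells whose first-choice tie spans all sites are therefore
  excluded from the vote tally (so the default black/pink/ERRC tallies are
  23/12/35 informative cells). Crediting such cells would both inflate the
  counts and make the appears-in-at-least-one-cell sets — the basis of the
  "!" verdict — vacuously full.
- Vote ties are reported as site sets, never broken; downstream scoring
  treats any member as a match.
- The second-choice prediction comes from the second-choice cell counts,
  not from the runner-up of the first-choice counts: the per-cell second
  smallest Ξ is its own defined quantity.

## Reference rankings and verdict symbols

Reference rankings are built from activation enthalpies ("Cal", ascending)
or experimental yield ratios ("Exp", descending; ratio 0 and absent entries
both mean "no isolated product" and are excluded). Sites within the tie
threshold — 2 kJ/mol for ΔH‡, 0.2 for yield ratios, inclusive by default
with a strict variant switchable — of a group's best value are equivalently
reactive. Grouping is anchored at the group's best value rather than chained
pairwise, which bounds group growth and reproduces the three-site groups of
the reference study.

A tie group of k sites occupies reference ranks 1..k. Concretely, the rank-2
reference consists of the leftover of a ≥2-site best group followed by the
next group. A prediction hitting a tie group of three or more sites scores
✓‡ rather than ✓: with three-plus equivalently reactive sites there is no
clear preference to be "correct" about. The inverted-pair verdict ✓* fires
only on a strict swap — first prediction confined to the reference second
group *and* second prediction reaching the reference best group — and then
covers both ranks. "!" is reserved for region-vote models and fires when the
reference site appears in at least one cell of the region at that rank.
Everything else is ⨯; a missing reference rank yields the non-verdict
`none`, excluded from all denominators. The default success set is
{✓, ✓*, ✓‡, !}, configurable.

## The packaged study and its audit

The embedded reference study (14 heteroarenes × 5 ring sites × 2 radicals;
ΔH‡ in kJ/mol at 298 K, yield ratios, condensed f⁰ per site, plus the
published per-cell verdicts of the Fukui-function model) is stored verbatim
— including "(0)" and "−" entries, so parsing policy stays in code — and
checksummed; `packaged_dataset()` refuses corrupted tables. Ground-state
condensed charges of the real heteroarenes are not part of the published
main-text data, so R-GPRI transition tables for those molecules require
user-supplied charge tables; the packaged harness audits the Fukui-function
model, and the R-GPRI path is exercised end-to-end on synthetic and
user-supplied data.

`rff_scorecard()` recomputes all 112 Fukui-model verdicts. Under the default
rules above, 105 match the published table; the seven that do not
(`DOCUMENTED_DEVIATIONS`) are internal inconsistencies of the published
verdicts, not free parameters of the harness — no single rule set can
satisfy them and the cells they conflict with simultaneously:

- reactions 10 and 11 + CF₃ apply the 2 kJ/mol rule to a 1.7 kJ/mol span
  (✓‡), while reaction 12 + CF₃ leaves an even tighter 1.0 kJ/mol span
  ungrouped (printed ✓; recomputed ✓‡, both ranks);
- reaction 14 + CF₃ (Exp) prints ⨯ for the identical swap pattern that
  reaction 11 + CF₃ prints as ✓* (recomputed ✓*, both ranks);
- reaction 10 + *i*-Pr leaves a 0.1 kJ/mol gap ungrouped, so its published
  rank-2 ⨯ conflicts with the tie rule (recomputed ✓);
- reaction 13 + *i*-Pr prints ✓* although the strict pair-swap condition
  fails there (recomputed ⨯/✓).

Each recomputed call carries a rationale string naming the clause that
fired, so the audit trail is per-cell. Aggregate accuracy fractions are
always recomputed from the emitted calls, never restated.

## Synthetic data

The generator fabricates molecules that *satisfy the descriptor
assumptions exactly*: per-heavy-atom f⁻ and f⁺ drawn from Dirichlet
simplices (concentration 5.0, giving realistically uneven Fukui weights
around a 1/6 mean), heavy-atom charges at Hirshfeld scale (σ = 0.08 e)
shifted to the exact net charge, one hydrogen per labeled carbon carrying a
5–30 % share of its site's Fukui weight, and energy triples with
I ∈ [0.25, 0.45], A ∈ [0.01, 0.15] hartree, I > A > 0. Defaults mirror the
reference study's shape: 14 molecules, five labeled ring carbons plus a
ring nitrogen. All randomness flows through one seeded generator; a spec's
seed fully determines the output.

Synthetic *studies* additionally fabricate barriers affine in Ξ at a chosen
grid point (default κ\* = −0.8, ΔN\* = −0.3, the representative
electron-transfer conditions for an electrophilic radical; offset 50 kJ/mol,
slope 150 kJ/mol per Ξ unit, placing barriers in the observed 15–60 kJ/mol
range) plus Gaussian noise, and yield ratios as a Boltzmann-like transform
of the clean barriers (scale 2.5 kJ/mol, detection cutoff 5 % of the top
rate, smallest kept ratio normalized to 1). Unit noise is drawn
independently of its scale, so accuracy-versus-noise comparisons share
draws. What passing recovery tests shows: the pipeline inverts its own
generative model perfectly at zero noise and degrades monotonically with
noise. What it does not show: performance on real charge distributions,
where the affine Ξ–ΔH‡ link is only an approximation (observed correlations
on real systems span R² ≈ 0.65–0.99 and are reproducible only with
user-supplied charge data), and where population-scheme artifacts (e.g.
negative condensed Fukui values, which the code accepts and reports as-is)
can occur.

Test problem sizes are chosen to pin the properties tightly at interactive
runtimes: 1000 randomized descriptor sets against the brute-force sort
oracle, 25 molecules for normalization checks, 200 molecules × 3 noise
levels for the monotonicity check, 400 Monte-Carlo replicates for the R²
calibration (tolerance 0.08, covering the small-sample upward bias of R² at
n = 10 sites plus Monte-Carlo error).

## Known limitations

- No quantum chemistry: geometries, charges, energies and barriers are
  inputs. Hirshfeld charges are assumed but not enforced.
- Hydrogen-attachment inference is geometric (nearest heavy atom within
  1.2 × the summed Cordero covalent radii; exact distance ties are
  rejected) and is a convenience for well-formed geometries, not a bond
  perception algorithm.
- Multiplicity bookkeeping for the N±1 states of open-shell species is the
  data producer's responsibility; the descriptors treat radicals and
  closed-shell molecules identically.
- The κ > 1 strongly-electrostatic regime is representable in custom grids
  but no region semantics are attached to it.
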