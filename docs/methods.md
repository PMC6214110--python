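# Methods

`ligphore` implements a ligand-based 3D-QSAR pharmacophore workflow of the
kind popularized by Catalyst/HypoGen and applied to ANO1 (TMEM16A) channel
inhibitors: perceive chemical features on conformers of known inhibitors,
generate quantitative hypotheses that correlate feature geometry with
IC50, validate the model statistically, and screen compound libraries for
new candidate inhibitors. This note documents the model, its parameters,
the synthetic-data design, and the numerical choices.

## Feature perception

A conformer is reduced to a cloud of typed points:

* **HBD** — N–H/O–H donors (anions that have already lost the proton are
  excluded), placed on the donor heavy atom, direction along the mean
  H-bond axis;
* **HBA** — N/O acceptors with an available lone pair (amide N,
  pyrrole-type aromatic N–H, oxidized and protonated N excluded), placed
  on the heavy atom, lone-pair axis direction;
* **HY** — centroid of each connected cluster of ≥ 2 non-polar carbons or
  halogens not adjacent to polar/charged atoms; a ring is one cluster;
* **RA** — centroid of each 5/6-membered fully aromatic ring, ring-normal
  direction.

The chemistry lives in a versioned SMARTS rule file
(`ligphore/data/feature_rules.yaml`) and can be overridden. Directions are
stored but not scored in the current mapping (centroid-only scoring); the
data model keeps them so a vector-aware scorer can be added without a
format change. Perception is purely topological plus coordinate
averaging, so feature positions are exactly equivariant under rigid
motions of the input conformer.

Molecules are prepared at a fixed pH-7.4 ionization rule set (carboxylic
acids deprotonated, aliphatic amines protonated; no pKa engine).
Conformers come from RDKit ETKDG with MMFF94 minimization, capped at
`max_conformers` (default 255) within an `energy_window` (default
10 kcal/mol) above the ensemble minimum; the embedding seed is explicit
(default 20181017) and generation is deterministic per seed.

## Hypotheses, mapping, and fit

A hypothesis is 3–5 typed features, each with a centroid (Å), a distance
tolerance *t* (default 1.6 Å), and a weight *w* (default 2.0), plus an
activity calibration (b₀, b₁). Mapping a compound searches, over its
conformers, all type-compatible injective assignments of cloud features to
hypothesis features, allowing up to `max_omitted` omissions (default 1 —
training sets routinely contain a least-active compound that lacks one
feature). Each assignment is scored after a least-squares rigid
superposition (Kabsch, proper rotation; fewer than 3 matched points fall
back to translation-only alignment) by

    fit = Σ_f  w_f · max(0, 1 − (d_f / t_f)²),

where d_f is the residual displacement of matched feature f. Ties break
toward lower superposition RMSD, then lexicographically smallest
correspondence, then lowest conformer index, making mapping fully
deterministic. Estimated activity is IC50 = 10^(b₀ − b₁·fit) in μM, with
(b₀, b₁) fit by least squares of log10 IC50 on fit (slope constrained
non-negative; a non-informative fit collapses to the geometric-mean
constant predictor).

The exhaustive search is exact; the test suite checks it against an
independent brute-force enumeration oracle on hundreds of random
instances. Batched 3×3 SVDs keep it fast enough for annealing loops.

## Three-phase generation

* **Constructive.** Leads are compounds within u² of the activity
  minimum, u = 1.5 being the multiplicative activity-measurement
  uncertainty. Every 3–5-feature subset of a lead's clouds with pairwise
  distances ≥ 2 Å (the minimum inter-feature distance) that maps into
  every other lead with all matched displacements inside tolerance
  (omissions up to `max_omitted` allowed, as everywhere in mapping)
  becomes a candidate; near-duplicates (same type multiset, sorted
  distance matrices agreeing within 0.5 Å) are merged.
* **Subtractive.** Candidates fully present (no omissions, all
  displacements within tolerance) in any inactive compound — activity
  more than 3.5 log units above the minimum — are removed. On realistic
  activity spans (≈ 0.1–30 μM) this phase is a no-op, as intended.
* **Optimization.** Candidates are shortlisted to the top `n_hypotheses`
  (default 10) by a cheap proxy cost (mapping restricted to assignments
  whose pairwise distances are compatible with in-tolerance matches), then each is refined by
  simulated annealing: centroid moves ≤ 0.5 Å, tolerance rescaling by
  [0.8, 1.25], weight steps of ±0.2, with the minimum inter-feature
  distance enforced and (b₀, b₁) refit at every evaluation. Full
  correspondence re-search happens every `remap_every` (10) steps with
  correspondences frozen in between — perturbations this small rarely
  change the optimal assignment, and the best fully-evaluated state is
  what is kept. The schedule is geometric (start 1.0, cooling 0.9, 40
  steps); at zero temperature only downhill moves are accepted. All
  randomness flows from one engine seed.

## Cost model (bits)

Following the description-length style of HypoGen cost analysis, with
σ = log10(u) as the error-code width:

    error_cost   = Σ_i [ Δ_i² / (2σ² ln 2) + log2(σ√(2π)) ],
                   Δ_i = log10(est_i) − log10(exp_i)
    weight_cost  = Σ_f (w_f − 2)² / (2σ_w² ln 2),   σ_w = 0.5
    config_cost  = log2(#candidates after the subtractive phase), capped at 17
    total_cost   = error + weight + config            (exact identity)
    null_cost    = error cost of the geometric-mean constant predictor
    fixed_cost   = config_cost + n·log2(σ√(2π))       (ideal zero-residual model)

The cost difference null − total measures the model's evidence over a
featureless null. The vendor tool's absolute bit values are not
reproducible from published material (its exact coding constants are
proprietary), so the package's costs are meaningful relatively — the
identities, the cap, and the difference arithmetic are what the tests pin
down. The published reference run's cost summary (null 194.608, fixed
63.804, per-model totals) ships as a data fixture for the arithmetic
checks.

## Validation battery

* **Activity scales**: IC50 < 1 μM (++++), 1–8 (+++), 8–18 (++), ≥ 18
  μM (+); half-open bins partitioning (0, ∞).
* **Error value**: signed max/min ratio of estimated vs experimental
  IC50, positive when overestimated; magnitude ≥ 1; exact ties return +1
  (the reference tables print −1 for one tie, presumably reflecting
  sub-print-precision differences, so printed comparisons are by
  magnitude).
* **Regression statistics** are computed on log10 IC50. This choice is
  load-bearing: it reproduces the published training correlation
  r = 0.969 and test-set r² = 0.909 from the printed tables, where
  linear-scale correlation does not (0.91/0.76). The published table
  labels both numbers "r²"; numerically the training value matches
  unsquared log-scale r and the test value matches squared log-scale r,
  so the package always reports r and r² explicitly.
* **Fischer randomization** (Y-scrambling): ⌈100/(100−confidence)⌉ − 1
  full regenerations on seeded non-identity activity permutations (19 at
  95%), same engine configuration; pass = no permuted run undercuts the
  original best total cost. Runs that produce no surviving candidate —
  common for scrambled activities, where the "leads" share no
  arrangement — report an infinite cost.
* **Leave-one-out**: n regenerations each dropping one compound,
  summarized as rmsd_r = √(mean (r_full − r_fold)²).

## Synthetic data

Synthetic compounds are abstract feature clouds, not molecules: the
engine's contracts are geometric, and removing chemistry confounds makes
recovery experiments interpretable. Small SMILES fixtures exercise the
chemistry path separately.

A planted hypothesis (k features, types one-of-each for k = 4, pairwise
distances ≥ 2 Å, tolerance 1.6 Å, weight 2.0) defines ground truth.
Actives carry a Gaussian-jittered copy of planted features (jitter σ
0.3 Å) plus 3–5 random distractor features in a 10 Å box; feature
retention is graded — 40% of actives carry all k features, the rest a
random 2..k−1 subset — mirroring real training sets, whose least-active
members map only part of the pharmacophore; a graded continuum is also
what makes each feature's activity contribution statistically
identifiable at n = 20. Decoys carry distractors only and are re-sampled
if they accidentally contain the full arrangement. True activity is
log10 IC50 = b₀ − b₁·fit + N(0, noise σ), clamped to the configured range
(defaults 0.107–29.2 μM, noise 0.2 log units, b₀ = log10 29.2,
b₁ = (log10 29.2 − log10 0.107)/8 so a perfect 4-feature map reaches the
bottom of the range), where fit is the cloud's actual best-mapping fit
against the planted hypothesis — so the planted model is exactly the
data-generating process and the zero-noise library regresses perfectly.
Clamp events are counted. Defaults: n = 20 compounds, decoy fraction
0.25.

What passing recovery tests do and do not show: they demonstrate that the
engine identifies a geometric feature arrangement from graded
fit-activity data with realistic noise; they do not exercise
conformational flexibility (synthetic clouds are single-conformer),
feature-direction effects, tautomers/stereochemistry, or the vendor
tool's proprietary scoring constants.

## Screening funnel

Properties → Lipinski rule of five (all four rules strict: HBD < 5,
HBA < 10, MW < 500 Da, LogP < 5) → declared ADMET criteria (solubility
level 3–4, BBB level 3, absorption level 0, CYP2D6 non-inhibitor,
non-hepatotoxic) → conformers → mapping → estimated-IC50 cutoff (default
0.1 μM) → ranking by estimated IC50 → one representative per Murcko
scaffold (best member = lowest estimated IC50, ties to the
lexicographically lower id). ADMET values come from a per-compound
profile table; predicting them is explicitly out of scope — the filter
logic, not the predictor, is the tested contribution. Lipinski and ADMET
are applied sequentially and both stage counts are logged; stage-wise
survivor counts are non-increasing and screening output is independent of
library order.

## Problem sizes and determinism

Default experiment sizes keep a full three-phase generation at roughly
2–3 s on one core (n = 20 compounds, single-conformer clouds), chosen so
the recovery study (20 generator seeds), the randomization study (10
batteries × 20 generations each), and the mapping-oracle comparison
(200 random instances) all run comfortably inside a routine CI pass.
Every stochastic component — conformer embedding, annealing, permutation
shuffles, the generator — draws from explicit seeds, and repeated runs
are bit-identical.

## Known limitations

* Feature directions are perceived but unscored; hydrogen-bond geometry
  beyond centroid distance is invisible to the fit.
* Absolute cost values, fit values, and screening counts of the vendor
  tool are not reproducible and are not targets; only structure
  (identities, caps, differences) and statistical behavior are.
* The pH-7.4 ionization rules are deliberately minimal; unusual
  protonation states need pre-processed input.
* Hypotheses with 5 features accept a repeated type; excluded-volume
  spheres and ionizable feature classes are not modeled.
* LOO regenerates with the same engine seed per fold; fold-to-fold
  variation therefore reflects the data, not annealing noise.
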