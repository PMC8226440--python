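# Methods

## Pedigree model

A pedigree is a directed acyclic graph of individuals with at most one
recorded sire and dam each. Individuals with both parents unrecorded are
founders, assumed unrelated and non-inbred; an unrecorded single parent
contributes zero to every recursion (no phantom-parent grouping).
Coancestry is computed by the tabular method in topological order:

    C(x, y) = [C(sire(x), y) + C(dam(x), y)] / 2        (y before x)
    C(x, x) = [1 + C(sire(x), dam(x))] / 2

so the inbreeding coefficient is F(x) = C(sire(x), dam(x)). Equivalent
complete generations (EG) follow the recursion
EG(x) = Σ over known parents of (1 + EG(parent)) / 2, which equals the
sum of (1/2)^n over all known ancestors at generation distance n. The
generation interval is the mean, over all (parent, offspring) links
where the offspring itself has recorded progeny and both birth dates are
known, of the parent's age at that birth; each link is one observation.
The test suite checks the tabular kinship against an independent
path-counting implementation of Wright's rules (sum over common
ancestors and node-disjoint path pairs of (1/2)^(n1+n2+1) (1+F_A)).

## Effective population size

Two realized-pedigree estimators are used throughout:

* NeF from individual increases in inbreeding. Each individual's
  rate is dF = 1 − (1 − F)^(1/(t − 1)) with t its EG; individuals with
  t ≤ 1 carry no increase information and are excluded (not imputed as
  zero). NeF = 1 / (2 · mean dF).
* NeC from pairwise increases in coancestry. For each unordered
  distinct pair, dC = 1 − (1 − C_jk)^(2/(g_j + g_k)); self-pairs are
  excluded. NeC = 1 / (2 · mean dC).

A cohort whose mean rate is exactly zero has no drift signal; its Ne is
reported as an infinity flag, and a cohort with no defined rates as
undefined. CSV exports keep the cell empty and set a flag column rather
than writing a numeric sentinel. Under unstructured random mating the
two estimators agree (NeC/NeF ≈ 1), which the tests verify on simulated
random-union pedigrees (20 breeders, 10 generations, 30 replicates);
a NeC/NeF far from 1 indicates family structuring.

## Mate-selection strategies

A seasonal mating plan assigns each of N_t prospective offspring a
(sire, dam) pair. Under the default harem constraint — motivated by
polygynous breeding systems — each dam is served by a single sire per
season (configurable off for sensitivity analyses). Plans never use
more distinct sires than distinct dams. Participation variants: "zero"
(suffix 0) requires every female to produce at least one offspring,
"one" (suffix 1) requires every female and every male to, "free"
(suffix f) imposes no floor.

Objective families, minimized over feasible plans:

| family | objective |
|--------|-----------|
| F      | Σ over matings of parent coancestry C_jk |
| ΔF (`dF`) | Σ of pairwise increases dC_jk |
| mFm    | Σ m_j C_jk m_k, m = mean kinship with the candidate group |
| ΔmΔFΔm (`dmFdm`) | the increase analogue of mFm |
| C      | Σ over distinct prospective-offspring pairs of C_lm |
| ΔC (`dC`) | Σ of offspring pairwise increases dC_lm |
| mix    | p1 · mean parent term + (1 − p1) · mean offspring term |

Offspring coancestries come from the one-generation extension
C_lm = (C_j1j2 + C_j1k2 + C_k1j2 + C_k1k2)/4, and offspring EG (needed
for ΔC) from EG_l = 1 + (EG_sire + EG_dam)/2. Offspring sums exclude
the diagonal (pairs l ≠ m); self-coancestry terms are available behind a
flag for sensitivity work. In the mix family the two components are
per-term means rather than raw sums: the parent sum has N_t terms while
the offspring sum has N_t(N_t−1)/2, so raw sums would let the component
sizes, not the printed weights p1 ∈ {0.01, 0.05, 0.50, 0.95}, set the
balance. (Raw-sum mixing can be recovered by scaling p1.) The 23
named strategies are F0, F1, Ff, ΔF0, ΔF1, mFm0, mFm1, ΔmΔFΔm0,
ΔmΔFΔm1, C0, C1, Cf, ΔC0, ΔC1, ΔCf and the eight mix/mixf weightings
(mix uses the all-females floor, mixf is floor-free).

## Optimization

Search state: an offspring count per dam plus one sire per used dam
(the harem representation makes the one-sire rule structural). Below a
configurable search-space estimate (default 5,000 plans) the optimizer
enumerates every feasible plan exactly, breaking ties by the
lexicographically smallest pair encoding. Above it, seeded simulated
annealing: a greedy initial plan (floors satisfied, sires chosen to
minimize per-mating cost), Metropolis sampling with geometric cooling
over three move kinds (resample a dam's sire; move one offspring slot
between dams, optionally resampling the affected dams' sires; swap or
jointly reassign two dams' sires), tracking the best state seen, then a
first-improvement hill climb from that best state. On small instances
(candidate males × females ≤ 42) the hill climb uses the full joint
neighbourhood so that the annealer reproduces exhaustive minima; at
reference-population scale a cheaper neighbourhood keeps each
optimization near 10 ms. Defaults are 8,000 proposals and 6 restarts;
the generational simulator uses 3,000 proposals and 2 restarts, which
testing showed leaves strategy rankings unchanged while keeping a
23-strategy experiment around a minute. The annealing kernel is
numba-compiled; the exhaustive path evaluates plans through the same
compiled objective so the two routes are float-identical.

## Generational simulator

Discrete, non-overlapping generations: the current cohort is the entire
parent pool, every planned mating yields exactly one offspring, and the
offspring replace the parents. Cohort size is Poisson with mean equal
to the reference-population size, clamped up to the smallest feasible
size when a participation floor binds (clamping is logged; rejection
sampling would bias the mean more and can stall). Offspring sexes are
independent Bernoulli draws with the base population's male fraction,
redrawn wholesale while a cohort lacks either sex; inside the simulator
the redraw also enforces males ≤ females, since a cohort with surplus
males contradicts the polygyny assumption and would make the
every-male-breeds variants structurally infeasible (redraws are
counted). Kinship, inbreeding and EG of each newborn cohort are carried
forward by the one-generation recursions, which — because simulated
parents are always fully recorded — equal recomputation from the full
cumulative pedigree (asserted in the tests). Per generation, NeF and
NeC are computed on the newborn cohort from these cumulative
quantities, so real-pedigree depth differences in the base population
propagate into the simulation.

Experiments run R replicates per strategy with per-(strategy,
replicate) generators spawned deterministically from a master seed; the
whole experiment is a pure function of its inputs and that seed. A
replicate whose constraints become unsatisfiable (e.g. all candidates
of one sex after an extreme draw) is aborted and flagged, never
silently dropped. The defaults are 100 replicates of 20 generations;
the test suite and the acceptance script run 30 replicates of 10
generations on both scenario profiles, sizes chosen so the mean
per-generation Ne ranks they compare are stable across master seeds.

## Synthetic reference scenarios

Two presets mirror the structure of the real reference populations the
toolkit targets: `almeria-like` (6 males, 16 females, mean F ≈ 0.26,
EG ≈ 8.8) and `lajita-like` (8 males, 11 females, mean F ≈ 0.37,
EG ≈ 9.0). The generator simulates a closed population under random
mating: pedigree depth is the number of generations (a complete
pedigree of depth g has EG exactly g, so g = round(target EG)), and the
inbreeding level is set by the breeder count N, seeded from the closed
form N = 1/(2 dF) with dF = 1 − (1 − F_target)^(1/(g−1)) and then
calibrated by pilot runs that share the final run's derived seed, so
the returned cohort realizes the pilot's measured mean F (within 0.05
of target, else an error). The final cohort has the exact requested
sex counts. The generator reproduces the statistical structure these
analyses consume — depth, inbreeding level, sex counts — but not
demographic realism: no age structure, mortality, twinning or seasonal
effects, and interior generations have balanced deterministic sexes.
Passing tests therefore demonstrate the machinery on realistically
structured inputs, not fidelity to any particular real herd.

## Numerical and design notes

* Undefined quantities (dF at t ≤ 1, dC at g_j + g_k = 0, Ne without
  defined rates) are NaN-propagated and surfaced as flags, never
  silently zeroed.
* The tie-break for exhaustive optimization (lexicographic pair
  encoding) plus seeded annealing makes every optimizer output
  reproducible.
* "Between two birth years" cohort windows are inclusive on both ends.
* Delimiters are sniffed among tab/comma/semicolon; unknown-parent
  codes default to {"", "0", "UNK"}; column roles can be remapped.
* The structure panel reports the cohort's female/male ratio as
  n_females/n_males computed from the cohort itself.

## Known limitations

* Overlapping generations, age structure and mortality are out of
  scope; so are marker-based relatedness and selection on traits.
* The annealer requires the harem constraint; harem-free optimization
  is exhaustive-only and thus limited to small instances.
* Published per-generation Ne tables for the 20-generation experiments
  are not reproducible number-for-number (the original optimizer is
  unpublished); the toolkit's contract is the rank structure of
  strategies, which its tests check across independent master seeds.
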