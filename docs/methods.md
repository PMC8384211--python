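# Methods

## The model

A T=1 icosahedral capsid contains 60 copies of one coat protein (CP).
X-ray work on small satellite plant viruses shows ordered RNA density at
the particle two-fold axes: an RNA stem-loop (a packaging signal, PS) can
contact the capsid interior in one of two orientations flanking each
two-fold axis, and the two orientations clash sterically.  We therefore
model the capsid interior as 60 RNA binding sites that fall into 30
mutually exclusive pairs, of which a packaged RNA occupies exactly one
member per pair.

The sites are built as the orbit of a generic point under the proper
icosahedral rotation group (order 60, generated here from a five-fold and
an adjacent three-fold rotation of the icosahedron with vertices at the
cyclic permutations of (0, ±1, ±φ)).  Because the action is free and
transitive, every site has an unambiguous nearest five-fold, three-fold,
second three-fold and two-fold axis, and nine "moves" connect a site to
its symmetry-related neighbours:

| move | rotation | axis |
|------|----------|------|
| 1 | 180° | nearest two-fold |
| 2 / 5 | ±120° | nearest three-fold |
| 6 / 7 | ±120° | second-nearest three-fold |
| 3 / 4 | ±72° | nearest five-fold |
| 8 / 9 | ±144° | nearest five-fold |

A *move set* is an inverse-closed subset of these moves; it encodes the
local assembly rules: which transitions the RNA may make between
consecutive PS contacts.  The chirality convention (which sense of
rotation carries which label, and which flanking three-fold is "nearest")
is not derivable from first principles; it was calibrated once against
the known path census (64 paths for moves {2,3,4,5}, 826 for {3,4,6,7})
and frozen in `FrameConfig`.  The mirror convention is equivalent.

The mutual-exclusion partner of a site is the composite "move 4 then
move 2" (equal to "move 5 then move 3"), a fixed-point-free involution
with 30 orbits.  CP–CP contacts correspond to the edges of moves
{1, 3, 4}; they form the 3-regular, 90-edge truncated-icosahedron graph
(move-1 edges are a perfect matching whose removal leaves the 12
five-fold pentagons).

## Path census

An RNA with 30 PSs packaged under a move set traces a *pseudo-Hamiltonian
path*: 30 distinct sites joined by moves of the set, visiting exactly one
member of every exclusion pair.  The census is computed by exhaustive
depth-first search with pruning (a step onto an occupied site or onto the
partner of an occupied site is cut).  Because the rotation group acts
freely and transitively on sites, each symmetry class of directed paths
has exactly one representative starting at any fixed site; counting
directed move sequences from one start therefore counts paths up to
lattice symmetry.  A path and its reversal are counted as distinct path
types (`counting_convention = "directed-fixed-start"`); this convention
reproduces the published census exactly, including 120086 paths for
{1,2,3,4,5} and 2240200 for {1,3,4,6,7}.  Censuses for move sets of 8–9
moves are combinatorially explosive and are refused without an explicit
node budget.

Since move sequences are symmetry invariants and determine the path up to
symmetry, the canonical label of a path is simply its dot-joined move
sequence.

## Stochastic assembly

Co-assembly of `n_rna` RNAs with a shared CP pool is simulated with an
exact Gillespie algorithm over the reactions:

* **binding** — a CP binds a free PS with propensity
  `k_bind · cp_activity · free_cp / cp_total` and unbinds at
  `k_bind · exp(ΔG_ps/RT)`, satisfying detailed balance against the PS
  binding free energy at CP activity `cp_activity` (default 1e-5 ≈ 10 µM
  on a 1 M standard state — the regime in which the −12…−4 kcal/mol
  affinity range maps onto occupancies spanning ~1 % to ~100 %);
* **nucleation** — two CPs on sequence-adjacent PSs form the first CP–CP
  bond, placing the pair at lattice positions related by a *contact move*
  (1, 3 or 4; the incoming protein must bind a protein).  One quantum of
  `k_nucleate` per co-bound adjacent pair, split over the eligible
  contact-move placements; the first position is fixed at a canonical
  site, valid by symmetry.  Move sets without contact moves can never
  nucleate and yield exactly zero capsids, whatever the PS profile —
  the model's structural zeros;
* **elongation** — the CP-bound PS immediately 5′ or 3′ of the in-shell
  interval attaches at any move image of the interval end whose site and
  exclusion partner are free (the RNA tether holds the complex; contact
  support is energetic, not an eligibility gate).  One quantum of
  `k_attach` per growable end, split over targets with
  Brønsted–Evans–Polanyi weights `exp(−φ·E_contact/RT)`, where
  `E_contact` is the CP–CP contact energy the placement would form —
  contact-rich sites capture the incoming complex preferentially;
* **reverse steps** — a terminal in-shell CP:PS detaches at
  `k_attach · exp(E_contact/RT)`; a two-CP nucleus dissolves as a single
  event.  An unsupported placement (no contacts) therefore evaporates at
  the full `k_attach` rate and persists only once buttressed by later
  neighbours.

Contact energies are interface-resolved: `ΔG_cs = −4.0` kcal/mol for the
pentamer (five-fold, move-3/4) interface and `ΔG_cs_two = −2.0` kcal/mol
for the dimer interface across the two-fold axis, which in this virus is
attenuated by the RNA helix occupying the two-fold region.  The
asymmetry matters: with equal interface energies the early growth tree
contains exactly tied branch choices whose wrong member buries itself
tens of CPs deep, and no PS profile assembles more than roughly half of
its RNAs.  With the asymmetry, the maximum-support growth path from
either nucleation chirality closes the first five-fold ring and then
runs essentially deterministically to completion — the two dominant path
types differ only in the clockwise/anticlockwise start around the
nucleation five-fold.

Rate-scale choices (`k_bind = 100`, `k_attach = 0.1`,
`k_nucleate = 1e-3`, time in arbitrary units): only ratios matter, and
the hierarchy *PS binding turnover ≫ shell attachment ≫ nucleation ≫
supported detachment* encodes three physical assumptions — hairpin
binding pre-equilibrates relative to shell incorporation; forming the
first CP–CP bond with no pre-organised shell edge is much slower than
adding to one (standard nucleation–elongation asymmetry); and assembled
interfaces are long-lived.  Two consequences do the mechanistic work:
nucleation probability becomes proportional to *equilibrium*
co-occupancy of a PS pair, so a pair of strong PSs at the RNA terminus
out-competes transiently co-bound weak pairs by an order of magnitude;
and mis-placed single-contact CPs anneal away during the binding waits
of the growth front, while correctly placed CPs are locked by ring
closures (two contacts).

An RNA is complete when all 30 PSs are in-shell — which, by the pruning
rule, covers all 30 exclusion pairs.  Completed capsids are frozen as
stable end states.  The run stops at `t_max` or when no nucleation,
elongation or detachment has occurred for `quiesce_window` time units
(the structural-zero move sets quiesce almost immediately).  Per-event
state updates maintain CP conservation
(`free + PS-bound + in-shell = cp_total`) exactly, and every completed
path is re-validated against the independent path oracle.

The CP pool defaults to 60 CPs per RNA (a full shell each) although only
the 30 path CPs are modelled; the 30 interstitial CPs of the real
particle are outside the model, which is why absolute capsid counts for
contact-rich move sets should be read qualitatively.

## Affinity optimisation

The assembly fitness landscape maps the 30-vector of PS affinities to the
equilibrium yield of a homogeneous ensemble.  `evolve` implements an
elitist genetic algorithm: the fittest quarter survives unchanged,
offspring are round-robin copies with each PS mutated (uniform redraw
within [−12, −4]) with probability 5 %, fitness is re-evaluated every
generation with fresh derived seeds, and the run stops when the top-k
spread falls inside a convergence window.  The full-scale profile (1024
variants, 2000 copies, ≤30 generations) mirrors the published protocol;
`desk` and `mini` profiles scale the population, copies and horizon down
to minutes of runtime.

At reduced scale plain elitist selection is noise-limited: the
per-evaluation yield s.e. (5–7 percentage points at ≤100 copies) exceeds
the ~2–7-point fitness effect of a single deleterious locus, and uniform
redraw mutation continuously re-introduces strong interior PSs (3/8 of
the redraw mass is in the strong band), so small populations plateau
well below the optimum.  Three optional search aids address this, all
off by default so the plain protocol remains available: uniform
crossover between random survivors (`GAConfig.crossover`); a second,
larger evaluation of the screening leaders before survivor selection
(`GAConfig.refine_copies`), which contains the winner's-curse bias of
small-copy estimates; `local_refine`, a coordinate-descent pass over
the 30 loci using common-random-number paired comparisons with an
acceptance margin; and `architecture_scan`, a model-guided grid search
over the architecture family that evolved variants converge toward —
short runs of strong PSs at the RNA termini over a uniform weak
background — scanning site placement, site length, site affinity and
background affinity directly, with any externally supplied genotype
(e.g. the GA best) competing as a candidate.  The test suite's
reduced-scale optimisation run chains a 96-variant random screen, a
12-generation GA with these aids, and the architecture scan, then
evaluates the winner on a 2000-copy ensemble at the default kinetics.
The scan consistently selects two-PS strong sites at both termini over
a −5 kcal/mol background; the corresponding best single-3′-site
architecture (the published site placement for move set {2,3,4,5}) is
used for the knockout/uniform contrast.

Evolved optima develop the published architecture: a nucleation site of
2–4 strong PSs (≤ −9 kcal/mol) at the RNA terminus and weak-to-medium
interior PSs.  `nucleation_site` reports the longest contiguous
strong-band run; `knockout` (site → −4) and `nucleation_only`
(non-site → −4) construct the standard perturbation variants.

## What the generator emulates — and what it does not

Inputs are fully synthetic: affinity vectors (uniform, random, knockout,
nucleation-only) and move-set specifications.  The simulator captures
PS-mediated, single-nucleus, tether-constrained shell growth with mutual
exclusion.  It does not model: multiple simultaneous nuclei per RNA (a
real kinetic-trap channel), the 30 interstitial CPs, RNA secondary
structure or sequence, competition with host mRNA, or spatial diffusion.
Consequently structural statements (path censuses, structural zeros,
exclusion bookkeeping) are exact, while yields are faithful in ordering
and magnitude class but not digit-for-digit; passing tests demonstrate
the mechanism, not a fitted reproduction of any particular experiment.

## Numerical choices

* Orbit points are identified by coordinates rounded to 1e-6 and ordered
  lexicographically: stable position ids.
* Axis assignment requires a margin of 1e-9 in the angular-distance
  ranking; degenerate frames (reference point on a symmetry axis or
  equidistant between axes) are rejected with instructions to perturb.
* The DFS uses uint64 bitmasks for the occupied/excluded sets; counts are
  exact integers, independent of the start vertex and of move ordering.
* The Gillespie kernel uses a splitmix64 PRNG (seeded from the run seed)
  and binary sum trees over per-RNA propensities; identical seeds give
  bit-identical trajectories.  Propensities are recomputed from scratch
  for the affected RNA after each event, so no drift accumulates.
* Default simulation horizon `t_max = 4e6` (quiescence window 5e5)
  covers the slowest growth mode of interest (weak-interior optima,
  median completion ≈ 7e5); scaled-down test kinetics shorten the
  horizon, trading a few yield points for runtime.

## Known limitations

* Exact capsid counts for productive move sets depend on the rate
  constants above and are reproduced as orderings, not values.
* Interface energies finer than the two-level five-fold/two-fold split
  (e.g. distinct three-fold trimer contributions) are not modelled.
* The GA's desk-scale profiles are search-budget-limited; rugged regions
  of the landscape (mid-sequence strong PSs) decay slowly under redraw
  mutation.
* Censuses for 8- and 9-move sets are out of reach by design; bounded
  partial counts are available with an explicit budget.
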