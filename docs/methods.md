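# Methods

This note documents the models, algorithms and design choices behind
`casepy`, in the order data flows through the package.

## Molecular model

Molecules are simple undirected heavy-atom graphs: each atom carries an
element symbol and an explicit attached-hydrogen count, each bond an integer
order 1–3.  Aromaticity is never stored — rings are kekulized — so the
structure generator, which assigns explicit bond orders, and the environment
encoder operate on one representation.  Formal charges, isotopes, radicals
and stereochemistry are out of scope and rejected at the conversion
boundary.  Multi-valence elements (S, P) default to their lowest standard
valence (2 and 3); a problem may widen this per atom, but nothing in the
bundled workflows does.

Canonical signatures are RDKit canonical SMILES of the kekulized graph.
Two graphs share a signature exactly when they are isomorphic at the
heavy-atom + hydrogen-count + bond-order level.  A consequence worth
knowing: the two Kekulé patterns of an *unsymmetrically* substituted
aromatic ring are distinct bond-order graphs and therefore count as distinct
generator solutions; collapsing them would require an aromaticity model
inside the generator, which we deliberately avoid.

## Spherical environment (HOSE) codes

The shift-prediction key for a carbon is a canonical string describing its
bonded environment out to *s* spheres (1 ≤ s ≤ 6).  At each node the
outgoing branches are ordered by their own recursively computed canonical
sub-strings, so the code is a pure function of graph structure: automorphic
atoms always receive identical codes and the encoding is invariant under
atom re-indexing.  Branch exploration excludes only the immediate parent
atom, so in rings the walk keeps unfolding with depth — deeper codes are
strictly more specific lookup keys, which is the property the sphere-fallback
predictor relies on.  Bonds of perceived aromatic rings are encoded with a
dedicated `*` symbol (perception runs on a copy; stored orders are
untouched); without this the two Kekulé forms of a symmetric ring would
split chemically equivalent atoms, e.g. the ortho pair of a monosubstituted
benzene, into different codes.  The stereochemical layer used by
stereo-enhanced variants of such codes is an extension point, not
implemented; diastereotopic carbons therefore share codes.

## Knowledge base

A record couples a molecule with per-carbon shifts.  Entries equal in both
shift and multiplicity merge into one signal whose equivalence index is the
number of merged carbons; equivalence indices of a spectrum always sum to
the carbon count.  Grouping uses exact equality of the stored values — no
epsilon — because assigned reference records carry identical values for
symmetry-equivalent carbons by construction.

Two derived stores feed the rest of the system:

* **HOSE library** — per sphere 1–6, each code maps to (count, mean, min,
  max) of the contributing shifts.  The mean is the predicted value; count
  and range are kept as per-atom quality metadata.  The mean is clamped into
  [min, max] to keep summation round-off from violating the range invariant.
* **Statistics store** — per (1-ppm shift bin = ⌊δ⌋, multiplicity, element
  set of the parent molecule): hybridization counts, neighbour-element
  presence counts (each neighbouring *element* counted once per carbon, so
  the mandatory/forbidden semantics stay crisp), and observation totals;
  per element set, hetero–hetero and total bond counts.  Queries aggregate
  over all stored keys whose element set is a *subset* of the query
  formula's elements — exact-formula keying would leave almost every key
  empty at realistic KB sizes.

Assigned records round-trip through V2000 SDF with a `CS_13C` data field of
`atomIndex:shift` lines; reading sanitizes without aromaticity perception so
the stored Kekulé orders survive unchanged.

## Dereplication

Signal pairs are valid when |Δδ| ≤ tolerance (default 2 ppm) and, when the
corresponding checks are enabled, multiplicities (default on) and
equivalence indices (default off) agree.  The assignment is greedy
closest-first unique matching; the exhaustive optimal assignment is kept in
the test suite as an oracle.  The spectrum distance is the mean |Δδ| over
matched pairs only.  Hits require all query signals paired (configurable
ratio) and distance ≤ 1 ppm by default; defaults are this package's choice
and every one is a per-run parameter.  Ties at equal distance are broken by
descending paired count, then by reference-side coverage (a reference
spectrum fully explained by the query outranks one with leftover signals —
this separates a compound from larger compounds whose spectra embed it),
then by identifier.

## Fragment library

Fragments grow breadth-first from every heavy atom, spheres 1–3 by default
(three spheres already reproduce ring-plus-anchor fragments while keeping
libraries small).  Two preservation rules keep load-bearing connectivity:
carbon–hetero bonds are never cut, and a start atom inside a ring pulls in
its entire fused ring system (computed as connected components of non-bridge
edges).  The closure runs to a fixed point, duplicates are removed by
(signature, subspectrum) key.  Subspectra become bit strings over 1-ppm bins
spanning [−20, 260) ppm — 280 bits covering the ¹³C range with headroom.
Screening keeps a fragment when all its bits lie in the query bits dilated
by ±1 bin by default; strict inclusion is available, but experimental
vs. library jitter would defeat it in practice.  Ranking: heavy-atom count
descending, then the dereplication matcher's average deviation, then parent
identifier.

## Constraint detection

For a query signal (δ, multiplicity) under a formula, hybridization states
with occurrence fraction < 1 % are discarded; neighbour elements (drawn from
the formula's heavy elements; hydrogen is encoded by the multiplicity) are
forbidden below 1 % and mandatory at ≥ 95 %; hetero–hetero bonds are allowed
when ≥ 1 % of all bonds in composition-compatible records connect two
heteroatoms.  Raising the discard threshold can only shrink the kept sets —
there is deliberately no "keep at least one" fallback, because it would
break that monotonicity; the all-states fallback applies only when the
statistics store has *no* data at the key (with a warning).  Ambiguous
multiplicities skip detection entirely rather than guess a key.

## Structure generation

The connectivity problem ("MCD") holds one entry per heavy atom of the
formula: carbons from the correlation table (attached-H pinned by
edited-HSQC sign: negative ⇒ 2, positive ⇒ {1, 3} until the user resolves
it — the search branches over unresolved sets), signal-less heteroatoms as
placeholders, explicit hetero-proton attachments (e.g. a hydroxyl proton)
as hydrogen bookkeeping on a placeholder.  Each HMBC correlation from a
proton on atom *a* to carbon *c* becomes a heavy-atom distance constraint
d(a, c) ∈ {1, 2} (the standard 2–3-bond reading; configurable per run), each
COSY pair a vicinal constraint d = 1, which doubles as a forced bond.

The search backtracks over bond orders 0–3 for atom pairs in row-major
order on an internally re-ordered atom list: atoms are accreted greedily
along the proximity-constraint graph so that both endpoints of a constraint
close early.  When the last pair of an atom's row is placed, its
neighbourhood is final, enabling exact checks of remaining valence,
final hybridization (sp³/sp²/sp from the double/triple pattern), mandatory
neighbours, and — since distances 1 and 2 depend only on the two
neighbourhoods — of every {1,2}-type proximity constraint.  Additional
prunes: per-pair remaining-valence feasibility, partial multiple-bond
pattern feasibility against the hybridization candidate set, and component
closure (a finished connected component that cannot reach the rest of the
atoms kills the branch).  Good- and bad-list fragments are enforced by
substructure monomorphism (elements and bond orders everywhere,
attached-hydrogen equality at valence-complete fragment atoms) at emission
time; orderly-generation seeding of fragment bonds is a possible
optimization, not needed for correctness.  Solutions are deduplicated by
canonical signature; enumeration is depth-first and deterministic, so the
truncation cap (500, aligned with the ranking cap) is reproducible.
`verify_solution` re-checks every constraint by direct predicate evaluation
(networkx distances, monomorphism) independently of the search, and a
brute-force enumerate-and-filter oracle in the test suite confirms
exhaustiveness and soundness for every formula with ≤ 5 heavy atoms over
{C, N, O} and randomized constraint sets.

Scale: fully correlated problems (every protonated carbon with 2-bond HMBC
coverage) solve in milliseconds at 11 heavy atoms and in minutes at 17 with
sparse statistics; worst-case behaviour is exponential, as for any
exhaustive generator, and the cap plus the truncation flag are the
intended control.

## Prediction and ranking

Each candidate carbon is encoded at sphere 6 and looked up; on a miss the
sphere is lowered until a library entry exists, recording the sphere used,
the entry count and the shift range.  Sphere 0 means unpredicted; such
carbons are excluded from matching and surface through the matched/total
coverage counts — no penalty term is applied, which is a documented
limitation (a candidate with many unknown environments can look better than
it should; coverage is therefore a ranking tie-break).  The library
statistic used as the prediction is the arithmetic mean of the entry
shifts.  Ranking is ascending average deviation, descending coverage, then
canonical signature, truncated to 500 by default.

## Synthetic fixture knowledge base

`make_fixture_kb` emulates an assigned reference collection: ~270 enumerated
small molecules over {C, H, N, O, S} (substituted benzenes with twelve
substituent types in mono/ortho/para patterns, plus chains, carbonyls,
alkenes/alkynes/nitriles and five-/six-membered heterocycles).  Each carbon
gets a deterministic pseudo-shift: a chemically typical window selected from
its hybridization and hetero neighbourhood (e.g. sp³ C–O 50–90 ppm, ester/
amide carbonyl 160–178 ppm, plain sp² 100–145 ppm), positioned inside the
window by an MD5 hash of its sphere-3 environment code.  Equal environments
therefore get equal shifts, so symmetry-equivalent carbons merge into
equivalence-indexed signals exactly as in curated data.  Records whose full
spectrum embeds within 0.8 ppm (multiplicity and equivalence respected) in
another record's spectrum are excluded — a spectrum-only matcher cannot
retrieve such a record uniquely, and the KB is meant to be an identifiable
testbed; this drops a handful of one-signal molecules.  The same seed
reproduces the KB byte for byte.

What the fixture does **not** emulate: real shift dispersion within an
environment class (every environment is a point value, so closed-world
prediction is exact by construction), solvent and temperature effects,
crowded spectral regions with overlap ambiguity, measurement noise beyond
the optional uniform/Gaussian jitter helpers, and the long-tail diversity of
natural-product scaffolds.  Passing tests therefore demonstrate the
correctness of the machinery — matching, counting, enumeration, fallback —
not the accuracy of shift prediction on real spectra, which is bounded by
the knowledge base a user supplies.

## Numerical and procedural choices

* Statistics bin width 1 ppm: matches displayed shift precision; finer bins
  starve the counts, coarser ones blur functional classes.
* Bit axis [−20, 260) at 1 ppm: covers reported ¹³C shifts with headroom;
  out-of-range shifts are an error, not a clamp.
* Greedy matching instead of optimal assignment: deterministic, linear-time
  after sorting, and equal to the optimum whenever the valid assignment is
  unique (asserted against the exhaustive oracle in tests).
* Library/stats serialization is versioned, key-sorted JSON, so builds are
  byte-reproducible and diffable.
* Degenerate inputs: empty KB dereplication warns and returns no hits;
  an infeasible generation problem returns an empty (not error) result;
  unpredicted carbons are values, not errors.

## Known limitations

* ¹³C only; the record model carries a nucleus field, but matching,
  statistics and prediction do not combine nuclei.
* No stereochemistry anywhere: generation emits constitutional isomers,
  prediction cannot separate diastereotopic carbons.
* Kekulé-level solution identity (see above) inflates counts for
  unsymmetric aromatic rings.
* The exhaustive generator is exponential in the worst case; very
  proton-poor molecules need good-list fragments or user constraints to
  stay tractable, which mirrors how such systems are used in practice.
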