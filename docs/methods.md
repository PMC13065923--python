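# Methods

## Scaffold model

A scaffold here is interaction-anchored: the 2D substructure of a 3D
docked conformation whose atoms realize every *key* point of a
pharmacophore hypothesis. This is deliberately stricter than Bemis–Murcko
framework analysis, which is retained only as a baseline in the diversity
reports. The definition entails three gates on a candidate fragment — at
least one attachment point (so it can seed enumeration), at least one
ring, and coverage of the key-point atoms — and a minimality principle:
the smallest such fragment is the scaffold.

"Smallest" counts heavy atoms excluding attachment points; ties are broken
by lexicographically smallest canonical SMILES so extraction is a pure
function of the pose. Counting attachment points instead is exposed as a
configuration choice, not the default.

## Partial BRICS decomposition

Leaf-level BRICS decomposition loses the intermediate fragments a chemist
would recognise as retrosynthetic way-points. We therefore enumerate every
connected product of cleaving any subset of at most `max_cuts`
BRICS-cleavable bonds (default 6). Fragments are deduplicated by their
parent-atom set; the 0-cut intermediate is the molecule itself, which can
never become a scaffold (0 ports). The subset cap bounds the enumeration
at Σ_{k≤6} C(b, k) cut sets for b cleavable bonds, which is inexpensive at
drug-like sizes; molecules with no cleavable bond yield only the flagged
0-port parent.

The test suite checks this enumeration against an independent brute-force
oracle that deletes bond subsets on a plain adjacency list and takes
connected components — no shared fragment machinery.

## Key-point coverage for a 2D fragment of a 3D pose

A 2D fragment cannot be re-embedded and re-matched without introducing a
conformer-generation dependency, so "matching all key pharmacophore
points" is interpreted as atom coverage: the fragment, viewed in the
parent pose's coordinates, must contain the atoms of the best-matching
feature of every key point. This is the only reading that is well-defined
without re-embedding, and it makes extraction exactly checkable by the
oracle above.

## Feature perception and matching

Perception uses a small editable SMARTS catalogue: HBD = N/O bearing a
hydrogen (one feature per atom); HBA = any O, or N that is not an amide N,
aromatic N–H, or cation; HYD = hydrophobic atoms (sp3/sp2 carbon not
double-bonded to a heteroatom, aromatic carbon, thioether S, halogens)
grouped into ring units and acyclic chain units; AROM = fully aromatic
rings; POS/NEG = formally charged atoms. Hydrophobes are grouped per ring
and per chain rather than as whole connected components — a single merged
component would span scaffold and peripheral atoms through ring–chain
junctions and make the key-atom set cover the whole molecule.

Matching is centroid-based and boundary-inclusive (distance ≤ radius); an
any-atom mode is available as a flag. The best feature for a point is the
nearest one, ties broken by lowest atom index. Matching is invariant under
joint rigid motion of pose and hypothesis, and enlarging a radius can only
add matches; both properties are asserted in the suite. Tolerance radii
are mandatory user input — no default radius is claimed to reproduce any
particular screening platform's behaviour.

## Ports, sides, and joining

Attachment points are dummy atoms whose isotope label carries port
identity: 1 = hydrophobic-side vector, 2 = polar-side vector, 3 =
auxiliary. A severed peripheral piece is classified *left* if its centroid
(parent coordinates) is strictly nearer the nearest key HYD point than the
nearest key HBD/HBA point, otherwise *right* (equidistant → right, a
deterministic tie-break). The port that lost a left fragment is labeled 1,
a right fragment 2; on a trivalent scaffold the remaining port takes the
unused label in deterministic bond order. Enumeration then always fuses
left fragments at port 1 and right at port 2, preserving the
hydrophobic/polar orientation end to end. Unlabeled input ports are
assigned labels by canonical atom order so port identity survives
round-trips through bare-`*` files.

Joining forms a single bond between the two port-neighbour atoms and
removes the dummies. Chemically impossible junctions in an enumeration are
skipped and counted, never fatal: combinatorial sets inevitably contain
incompatible pairs and the skip counter keeps the attrition auditable.

## Neutralization

`Atom.SetFormalCharge(0)` semantics, applied before deduplication: charges
removable by hydrogen-count adjustment without valence violation
(ammonium N–H, carboxylate O⁻, …) are zeroed; atoms where this is
impossible (quaternary N, charge-separated ylides) are left charged and
flagged rather than mangled.

## Trivalent expansion

2D generative engines practically handle at most two attachment points, so
trivalent crude scaffolds are expanded: every port on an aromatic carbon
is replaced, one at a time, by each capping fragment, and results are
canonical-deduplicated (a `--single-port` flag restricts to the first
aromatic port for the stricter reading). The shipped capping set —
hydrogen (port deletion), methyl, fluoro, chloro, methoxy, cyano,
trifluoromethyl — is typical aromatic-substituent configuration in an
editable file, not a claimed constant. Scaffolds with no aromatic-carbon
port are not expandable and drop out of the final set.

## Implicit spaces: counting, streaming, sampling

The space size is Σ over scaffolds of (left factor × right factor), with a
factor of 1 for an absent port and min(k, set size) under sampling —
always Python integers, so the 10¹¹-scale counts cannot overflow.
Streaming enumeration is lexicographic over (scaffold, left, right) with
constant memory; sampling draws per-scaffold without-replacement subsets
from a generator seeded by (seed, scaffold index), which makes reruns
byte-identical and scaffolds independently parallelizable. Products are
not globally deduplicated during streaming (that would break the memory
contract); a post-pass dedup helper is provided.

## Structural alerts and descriptors

Three alert tiers (minimal/moderate/covalent) ship as tab-separated
`rule_id / SMARTS / description` files assembled from public
structural-alert collections; the file format is the stable contract, the
contents are configuration. `minimal ⊆ moderate` is enforced at load time
so failing the minimal tier implies failing the moderate one. The covalent
tier is a distinct list applied like the others, with an `--invert` flag
for workflows that *select* warheads instead of removing them. Descriptor
annotation covers MW/HBD/HBA — donors and acceptors counted with the same
SMARTS the pharmacophore module perceives features with, so 2D annotation
and 3D matching cannot disagree — and is extensible through a plug-in
hook. Proprietary synthesizability and medicinal-chemistry scores are
intentionally not reimplemented.

## Reward shaping

CRV returns exactly the constant *c* for every filter-passing structure
(reward variance over any accepted batch is identically zero). SPAG
computes `max(0, base − w·s_max)` where `s_max` is the maximum Tanimoto
similarity (hashed circular fingerprints, radius 2, 2048 bits — standard
practice) of the candidate to the archive of previously accepted
structures, then inserts the candidate. The linear clamped form is a
design choice — the intent (penalize similarity to prior generations) is
fixed, the functional form is pluggable. SPAG applies to the CRV-capped
value (CRV first, then SPAG); applying it to the raw score instead is a
one-line change in `make_reward_fn`.

The toy generator exists to demonstrate direction, not magnitude: it
mutates parents chosen by reward tournament (size 4), so a raw
similarity-to-target scorer exploits its best cluster while CRV
degenerates selection to uniform and SPAG additionally suppresses
re-visits. Over ten paired seeded runs the CRV+SPAG mean unique
primary-scaffold count exceeds the default-reward mean (sign test,
α = 0.05). The published-scale gain of a production generative stack is
treated as directional only — it depends on generator and reward
internals that are out of scope here.

## Hit-rate extrapolation

`hit_rate` reports 100·hits/n with a Wilson 95% interval (Wald intervals
misbehave at small rates; the upstream screening reports point estimates
only, so the interval is an additive contract). Display rounding (1 or
2 d.p.) never touches the stored full-precision values. The Wilson
interval's exact coverage oscillates around the nominal level — the suite
verifies coverage ≥ 95% by exact pmf enumeration at n = 2000 for rates
0.10/0.26/0.59 and checks a seeded 10,000-rep simulation against the exact
value within Monte-Carlo error.

## Synthetic fixture libraries

The generator assembles poses as join(scaffold, left, right) over pools of
6 bivalent single-ring scaffolds bearing donor + acceptor motifs, 8
hydrophobic left fragments and 8 polar right fragments. Coordinates are
constructed geometrically: the scaffold ring is a regular polygon whose
hydrophobic-member centroid sits exactly on the HYD point, the donor and
acceptor atoms sit exactly on the HBD/HBA points, the left fragment is
placed beyond the HYD point and the right fragment beyond the polar
midpoint, and remaining atoms get a relaxed outward neighbor layout.
Gaussian noise of `noise_sd` Å (default 0) is added last.

What this emulates: the geometric relationship between a docked hit's
interaction atoms and a hypothesis, with known composition. What it does
not: physical conformers, docking poses, steric strain, tautomers, or
pocket realism — coordinates are consumed only through distance tests, so
passing tests demonstrate the logic of matching/extraction/enumeration,
not performance on real docking output. Pool members are chosen with no
internal BRICS-cleavable bonds and BRICS-cleavable junctions (aromatic
C–sp3 C), so at zero noise the planted scaffold is, by construction,
almost always the unique minimal qualifying fragment; recovery is asserted
at ≥ 95% against the independent oracle on a 200-pose library.

## Problem sizes and numerical choices

Default problem sizes in the suite and acceptance script — 200-pose
recovery library, 50 randomized enumeration specs (≤ 10×10×10), 10 paired
generation runs of 150 iterations on 8 seed structures — were chosen as
the smallest sets where the stochastic assertions are stable across
seeds. `max_cuts` defaults to 6 as a tractability cap on subset
enumeration. All randomness flows from explicit integer seeds
(`numpy` generators seeded by (seed, index) tuples; `random.Random` for
the toy generator), so every stochastic path is reproducible.

## Known limitations

* Scaffold/port semantics assume at most one left- and one right-classified
  port per scaffold carries meaning; a trivalent scaffold with two
  same-side peripheries falls back to deterministic label order.
* Feature perception is a transparent minimal catalogue, not a replica of
  any commercial perception engine; results shift with the catalogue, which
  is why it is an editable input.
* The enumeration engine does not deduplicate across scaffolds; identical
  products reachable from different scaffolds are counted separately, as
  in the implicit-space arithmetic.
* The shipped alert tiers are public-collection approximations; projects
  should curate their own files for production triage.
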