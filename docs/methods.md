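# Methods

## Model and semantics

The package models gene regulation as a Boolean network: each factor holds
one bit and is updated by a logical rule (`&`, `|`, `¬`) over its
regulators.  The shipped system couples two sub-networks — the DNA-damage
response / cell-cycle-arrest axis and proinflammatory IL-1/IL-6/IL-8
signalling — into one 51-node network, stored as a single BoolNet-format
file (`src/saspnet/data/sasp_model.bn`) that `build_sasp_model()` parses;
the rules are never duplicated in code.  Two nodes, `DNAD` and `Hypoxia`,
carry the identity rule `X = X` and act as external inputs; every state of
such a node is self-sustaining, so a condition is specified by setting the
input bits in an otherwise all-inactive initial state.

Synchronous update applies every rule simultaneously, giving a
deterministic map `F` on the 2^N state space; trajectories are reported
1-indexed with **t = 1 the un-updated initial state**.  This convention is
forced by the model's printed time courses: from the all-inactive state the
rules yield CDK4 at t = 2, pRB at t = 3, E2F at t = 4 and CDK2 at t = 5,
which is exactly the published ordering only under t = 1-as-initial
indexing.  Asynchronous update fires one node at a time; the package treats
it by seeded uniform-random walks plus the identity (tested, not assumed)
that point attractors are scheme-independent.

Two printed time points in the source material's damage figure (NEMO at
t = 3, interleukins at t = 7) are inconsistent with the printed rules under
any single indexing convention (`NEMO = DNAD` forces t = 2; the IL rules
fire at t = 5).  The package reports what the rules give and does not treat
those two values as reference points.

### Model-encoding decisions

* The published rule table lists a factor "MPK1" (rule `AP1`) while the JNK
  and p38 rules reference "MKP1".  Since only one rule exists for either
  spelling and the merged node is the AP1-induced MAPK phosphatase, both
  spellings denote one node, canonicalised to `MKP1`; the reader accepts
  the alternative spelling via an alias map.  The model therefore has 51
  nodes.
* `Oncogene` is encoded as the cytokine feedback `IL8 | IL6`, exactly as
  the rule table defines it, even though prose elsewhere calls "activated
  oncogenes" an external signal; the declared inputs are exactly `DNAD`
  and `Hypoxia`.
* Node names are ASCII-safe (`NFkB`, `IkB`, `p16INK4`, `CEBPbeta`,
  `MEK1_2`, `ERK1_2`); a display-name map carries the Greek/superscript
  forms for presentation.
* The hypoxia condition ships with no published time course; it is covered
  by invariant tests only (HIF1 = Hypoxia & ¬p53, arrest via p21).

## Attractor enumeration

`exhaustive_attractors` is exact under all strategies.

* **direct** (N ≤ 20): the successor of every state is computed with
  vectorised rule evaluation; cycles of the functional graph are found by
  iterated in-degree-zero peeling, and basin sizes by pointer-doubling
  label propagation.  Basins always sum to 2^N.
* **reduction**: branch over all assignments of the declared inputs (their
  self-loops make each assignment invariant), then iteratively substitute
  nodes whose rules simplify to constants — such nodes hold their constant
  in every attractor, so elimination is exact.  The residual wiring is
  condensed into strongly connected components, processed in topological
  order: each component is enumerated over its own state space, driven by
  the periodic trace of the already-solved upstream components (product
  space `2^b × period`), which composes cycles exactly.
* **branch-and-reduce**: if a residual component exceeds the component cap
  (default 2^20 states), the enumerator picks a node whose rule is
  *absorbing* in itself — once active it stays active (e.g.
  `IkB = NFkB | IkB` after NEMO is off, `IRAK = IL1R | MyD88 | IRAK`), or
  dually once inactive it stays inactive.  Such a node is constant on every
  synchronous cycle, so fixing it to 0 and to 1 partitions the attractor
  set exactly.  The absorbing value is self-consistent; the opposite value
  adds the constraint that the node's rule keeps evaluating to it, which is
  checked on every state of every enumerated cycle (and branches whose
  constraint simplifies to a contradiction are pruned).  Every cycle the
  reduction path reports is additionally verified step-by-step against the
  original rules.

This strategy enumerates the 51-node model in well under a second: fixing
`DNAD = 1` propagates to a single fixed point per hypoxia value, and the
`DNAD = 0` branches collapse, after one `IkB`/`IRAK` branching level, to
components of at most ~19 nodes.  A component that stayed oversized with no
absorbing node available raises `ResourceCapExceeded` naming the component
size rather than returning a partial answer.

The published attractor comparison ("87 to 19") refers to the integrated
network as a single object, so the count is taken over the full 2^N state
space with both inputs free; the package reproduces the 19.  The "87" of
the two standalone sub-network files is not reproduced — those files are
supplementary material not reprinted with the rule table — but the same
enumeration machinery accepts any BoolNet file.

## Perturbations and the screen

A perturbation clamps one node's rule to a constant (knockout 0,
overexpression 1); the perturbed node is forced to its clamped bit already
at t = 1, since a constitutive intervention is present from the start of a
time course.  The screen enumerates all single perturbations except the
readouts themselves and the declared inputs (input values belong to the
condition, not to an intervention): `2 · (N − |readouts| − |inputs|) = 94`
candidates for the shipped model.  A perturbation "silences" the readouts
only if every readout is 0 in **every** phase of the reached attractor —
preventing activation is an always-off claim.  Double perturbations are
supported by composition but not screened by default (quadratic growth in
candidates).

Under DNA damage the screen returns exactly `NEMO=0`, `IKK=0`, `NFkB=0`
and `IkB=1`.  An ATM knockout does *not* silence the cytokines in this
model: the rule table wires NEMO to DNA damage directly rather than
through ATM, so ATM=0 leaves NF-κB signalling intact.  This is reported as
a property of the shipped rules, not adjusted to match external knockout
literature.

## Synthetic networks

The generator draws classic N-K random Boolean networks: each non-input
node receives exactly K distinct regulators chosen uniformly and a truth
table whose rows are 1 with probability p; rules are realised in
sum-of-products form so generated networks round-trip through the same
parser and file format as the biological model.  An all-zero table becomes
a contradiction (and an all-one table a tautology) that still references
all K regulators, keeping the declared in-degree exact.  The test corpus —
200 networks, N = 5..12, K ≤ 3, p ∈ {0.2, 0.5, 0.8}, 0–2 input nodes,
fixed seeds — is enumerated by an intentionally simple interpreted
brute-force oracle against which the vectorised and reduction strategies
are compared, including basin sizes.  These fixtures exercise engine
correctness; they do not emulate biological wiring (no canalisation,
scale-free topology or curated logic), so passing them validates the
algorithms, not the biology of any particular model.

## Numerical/engineering choices

* States are packed into integers (node i at bit i); the synchronous step
  is compiled to a bit-operation expression per network for scalar use and
  evaluated over numpy arrays for whole-state-space work.
* Attractor cycles are canonicalised to start at their lexicographically
  smallest state (bit-vector order over declaration order), making equality
  phase-invariant; reports list attractors in that order.
* All randomness (asynchronous walks, network generation) flows from
  explicit integer seeds through `numpy.random.default_rng`; repeated runs
  are bit-identical.
* The CLI and `run_pipeline` write CSVs whose column order always equals
  node declaration order; a run log records config, seed and version.

## Limitations

* Exhaustive *asynchronous* attractor analysis (complex/loose attractors)
  is out of scope; asynchronous behaviour is explored by sampling only.
* Basin sizes are computed by full-state-space sweep and therefore only for
  networks within the direct cap (N ≤ 20).
* The model is Boolean: no graded damage levels, no kinetics, no
  probabilistic rule choice; multi-valued and ODE semantics are non-goals.
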