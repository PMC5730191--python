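# saspnet

Boolean network modelling of DNA-damage-induced senescence and the
senescence-associated secretory phenotype (SASP).

Senescent cells arrest their cycle after severe DNA damage and, over time,
start secreting proinflammatory factors — IL-6 and IL-8 chief among them —
that inflame tissue and push neighbouring cells into senescence.  `saspnet`
implements a logical (Boolean) model of the regulatory network behind this
switch: a 51-factor network coupling the DNA-damage response
(ATM/ATR → CHK1/CHK2 → p53/p21 and p16^INK4A → CDK4/CDK2 arrest) to
NF-κB-driven cytokine signalling (IL-1, IL-6, IL-8 and their receptor
cascades), driven by two self-looped external inputs, `DNAD` (DNA damage)
and `Hypoxia`.  It is aimed at systems biologists who want to simulate the
model, enumerate its attractors, and screen in-silico knockouts or
overexpressions that keep the SASP mediators off.

## The model

Each regulatory factor `xᵢ ∈ {0, 1}` is updated by a logical rule over its
regulators, e.g.

```
p53  = (CHK2 | CHK1 | ATM) & ¬MDM2
NFkB = IKK & ¬IkB
IkB  = (NFkB | IkB) & ¬(IKK & NEMO)
```

Under the synchronous scheme all rules fire at once,
`x(t+1) = f(x(t))`, so the dynamics on the 2^N state space are a
deterministic map whose cycles are the network's **attractors** — the
model's counterpart of stable biological phenotypes.  The asynchronous
scheme updates one factor at a time; its *point* attractors coincide with
the synchronous fixed points, which the package exploits and tests.
Knockout (`node = 0`) and overexpression (`node = 1`) are modelled by
clamping a rule to a constant.

Attractors are enumerated exactly at 51 nodes by branching over the input
assignments, propagating implied constants, condensing the residual wiring
into strongly connected components solved block by block, and — when a
component is still too large — branching on nodes whose rules are absorbing
in themselves (see `docs/methods.md`).

## Worked example

```python
import saspnet as sn

model = sn.build_sasp_model()            # 51 nodes, inputs DNAD & Hypoxia
net = model.network

# Time course after DNA damage (t = 1 is the initial state)
traj = sn.simulate(net, model.condition_state("dna_damage"))
for node in ("ATM", "ATR", "p53", "NFkB", "IL6"):
    print(node, sn.first_activation_time(traj, node))

# Exhaustive synchronous attractor enumeration
print(len(sn.exhaustive_attractors(net)))

# Which single perturbations silence IL-6 and IL-8 under DNA damage?
screen = sn.screen_single_perturbations(model, "dna_damage", ("IL6", "IL8"))
print([str(p) for p in screen.silencing_set])
```

prints

```
ATM 2
ATR 2
p53 3
NFkB 4
IL6 5
19
['NEMO=0', 'IKK=0', 'IkB=1', 'NFkB=0']
```

Damage activates the DDR at t=2, stabilises p53 at t=3 and switches NF-κB
on at t=4, after which the cytokines fire; the integrated network has 19
synchronous attractors in total; and exactly four single interventions on
the NF-κB axis — NEMO or IKK or NF-κB knockout, or IκB overexpression —
keep both IL-6 and IL-8 permanently off while leaving the p53/p21 arrest
intact.

The same operations are available from the shell:

```
saspnet simulate --condition dna_damage --perturb NEMO=0 --steps 30 --out traj.csv
saspnet attractors --strategy reduction --out attractors.csv
saspnet screen --condition dna_damage --readouts IL6,IL8 --out screen.csv
saspnet make-fixtures --n 10 --k 2 --count 200 --seed 42 --outdir fixtures/
```

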