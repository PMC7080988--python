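# endmtbn — a Boolean network model of the endothelial-to-mesenchymal transition

Endothelial cells (ECs) lining blood and lymph vessels are plastic: under
angiogenic signals they behave as quiescent *Phalanx*, proliferative
*Stalk*, or migratory *Tip* cells, and under sustained TGFβ/WNT/NOTCH/PDGF
signalling or hypoxia they can differentiate into mesenchymal cells (MCs)
— the endothelial-to-mesenchymal transition (EndMT), central to heart
valve development, fibrosis, atherosclerosis, and pulmonary arterial
hypertension.  `endmtbn` implements a 29-node synchronous Boolean network
that couples the VEGF, HIF, NOTCH, FGF, TGF, WNT, and PDGF pathways to the
transcription factors of endothelial identity (FLI1, GATA2, ETS1) and of
the mesenchymal program (SNAI1, SNAI2, TWIST1, ZEB1, ZEB2, LEF1), together
with the complete analysis suite used to study it.

## The model

Each molecule is a binary variable `x_i`; all nodes update simultaneously,

    x(t+1) = f(x(t)) = (f_1(r_1(t)), ..., f_n(r_n(t))),

where `f_i` is a Boolean function of node *i*'s regulators `r_i`.  Seven
ligand/condition nodes (DLL4, FGF2, HIF1a, PDGF_AB, TGFB, WNT5b, WNT7a)
carry identity rules `x_i(t+1) = x_i(t)`: their joint assignment — the
**microenvironment** — is a constant of motion, so the `2^29` state space
decomposes exactly into `2^7 = 128` independent subspaces.  Attractors
(fixed points and cycles) are read as cell types and cyclic cell
behaviors; the **trap space** of a cell class is the union of the basins
of the attractors carrying its label.

The package provides:

* `network` / `model` / `io` — Boolean networks as truth-table-compiled
  rules, the bundled EndMT model, `.bnet` text-format round-tripping;
* `dynamics` — synchronous stepping (scalar and vectorized), trajectory
  convergence, per-microenvironment successor maps;
* `attractors` — exact, complete attractor enumeration of the full state
  space (constant percolation per environment + pointer doubling), and a
  resolver mapping arbitrary states to their attractor;
* `classify` — marker-based cell-type labelling (EC, MC, Phalanx, Stalk,
  Tip), the nine disjoint cell-type classes, Monte Carlo trap-space
  estimation;
* `structure` — signed functional-interaction extraction, elementary
  feedback-circuit enumeration, circuit functionality;
* `perturb` — knockout/overexpression scans, double mutants, update-rule
  bit-flip robustness, state-noise sensitivity, and the cell-fate
  transition map;
* `cli` — the `endmt` command-line front end.

## Worked example

```python
>>> import endmtbn as e
>>> net = e.build_endmt_network()
>>> atlas = e.enumerate_attractors(net)
>>> atlas.summary()
{'total': 444, 'by_period': {1: 169, 2: 18, 4: 257}, 'environments': 128}
```

The synchronous dynamics has 444 attractors: 169 fixed points, 18 cycles
of period 2, and 257 of period 4 — far more than the 128 guaranteed by
the microenvironments, reflecting the multistability created by the
positive feedback circuits.  In the EndMT-inducing microenvironment
(DLL4, TGFB, WNT5b, WNT7a, PDGF_AB present; HIF1a, FGF2 absent) there are
exactly three attractors, all period 4:

```python
>>> env = e.Environment.from_assignment(net, dict(
...     DLL4=1, FGF2=0, HIF1a=0, PDGF_AB=1, TGFB=1, WNT5b=1, WNT7a=1))
>>> for att in e.attractors_in_environment(atlas, env):
...     ls = e.label_attractor(net, att)
...     print(att.period, sorted(ls.base), ls.nine_class)
4 ['EC', 'MC', 'Stalk'] MCStalk
4 ['MC'] MCsnECs
4 ['EC', 'MC'] MCEConly
```

— a mesenchymal stalk cell, a fully transitioned (non-endothelial)
mesenchymal cell, and an activated EC that cannot fully become a tip cell.
Classifying the whole atlas and estimating trap-space sizes:

```python
>>> report = e.classify_atlas(atlas)
>>> report.counts['MCsnECs'], round(report.fractions['MC'], 3)
(48, 0.568)
>>> est = e.estimate_trap_spaces(net, n_samples=10_000_000, seed=7, atlas=atlas)
>>> round(est.percent('EC'), 3)
97.237
```

48 attractors are mesenchymal-but-not-endothelial (full EndMT), 56.8% of
attractors are mesenchymal, and 97.2% of all initial states drain into an
attractor with endothelial identity.  Simulating disturbed (non-laminar)
blood flow as the ETS1/FLI1 double loss-of-function:

```python
>>> dm = e.double_mutant_analysis(net,
...     [e.MutationSpec('ETS1', 'loss'), e.MutationSpec('FLI1', 'loss')],
...     wild_atlas=atlas)
>>> dm.label_counts['EC'], dm.class_counts['MCsnECs'], round(dm.class_fractions['MCsnECs'], 2)
(0, 347, 0.69)
```

— all endothelial attractors disappear and full-EndMT attractors expand
from 48 to 347 (fraction 0.108 → 0.69): non-laminar flow drives full
EndMT.

The same analyses are available from the shell:

```sh
endmt attractors --out atlas.csv
endmt classify
endmt trapspace --samples 1000000 --seed 42
endmt circuits --functional
endmt mutants --double 'ETS1-,FLI1-'
endmt report --seed 42 --out-dir endmt-report
```

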