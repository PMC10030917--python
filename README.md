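# mechbool

Boolean regulatory-network simulation for mechanosensitive cell-fate
models: rule parsing, four update engines, environment-partitioned
attractor sampling, automated sub-network isolation, in-silico mutant
ensembles, non-saturating inputs with partial knockdown/overexpression,
and phenotype / cell-cycle event statistics.

It is aimed at systems biologists who work with logical models of
processes such as the epithelial–mesenchymal transition (EMT), where cell
fate emerges from multistable switches coupled to mechanosensitive inputs
(ECM stiffness, growth factors, cell density), and who need to map every
stable phenotype of a model and then run virtual experiments against it.

## The model class

Each node is ON/OFF and updates through a Boolean gate over its
regulators, written in a BooleanNet-style rule dialect:

```
GF       *= GF                  # identity self-loop: environmental input
SNAI1    *= NFkB and not GSK3 and not miR_34
miR_34   *= not (SNAI1 or ZEB1)
```

Input nodes are held fixed within an environment *context*; the state
space partitions into one sub-space per input combination.  Attractors of
the deterministic synchronous map — fixed points and limit cycles — are
the model's stable phenotypes.  They are found by a stochastic sampler
that runs short noisy trajectories (per-node flip probability
`p_noise = 0.02`) from random initial states and descends deterministically
from every visited state and every single-bit neighbor, reaching small
basins that noise alone would miss.  Sub-networks are isolated by freezing
removed regulators at the combination that keeps the remaining regulators
functional and maximizes the gate entropy
`H_G = −p·log p − (1−p)·log(1−p)` (`p` = OFF-output fraction).
Time-course experiments use synchronous, noisy, random-order asynchronous,
or biased asynchronous update (condition-dependent node priorities that
suppress unphysiological event orderings in cell-cycle logic).

See `docs/methods.md` for the full account.

## Worked example

The packaged EMT-switch fixture is the tri-stable core of EMT — mutual
inhibition between the epithelial microRNAs miR-34/miR-200 and the
transcription factors Snai1/Zeb1, with former external regulators frozen
by the isolation rule:

```python
from mechbool import build_emt_switch, sample_attractors

model = build_emt_switch()
report = sample_attractors(model, n_rnd=200, rng=0)
print(report.table(model).to_string())
```

```
                A0:5ee92a1dd510  A1:471be9ec38ff  A2:77351c6bac00
period                        1                1                1
NFkB                          1                1                1
GSK3                          0                0                0
c_Myb                         1                1                1
miR_34                        0                1                0
SNAI1                         1                0                1
Twist1                        1                0                1
SNAI2                         1                0                1
ZEB1                          1                0                1
ZEB1_H                        0                0                1
miR_200                       1                1                0
Ecadherin_mRNA                1                1                0
N_bcatenin                    1                0                1
N_bcatenin_H                  0                0                1
```

Three attractors, all fixed points.  `A1` is the epithelial state
(miR-34, miR-200 and E-cadherin mRNA ON, all EMT drivers OFF), `A0` the
hybrid E/M state (miR-34 lost, Snai1/Twist/Snai2 ON with moderate Zeb1,
junctions retained), and `A2` the mesenchymal state (complete flip, high
Zeb1 and high nuclear β-catenin).  Column headers are content-addressed
attractor IDs: the same attractor gets the same ID in any run.

The same workflow scales to deposited full models and scripted virtual
experiments:

```
mechbool sample model.booleannet --n-rnd 200 --seed 1 --out attractors.csv
mechbool isolate model.booleannet --modules EMT,Apoptotic_SW
mechbool run model.booleannet Virtual_Experiment_List.txt --out-dir results
```

where an experiment file holds lines like `Sampling 200 (Trail=0)`,
`Pulse1 41 Stiff_ECM 100`, or
`NonSaturating_Stats_Scan_1Env_fnKDOE 34 GF_High (Stiff_ECM=0.9, GF=1)`.

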