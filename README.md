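# delaynet

Whole-brain **conduction delays** from microstructural connectome weights.

Structural brain networks are usually weighted by streamline counts or
lengths, but the quantity that actually constrains large-scale dynamics is
the *conduction delay* of each white-matter connection. For a myelinated
fibre bundle the delay follows from two microstructural determinants — the
inner axon diameter *d* and the relative myelination expressed by the
g-ratio *g* — through the Rushton relation and the Stikov g-ratio model:

```
MTV = 1 − PD/PD_f                        (macromolecular tissue volume)
AVF = (1 − MTV)(1 − f_csf) · f_r         (axonal volume fraction)
g   = sqrt( 1 / (1 + MTV/AVF) )          (g-ratio)
v   = k · d · sqrt(−ln g)                (conduction velocity, k = 7·10⁶ s⁻¹)
τ   = L / v                              (delay of a connection of length L)
```

Given per-subject connectivity matrices carrying streamline count, mean
connection length, mean axon diameter and the myelin/diffusion volume
fractions, `delaynet`:

1. computes subject-level delay matrices and averages them into a **group
   network** (an edge is retained iff it has more than 4 streamlines in at
   least 9 subjects; contributor-only means, no zero-imputation);
2. fits the **delay–length regression**, whose reciprocal slope is the
   *implied constant conduction velocity* of the network;
3. compares the estimated-delay network against the **constant-velocity
   approximation** with delay-weighted graph measures (Dijkstra shortest
   paths, betweenness centrality, per-block percent differences);
4. simulates **delay-coupled Kuramoto dynamics** (identical 40 Hz
   oscillators, binary coupling, explicit Euler at 1 ms with a delay history
   buffer) over a coupling sweep, summarising each run by global synchrony
   (mean of the order parameter r(t)) and metastability (SD of r(t)).

A synthetic connectome generator (`delaynet.synthetic`) stands in for the
MRI/tractography front end and provides ground-truth stacks for
parameter-recovery tests, including a constant-velocity mode in which the
microstructure is solved backwards from a prescribed velocity.

## Worked example

```python
from delaynet import ConductionDelayModel, SynthConfig

model = ConductionDelayModel.from_synthetic(SynthConfig(seed=1))
res = model.fit()
print(res.summary())
```

```
Conduction delay network results
================================================
ROIs                            82
retained edges                 811
mean length                 0.0832 m
mean diameter               3.4208 um
mean g-ratio                0.7496
mean velocity              12.7483 m/s
mean delay                  6.6072 ms
------------------------------------------------
delay ~ length (OLS)
  slope                    0.07818 s/m
  intercept                0.09974 ms
  R^2                       0.9566
  implied velocity         12.7913 m/s
------------------------------------------------
diameter in [3, 4] um       80.02 %
g-ratio ~ diameter R^2      0.4358
velocity-diameter r         0.8660
```

Reading the output: with axon diameters concentrated near 3–4 μm and
g-ratios near 0.7, every connection conducts at roughly the same ~13 m/s,
so delays grow almost linearly with length (R² ≈ 0.96) and the network as a
whole behaves close to a constant-velocity medium. Downstream of the fit:

```python
cmp = res.compare_paths()          # shortest paths + betweenness, both conditions
print(cmp.blocks)                  # percent differences per connection block

sweep = res.kuramoto_sweep(condition="estimated")   # full 100x100 protocol
```

The same pipeline runs from the shell:

```bash
delaynet run-all --out out/ --seed 1            # scaled-down Kuramoto grid
delaynet run-all --out out/ --seed 1 --full-protocol
```

writing group matrices, `regression.json`, shortest-path/betweenness CSVs,
`sweep_estimated.csv` / `sweep_constant.csv` and a `report.json` that is
fully regenerable from config + seed.

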