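# rcclock

Bayesian relaxed-clock divergence dating for reaction-center proteins,
with the derived rate-through-time statistics used to ask when
Photosystem II acquired the machinery of water oxidation.

## The problem

The two core subunits of Photosystem II, D1 and D2, arose by gene
duplication from a homodimeric ancestor (the duplication node is
called **D0**).  All extant Cyanobacteria inherit a *standard* form of
D1 (groups G3/G4) with a complete Mn₄CaO₅-cluster ligand set.  The
span of time between D0 and the ancestral standard D1,

    ΔT = t(D0) − t(ancestral standard D1),

measures how long the photosystem took to evolve from a highly
oxidizing homodimer to the standard water-splitting enzyme.  Because
D1 and D2 share only ~29% sequence identity while their rate of change
over the Proterozoic is slower than 1% per 100 Ma, ΔT comes out on the
order of a billion years under a wide range of assumptions — which
places the earliest stages of oxygenic photosynthesis deep in the
Archean, long before the Great Oxidation Event (~2.4 Ga).

`rcclock` implements the full analysis pipeline as a tested library
and CLI for anyone doing divergence dating of ancient protein
paralogs:

* amino-acid likelihood (Poisson or empirical LG exchangeabilities,
  discrete-Γ with four categories) on a fixed rooted topology, by
  Felsenstein pruning with fast partial updates;
* a normal root prior, fossil calibrations with hard or *soft* bounds
  (2.5% tail mass outside each bound, 5% below a single minimum), and
  an autocorrelated log-normal clock — a child's log-rate is normal
  around its parent's with variance σ²Δt — or an uncorrelated gamma
  clock;
* a Metropolis–Hastings sampler over node ages, node rates and
  hyperparameters, with multi-chain split-R̂/ESS convergence checks;
* the derived statistics: ΔT with its ±1 sd range, per-node rate
  series, ν_max/ν_min, single-exponential rate-decay fits, the
  power law of ν_max against ΔT, per-site waiting times 1/ν, time to a
  target percent identity, and the identity-versus-time regression;
* a synthetic-data module that generates chronograms, autocorrelated
  rates with a fast-early/slow-late trend, simulated alignments and
  identity tables — including a labeled 74-taxon fixture shaped like
  the Type II reaction-center tree with its eleven fossil-calibration
  events attached.

## Worked example

```python
from rcclock import (
    SimulationConfig, simulate_dataset, calibrations_at_true_ages,
    poisson_model, McmcConfig, run_chain, summarize_nodes,
    rate_ratio_and_waiting_times,
)
from rcclock.priors import ClockModel, RootPrior

# 20 extant proteins, 300 sites, autocorrelated clock sigma^2 = 0.1,
# root at 3.5 Ga, three soft fossil-style calibrations at true ages
config = SimulationConfig(seed=3)
tree, alignment, truth = simulate_dataset(config)
calibrations = calibrations_at_true_ages(tree, n=3)

trace = run_chain(
    alignment, tree, poisson_model(),
    ClockModel(sigma2=0.1, root_rate=0.25),
    RootPrior(3.5, 0.05), calibrations,
    McmcConfig(iterations=400, burn_in=150, thinning=2, seed=7),
)
summary = summarize_nodes(trace, tree)
root = summary[summary.node == f"n{tree.root.index}"].iloc[0]
print(f"root age {root.age_mean:.2f} +/- {root.age_sd:.2f} Ga")
print(f"sigma^2 posterior mean {trace.data.sigma2.mean():.3f}")

wt = rate_ratio_and_waiting_times(17.0, 0.12)
print(f"rate ratio {wt['ratio']:.1f}, "
      f"waiting time {wt['waiting_time_a_ma']:.1f} Ma")
```

prints

```
root age 3.51 +/- 0.05 Ga
sigma^2 posterior mean 0.068
rate ratio 141.7, waiting time 58.8 Ma
```

The root age and σ² recover the generating values (3.5 and 0.1, each
well within two posterior sds); the
last line is the rate arithmetic comparing a fast *Conus* peptide
neurotoxin (17 subs/site/Ga) against standard D1/D2 (0.12): about 140
times faster, each site changing within roughly 60 Ma rather than 8 Ga.

The same pipeline runs from a shell:

```sh
rcclock simulate --n-tips 20 --seed 3 --out toy
rcclock date --alignment toy.fasta --tree toy.nwk \
             --root-mean 3.5 --root-sd 0.05 --chains 4 --seed 7 --out run
rcclock summarize --trace run.chain0.tsv --trace run.chain1.tsv \
                  --tree toy.nwk --decay --out nodes
rcclock identity --pairs pairs.tsv
```

For a real dataset, pass your alignment (FASTA or relaxed PHYLIP), the
fixed rooted topology (Newick), `--model lg`, and a calibration file
written with `rcclock.priors.write_calibration_file` from one of the
packaged profiles (`calibration_1` anchors the MRCA of Cyanobacteria
at 2.45 Ga, `calibration_2` at 2.70 Ga).

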