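# epigames

Agent-based games on contact networks for studying collective resilience,
tipping points, and hydra effects in public health and microbial ecology.

The package implements two minimal models that share one update rule —
synchronous *imitate-the-best* — on the same family of contact structures:

1. **Public health game** (`epigames.phgame`). Individuals on a network
   either *protect* (pay a cost `c` per neighbor; cannot be infected) or
   *defect* (pay nothing; susceptible). Everyone earns a benefit `b` per
   healthy member of their closed neighborhood. An SIS infection spreads
   from each infected individual to each healthy defecting neighbor with
   per-contact probability β and lasts 5 steps. Each round every individual
   adopts the behavior of the highest-earning member of its closed
   neighborhood, switching only when a holder of the *other* behavior
   strictly out-earns every holder of its own:

   `payoff_i = b · |{j ∈ N[i] : j healthy}| − c · deg(i) · 1[i protects]`

2. **Three-strain cyclic dominance game** (`epigames.rpsgame`). Three
   E. coli strategy types compete rock-paper-scissors style: an antibiotic
   *producer* beats the sensitive fast *grower* (with probability
   `attack_rate` per encounter), the *resister* beats the producer, and the
   grower beats the resister. Each cell scores a point per beaten neighbor,
   pays a flat per-round strain cost, and imitates the best local strain.

Both games run on a Moore-neighborhood lattice on a torus (every node has 8
neighbors; mean local clustering exactly 3/7), a uniform G(n, m) random
graph matched on mean degree, or degree-preserving partial rewirings that
interpolate between the two (`epigames.networks`). `epigames.experiments`
provides the parameter sweeps (benefit, infectivity, rewiring fraction,
attack rate, producer cost) plus majority-vote threshold detection and
largest-gap bimodality classification.

## Worked example

```sh
$ epigames phgame run --side 61 --b 5 --c 1 --infectivity 1.0 \
      --steps 500 --seed 1 --out traj.csv
mean_prop_infected: 0.1585
```

At benefit-to-cost ratio 5 on the 61×61 lattice, protection survives and
the population settles into rolling waves — protection, then free-riding
defection, then infection — with roughly 16% of the 3721 individuals
infected on average over the 500 rounds (the exact value varies by seed).
`traj.csv` holds the four compartment counts per step and
`traj.config.json` the fully resolved configuration, from which the run can
be regenerated byte-for-byte.

Dropping the benefit below the lattice's tipping point collapses
protection entirely:

```sh
$ epigames phgame run --side 61 --b 3 --c 1 --infectivity 1.0 \
      --steps 500 --seed 1 --out traj_b3.csv
mean_prop_infected: 0.8310
```

The microbial game at full attack rate shows long-run coexistence at one
third per strain:

```sh
$ epigames rps run --side 61 --attack-rate 1.0 --steps 500 --seed 2 --out rps.csv
mean_prop_producer: 0.3330
mean_prop_resister: 0.3338
mean_prop_grower: 0.3333
```

Sweeps are driven the same way, e.g. the attack-rate experiment that
exposes the hydra effect (restraining the producer's attack makes producers
*more* abundant):

```sh
epigames exp sweep-attack --values 0.1,0.2,0.5,1.0 --reps 5 \
    --master-seed 1 --out attack.csv
```

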