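# refnet

Patient-referral network analysis for district health systems.

Referral systems in many low- and middle-income health systems are
pyramidal: dispensaries (primary care) should refer slightly complicated
cases to health centres (secondary), which should act as **gatekeepers**
and pass only the complex cases on to hospitals (tertiary).  `refnet` is
a toolkit for asking, with survey data on referral events between
facilities, whether that actually happens and which facility
characteristics drive referral ties.  It is aimed at health-systems and
network researchers working with facility rosters, referral ledgers and
road-distance matrices.

The package

* assembles **binary directed referral networks** (one per district and
  care domain, e.g. childcare vs non-communicable diseases): a tie
  `y_ij = 1` iff at least one referral from facility *i* to facility *j*
  was reported in the study window;
* computes the gatekeeping descriptives — density, tier-to-tier flow
  tables, referral rates per visit volume, in-degree and raw directed
  **betweenness centrality**;
* fits directed **exponential random graph models (ERGMs)**

  P(Y = y) = exp(θ·u(y)) / Z(θ),

  where u(y) collects edge propensity, isolates, the geometrically
  weighted in-degree distribution GWIDEG(α) with fixed decay, a dyadic
  road-distance covariate, and sender/receiver facility covariates
  (tier factors, beds, rooms, vehicles, log catchment population,
  log deliveries).  Estimation is by maximum pseudolikelihood (Newton
  with step-halving) and by MCMC maximum likelihood (tie/no-tie
  Metropolis–Hastings sampler, Geyer–Thompson iteration with partial
  stepping, bridge-sampled log-likelihood, AIC/BIC over the
  m = n(n−1) directed dyads);
* judges fits by **simulation goodness of fit** (95% envelopes for the
  model statistics and both degree distributions, with degeneracy
  flags) and turns coefficients into **conditional tie probabilities**
  p_ij = logistic(θ·δ_ij), where δ_ij is the change statistic of dyad
  (i, j) holding the rest of the network fixed — including what-if
  scenarios ("how much more likely is an incoming referral if this
  health centre adds five rooms?");
* generates **synthetic two-district data** — rosters with realistic
  tier mixes and covariate ranges, road-like distances, ERGM-simulated
  networks at known coefficients, and deterministic fixtures that
  reproduce the published tier-to-tier referral breakdowns of the two
  study districts exactly.

## Worked example

```python
import refnet
from refnet import Ergm, ErgmSpec, TermDef
from refnet.studies import recovery_config, recovery_terms, RECOVERY_THETA
from refnet.synth import generate_roster, generate_distances, generate_network

cfg = recovery_config()                      # 40 facilities: 34 D, 3 HC, 3 H
roster = generate_roster(cfg, seed=42)
distances = generate_distances(roster, cfg)
net = generate_network(roster, distances, RECOVERY_THETA, recovery_terms(), seed=42)
print(f"{net.n} facilities, {net.n_edges} ties, density {refnet.density(net):.3f}")

terms = recovery_terms() + [TermDef("node_cov_in", attribute="rooms")]
spec = ErgmSpec(terms, roster=roster, distances=distances)
fit = Ergm(net, spec).fit(method="mcmc", seed=1, n_samples=800,
                          burn_in=20_000, interval=100)
print(fit.summary())
```

prints

```
40 facilities, 26 ties, density 0.017
                 Exponential Random Graph Model
================================================================
District: simdistrict            Domain: childcare
Nodes: 40     Edges: 26     Dyads: 1560
Method: mcmc_mle     Converged: True
Log-likelihood: -126.76   AIC: 261.52   BIC: 282.93
----------------------------------------------------------------
term                                    coef   std err       z
edges                                 -3.601     0.630   -5.71
edgecov.log1p(distance)               -0.937     0.753   -1.24
node_factor_in.hospital                1.512     1.406    1.08
node_cov_in.rooms                     -0.006     0.086   -0.07
================================================================
```

The data were simulated at θ* = (−3.5, −1.0, +2.0, 0): ties are rare,
less likely over longer road distances, and concentrate on hospitals;
the fit recovers exactly that, with the extra rooms coefficient
correctly near zero.  Post-estimation:

```python
sc = fit.scenario_delta(("SIM-D01", "SIM-H03"), receiver_changes={"rooms": 5})
print(f"receiver rooms +5: p {sc.p_old:.3f} -> {sc.p_new:.3f} ({sc.relative_change:+.1%})")
rep = fit.gof(n_sim=200, seed=3)
print(f"GOF: {rep.fraction_inside:.1%} of monitored statistics inside 95% envelopes")
```

```
receiver rooms +5: p 0.064 -> 0.062 (-2.8%)
GOF: 100.0% of monitored statistics inside 95% envelopes
```

The deterministic study-district fixtures drive the descriptive side:

```python
roster, records = refnet.fixture_from_table4("kilolo", "childcare")
net = refnet.assemble_network(records, roster, "kilolo", "childcare")
refnet.density(net)                      # 0.016 on 46 nodes, 33 ties
refnet.tier_flow_counts(net, roster)     # {D->HC: 5, D->H: 22, HC->D: 1, ...}
```

## Command line

```bash
refnet simulate --district kilolo --seed 3 --out sim/
refnet describe --facilities f.csv --referrals r.csv \
    --district kilolo --domain childcare --out reports/
refnet fit --facilities f.csv --referrals r.csv --distances d.csv \
    --district kilolo --domain childcare \
    --terms 'edges + isolates + gwidegree(0.7) + edgecov(distance,log1p)' \
    --method mcmc --seed 1 --out fit/
```

Every stochastic command requires `--seed` and writes a `manifest.json`
from which its outputs are reproducible.  Exit codes: 0 success,
2 usage, 3 data validation, 4 model degeneracy.

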