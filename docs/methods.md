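# Methods

## Data model and network coding

A study consists of a **facility roster** (every facility that can
appear in a network: surveyed facilities of the study district plus
non-surveyed external referral destinations, which must still carry the
model covariates), **referral records** (sender, receiver, condition
category, care domain, reported multiplicity) and a symmetric
**road-distance matrix** in km covering the whole roster.  Distances
are accepted from any source (routed or straight-line); the matrix
records its provenance, is required to be symmetric within 1e-6 km and
is then symmetrized by averaging, since the model uses a single dyadic
distance coefficient.

Networks are coded **binary and non-weighted**: for one district and
care domain, `y_ij = 1` iff at least one referral in any condition
category was reported from *i* to *j*.  Multiplicities are retained in
the records but deliberately ignored by assembly.  The node set is
every roster facility of the district plus any external facility that
receives a matching referral; isolates are kept (the model has an
isolates term).  Node order is roster order, making every downstream
computation deterministic.  Cross-district ties attach the receiver to
the sender's district network; no merged multi-district network is
built, because districts are analysed separately.

## Descriptive statistics

* **Density** = edges / n(n−1) (directed).
* **Tier flows**: tie counts by ordered (sender tier, receiver tier)
  pair, plus ties to privately/faith-based-owned receivers and ties
  crossing district boundaries.
* **Referral rates**: ties per `scale` outpatient or reproductive-and-
  child-health visits at the referring facilities.
* **In-degree / out-degree** and the in-degree distribution D_k.
* **Betweenness** is the raw (unnormalized) directed count of shortest
  paths through a node, with fractional attribution across tied
  shortest paths and endpoints excluded (computed via networkx, checked
  in the test suite against exhaustive path enumeration).  Raw counts
  are used because on referral networks the scores of interest are
  small integers ("this health centre lies on four referral chains"),
  which a [0,1] normalization would obscure.  Rankings break ties by
  facility id.

## The ERGM

P(Y = y) = exp(θ·u(y)) / Z(θ) over simple directed binary networks on a
fixed node set of n facilities (m = n(n−1) dyads).  Implemented terms:

| term | statistic | notes |
|---|---|---|
| `edges` | Σ y_ij | baseline tie propensity |
| `isolates` | #{i: in+out degree 0} | facilities with no referral activity |
| `gwidegree(α)` | e^α Σ_{k≥1} [1 − (1 − e^{−α})^k] D_k | skew of incoming-tie concentration; decay α is **fixed**, one value per model, and not counted among the k parameters |
| `edgecov(x)` | Σ y_ij x_ij | dyadic covariate, e.g. road distance |
| `node_cov_in/out/combined(a)` | Σ y_ij a_j / a_i / (a_i + a_j) | numeric facility covariate |
| `node_factor_in/combined(level)` | indicator versions for tiers | reference level is `dispensary`, never a term |

Covariate transforms are declared per term: `identity`, `log`
(catchment population, guaranteed ≥ 1) or `log1p` (counts that may be
zero, e.g. facility deliveries; also the recommended distance
transform — a strict per-km identity coefficient of paper-typical
magnitude would make referrals beyond a few km essentially impossible,
so the transform is exposed rather than presumed).

The **change statistic** δ_ij = u(y with y_ij=1) − u(y with y_ij=0) is
computed incrementally (edges: 1; edgecov: x_ij; gwidegree:
(1 − e^{−α})^{d_j} with d_j the receiver's in-degree excluding the
focal tie; isolates: −(1[i would stop being isolated] + 1[j would stop
being isolated]); nodal terms from their sums).  θ·δ_ij is the
conditional log-odds of the tie given the rest of the network, and
logistic(θ·δ_ij) its conditional probability.  The test suite verifies
δ against global recomputation for every term on random digraphs.

### Estimation

**MPLE** maximizes Σ_{i≠j} [y_ij θ·δ_ij − log(1 + exp(θ·δ_ij))], a
logistic regression of tie indicators on change statistics over all m
dyads (δ evaluated on the observed network with the focal tie removed;
dyads enumerated row-major in roster order).  Newton iteration with
step-halving; standard errors from the observed information.  Empty or
complete networks raise a separation error.  Quasi-separation (any
|θ| > 20 at convergence) triggers a warning and a refit with a ridge
penalty of 1e-4, flagged in the results.  For dyad-independent models
(no isolates/gwidegree) the pseudolikelihood is the true likelihood and
MPLE is exact ML.  The reported `llf` of an MPLE fit is the
pseudolikelihood and is labelled as such.

**Sampling** uses a tie/no-tie (TNT) Metropolis–Hastings proposal:
with probability 1/2 (when ties exist) toggle off a uniformly chosen
existing tie, otherwise toggle a uniformly chosen dyad; the acceptance
ratio carries the exact proposal correction, including the empty-graph
edge cases.  Statistics are maintained incrementally from change
statistics (verified against global recomputation), the hot loop is
numba-compiled, and every run is reproducible from its seed.  Sampler
defaults for a final fit are burn-in 1e5 proposals, interval 1e3,
1000 samples; iterative phases inside estimation use shorter chains.

**MCMC-MLE** starts from the MPLE (clipped to an edges-only start when
the MPLE quasi-separated) and applies Geyer–Thompson iteration:
simulate at θ_t, maximize the importance-sampled log-likelihood-ratio
approximation Δ·u_obs − log mean exp(Δ·u_s) by damped Newton, update.
When the observed statistic vector lies outside the simulated values'
bounding box, a **partial stepping** correction aims at the farthest
usable convex combination of u_obs with the simulated mean (componentwise
box with a 5% interior margin); if the usable fraction stays below 5%
for three consecutive iterations the model is declared degenerate, with
a diagnostic payload of observed vs simulated statistics.  Convergence
requires the observed vector inside the sampled box and an update below
max(tol, three times the update's own Monte-Carlo noise floor,
estimated as the coefficient standard error over sqrt(sample size)).
Standard errors come from the inverse covariance of sampled statistics
at the final estimate (the estimated Fisher information).

The **log-likelihood** is estimated by a bridge/importance path whose
reference keeps the estimate on all dyad-independent coordinates (their
normalizer factorizes over dyads and is computed exactly) and zeroes
the dyad-dependent ones (isolates, gwidegree); bridges then span only
the dyad-dependent direction, whose statistics have small spread, with
16 bridges of 200 samples by default.  For dyad-independent models the
result is exact.  AIC = −2ℓ + 2k and BIC = −2ℓ + k·log m use
m = n(n−1) as the sample size; k counts estimated coefficients only
(fixed GWIDEG decays are not parameters).  This convention reproduces
the published information-criterion arithmetic this package's
acceptance checks use.

### Goodness of fit and prediction

GOF simulates n_sim networks at the fitted coefficients and compares
the observed model statistics and the full in- and out-degree
distributions against 2.5/97.5-percentile envelopes.  (Geodesic-based
GOF statistics are deliberately not monitored: at densities around
0.02 they are dominated by disconnected pairs and unstable.)
Degeneracy is flagged when the simulated mean density falls below 0.1x
or above 10x the observed density, or when more than 90% of simulations
are empty/complete.

Tie probabilities and scenario deltas are **conditional**: δ is
evaluated on the observed network with the focal tie absent, so results
depend on the dyad's initial conditions.  Scenario prediction applies
raw-attribute increments to the receiver and/or sender before the
term's transform, recomputes δ, and reports (p_new − p_old)/p_old.
Attributes not referenced by the model warn and contribute nothing.
In the edges-only model the tie probability equals the observed density
for every dyad — the inverse-logit identity used as an analytic check
of the whole chain.

## Synthetic data

The generator is a pure function of (config, seed) and emulates the two
study districts' structure: tier mixes 40/3/3 (n = 46) and 25/4/2
(n = 31), per-tier covariate ranges bracketing the published
mean/median/range summaries (counts drawn from truncated
negative-binomial-like distributions, populations log-uniform within
per-tier ranges so the roster median stays dispensary-sized), facility
coordinates uniform on a square with hospitals placed centrally, at the
district edge, or outside the square (the "distant hospital"
geography), and road distances = Euclidean x a detour factor (1.3 by
default).  Networks are drawn from the package's own sampler at
user-supplied coefficients after a long burn-in, with a degeneracy
guard that rejects coefficient vectors producing empty/complete draws
in more than 90% of attempts.

Deterministic **fixtures** reproduce the published tier-to-tier
referral breakdowns of both districts and domains exactly (33/32/33/19
ties; densities 0.016/0.034/0.016/0.020 at 3 d.p.), assigning edges to
distinct dyads by round-robin over roster order — the published tables
constrain only tier-pair counts, not which facilities connect.
Roster-level ownership and survey marks match the published counts
(3 faith-based facilities in the first district; 1 private and
1 faith-based in the second; 42 of 46 and 27 of 31 surveyed).  The
published edge-level marginals ("ties to private/faith-based",
"outside district") are *not* reproduced: their joint assignment with
the tier breakdown is not recoverable, and all fixture nodes keep the
study-district label so that both domains span the full node set.
Fixture edges are deterministic, not model draws, so ERGMs with rich
receiver-tier terms are near-separated on them — useful for exercising
the separation/stepping machinery, not for interpreting coefficients.

## Simulation studies

**Parameter recovery** (the estimator's internal evidence): 50
replicate districts of 40 facilities (34/3/3) on a compact 2 km square
with road factor 1.3, networks drawn at
θ* = (edges −3.5, log1p-distance −1.0, hospital-in +2.0), each refit by
MCMC-MLE.  The spatial extent is a free unit absorbed by the distance
coefficient; 2 km makes the expected density ≈ 0.02, the sparsity
regime of the observed networks, and was fixed analytically from the
inverse-logit mean.  Passing bias/coverage here shows the estimator
recovers known coefficients from data generated by its own model at
realistic sparsity; it does not certify behaviour under model
misspecification, informative missingness, or real road networks.

**GOF calibration**: 20 replicate networks evaluated at the generating
θ* keep ≈ 98% of monitored statistics inside their 95% envelopes.

## Numerical choices and known limitations

* Dyad enumeration and node order are roster order throughout;
  centrality ranking ties break lexicographically; all stochastic
  outputs record their seed.
* The MPLE Newton stops on gradient < 1e-8 or likelihood change
  < 1e-10, with up to 40 halvings per step.
* The stepping hull test is a componentwise bounding box, a cheaper,
  slightly conservative stand-in for the true convex hull.
* At the recovery study's size (≈ 26 ties, three correlated
  coefficients) the ML estimate of the distance coefficient shows a
  genuine finite-sample attenuation of about 0.1 — visible identically
  under exact ML on the dyad-independent model, so it is a property of
  maximum likelihood at this sparsity, not of the MCMC approximation.
* GWIDEG decay is fixed, never estimated (no curved ERGMs); no triadic
  or temporal terms; no marginal-effect curves — tie probabilities are
  conditional by construction.
* The log-likelihood of dyad-dependent models is simulation-based;
  repeated runs vary at the Monte-Carlo level, and AIC/BIC comparisons
  should only be made between fits using the same method tag.
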