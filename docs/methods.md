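# Methods

This note documents the models implemented in `msmkin`, the assumptions
they rest on, the tunable parameters that matter, and the choices made
where the design was genuinely open.

## Markov state models

A discrete trajectory is a sequence of microstate labels with a fixed frame
spacing Δt (ns). Transition counts at lag τ = L·Δt use sliding-window
counting: every frame t with t + L inside the same trajectory contributes
the ordered pair (s_t, s_{t+L}). Sliding windows maximize counts at the
price of correlated pairs; the alternative (strided counting) discards
data without removing the correlation problem in practice.

Estimation restricts to the largest strongly connected component of the
count graph (ties broken toward the component holding the most counts),
then symmetrizes and row-normalizes: T = rownorm((C + Cᵀ)/2). This
estimator imposes detailed balance exactly — π_i T_ij = π_j T_ji — and its
stationary distribution is available in closed form as the normalized row
sums of the symmetrized counts. It is a consistent estimator only for
dynamics that are reversible in truth, which physical equilibrium
simulations are; applying it to data from a genuinely irreversible process
biases the model (and, usefully, causes the Chapman–Kolmogorov test to
fail). The maximum-likelihood reversible estimator is deliberately out of
scope: at the package's supported scale the naive scheme is standard and
transparent.

Implied timescales are tᵢ(τ) = −τ / ln λᵢ(τ) for the eigenvalues
λ₂ ≥ λ₃ ≥ … of T(τ). (The negative sign belongs under the logarithm's
reciprocal — a timescale, not a rate; the form −τ·ln λ that sometimes
appears in print is dimensionally inconsistent with the requirement that
timescales be constant in τ.) Because T is reversible, the spectrum is
computed stably through the symmetric similarity transform
D^{1/2} T D^{−1/2}. Eigenvalues ≤ 0 yield undefined timescales, which are
reported as NaN with an explicit flag rather than dropped. The Markovian
lag is the smallest scanned lag after which every successive relative
change of the slowest timescale stays within a tolerance (default 10%); if
no such lag exists the result is an explicit "no plateau", never a silent
fallback.

## Chapman–Kolmogorov test

For each tested state A and multiple k, the model prediction
pMSM(A,A;kτ) = [T(τ)ᵏ]_AA is compared with pMD(A,A;kτ), the AA element of
a transition matrix re-estimated directly at lag kτ. The uncertainty on
pMD is the binomial standard error √(p(1−p)/N_A) with N_A the transition
counts originating in A at lag kτ; a cell passes at |pMSM − pMD| ≤ 2σ.
This is a deliberate simplification of the full Bayesian error expression
in the MSM validation literature: it captures the leading 1/√N behaviour,
and an implementer needing the exact posterior width can substitute it at
one marked point. Only singleton state sets are tested (the common
practice when trajectories are only a few lag times long); k defaults to
1..3 for the same reason.

## BACE coarse-graining

Merging is agglomerative under the log Bayes factor

    ln B_ij = C_i · D(p_i ‖ q) + C_j · D(p_j ‖ q),

where p_i is row i's normalized transition profile, C_i its total outgoing
counts, q the count-weighted mean profile of the pair, and D the
Kullback–Leibler divergence. At every step the minimal-cost pair is merged
(cost ties broken toward the lexicographically smallest pair), rows and
columns of the aggregated count matrix are summed (total counts are
conserved exactly), and the cost is recorded against the resulting model
size.

The macrostate count is chosen at the Bayes-factor elbow. For each size n
the jump ratio cost(n−1)/cost(n) measures how much more damaging it would
be to coarse-grain below n than it was to reach n. The selected size is
the most prominent jump — the largest ratio, ties toward the smaller
size — provided it reaches `jump_factor` (default 3). Prominence, rather
than the first ratio exceeding the factor, is used because sampled counts
produce mild spurious ratios (3–4×) all along the cost curve; the elbow of
a genuinely metastable system exceeds the background by orders of
magnitude. When no jump reaches the factor the smallest size is returned
with a warning.

Lumping re-estimates the macrostate transition matrix from the aggregated
counts with the same symmetrize-and-normalize scheme, rather than
π-weighting the microstate matrix: this keeps counts exactly conserved and
matches the count-based logic of the merge criterion. Macrostate
populations are sums of member microstate stationary weights (exact).

Binding-competence classification labels a macrostate *active* when its
mean docking score is at or below a cutoff (default −5.0 kcal/mol,
boundary inclusive). The free-energy reference state is an explicit
argument everywhere, since "the most populated state" can be ambiguous
when two populations are close.

## Kinetics

MFPTs solve x_i = τ + Σ_j T_ij x_j for i ≠ target with x_target = 0, i.e.
the linear system (I − T_sub)x = τ·1 — algebraically identical to the
fundamental-matrix closed form (I − T_sub)⁻¹τ·1, but solved rather than
inverted. Results scale linearly in τ and are reported in ns. Relative
free energies are FE_i = −ln(p_i/p_ref) in kT. Under Arrhenius kinetics
rate constants are proportional to exp(−ΔG‡/kT), so relative barrier
heights follow from MFPT ratios, ΔΔG‡ = ln(MFPT/MFPT_min) with MFPT_min
the single smallest off-diagonal entry (when the two lowest barriers are
equal, as in degenerate landscapes, this coincides with normalizing by
their mean).

Transition-path theory: the forward committor q⁺ is harmonic between the
source (q⁺=0) and sink (q⁺=1) sets. Net reactive flux uses
f⁺_ij = max(0, π_i q⁻_i T_ij q⁺_j − π_j q⁻_j T_ji q⁺_i) with q⁻ = 1 − q⁺,
the backward committor of a reversible chain — for reversible T this
reduces to π_i T_ij (q⁺_j − q⁺_i)⁺ and satisfies flux conservation, with
the total reactive flux equal to Σ_{i∈source,j} π_i T_ij q⁺_j. (A variant
that subtracts the doubled reverse term violates that conservation
identity and is not used.) Pathways are extracted by iterative bottleneck
decomposition: the maximum-bottleneck source→sink path (widest-path
Dijkstra), subtraction of its bottleneck flux, repeat. Fractions are
relative to the total reactive flux; for non-reversible input matrices the
q⁻ = 1 − q⁺ identity is approximate and fractions may not reach 1.

## Uncertainty

Transition matrices consistent with the observed counts are sampled by
Metropolis Monte Carlo: each step picks a row and two entries, shifts
probability mass Δ ~ U(−w, w) between them (rejecting moves that leave
[0,1]), and accepts with the multinomial likelihood ratio
Π (T′/T)^C over the two changed entries. Detailed balance is *not*
imposed on the samples — the move set is explicitly
nonreversible-ensemble — and zero-count entries remain proposable (their
likelihood exponent is 0), since forbidding them would narrow the
intervals artificially. Defaults: 10⁶ steps, thinning 1000 (1000 samples),
proposal width 0.05 tuned to a 20–50% acceptance rate on fixture counts;
rows without counts are held fixed with a warning.

Observables are recomputed per thinned sample; intervals are percentile
pairs (10th/90th for the default 80% level). Samples whose MFPT system is
singular (reducible draws) are skipped and counted, and the computation is
rejected if more than half are. When a skewed posterior puts the MLE point
outside the percentile interval the estimate is flagged, not clipped. The
bootstrap (default 10,000 rounds) resamples with replacement and returns
the standard deviation of the statistic's bootstrap distribution.

## FAST adaptive sampling

Rewards are rf(i) = f̄(i) + a·ȳ(i) with f̄ the min–max normalized
structural objective (direction-aware) and ȳ = (C_max − C_i)/(C_max −
C_min) the undersampling preference; a = 1 weights the two equally, and
rf is invariant to affine rescaling of the objective. Degenerate spreads
(all f equal, or all counts equal) zero the corresponding term: an
uninformative term should express no preference. Batches are allocated
proportionally to rf with largest-remainder (Hamilton) rounding, so counts
are integers summing exactly to the batch size and allocation is monotone
in each state's reward. The within-protocol re-clustering into a small
number of restart states reuses the clustering module (k = 10 restart
states for a 30-simulation batch gives an average of three starts per
state).

## Rate recovery from biased simulations

The acceleration factor of a history-dependent bias V(s,t) is the running
average a(t_n) = (1/n) Σ_{m≤n} exp(V(s,t_m)/k_BT) over recorded trace
samples (uniform weight per sample; the trace stride is assumed constant,
as in deposition-stride output files). The unbiased event time is
a(t_event)·t_event, with a evaluated at the last recorded sample at or
before the event. Event-time sets are fitted to the Poisson law
P(t) = 1 − exp(−t/τ); τ is the exponential maximum-likelihood estimate
(the sample mean) by default, with an ECDF least-squares option
(`method="ecdf"`) since the fitting variant materially changes
small-sample estimates. The KS p-value is computed against the *fitted*
exponential and is therefore approximate (anti-conservative); it is meant
to flag clearly non-Poissonian sets, not as a calibrated test. Lifetime
comparisons propagate ratio errors to first order:
SE(r)/r = √((SE_a/τ_a)² + (SE_b/τ_b)²).

## Synthetic ground truth

The chain generator produces a reversible metastable chain with an exactly
prescribed stationary distribution: states are grouped into blocks sharing
the block population uniformly, and

    T = (1 − mixing) · U_block + mixing · 1πᵀ,

a mixture of a within-block uniform jump and a global jump to the
stationary law. Both components are reversible with respect to π, so
detailed balance holds to machine precision; same-block microstates have
identical rows (exchangeable), which is precisely the structure a
count-profile coarse-grainer can recover; and the spectrum is analytic —
eigenvalue (1 − mixing) with multiplicity n_blocks − 1 for inter-block
relaxation, 0 for all within-block modes. An earlier sqrt(π_iπ_j)-affinity
skeleton with a global row scale was abandoned: it made minor-state
microstates nearly absorbing and gave same-block states dissimilar
transition profiles, smearing the coarse-graining elbow.

Default fixture: 8 macrostates with populations, indexed by label,
(6.0, 4.2, 43.9, 3.1, 2.2, 38.9, 1.2, 0.5)% — the dominant pair at the
reported 43.9%/38.9%, minor states inside the reported 0.5–6.0% band
(their individual values are fixture choices, not reported quantities) —
three microstates per block, mixing 0.05 (slowest relaxation ≈ 19.5
frames), frame time 0.1 ns. Docking-score means are set so that
macrostates 1, 2, 5 and 6 fall on the active side of the −5.0 kcal/mol
cutoff (active population 51.3%; macrostate 2 sits exactly on the
boundary, so finite docking samples classify it active roughly half the
time — the honest behaviour of a boundary state). Feature emission is
isotropic Gaussian per state with means drawn at 3× unit scale in 3
dimensions and σ = 0.08, i.e. tens of σ between typical state means, so
discretization error is negligible by construction; anisotropic or
overlapping emissions are intentionally not modelled. Bias schedules are
deterministic; the well-tempered-like kind accumulates increments
h·exp(−V/((γ−1)k_BT)) at a fixed deposition interval (defaults 2.5 kJ/mol
per 5 ps, bias factor 10). The replica-ladder helper implements geometric
spacing T_i = T_min·(T_max/T_min)^(i/(n−1)) and reports the arithmetic
mean spacing.

What a green test on this synthetic world does *not* establish: clustering
quality under overlapping emissions, estimator behaviour for irreversible
dynamics, elbow detection when metastability is weak (merge-cost
background within a factor ~3 of the elbow), or anything about a specific
molecular system — the generator states a world with exactly recoverable
structure so that algorithmic correctness, not robustness to messy data,
is what the tests certify.

## Numerical choices and degenerate inputs

- Row-stochasticity is enforced to 1e-12 in sampled matrices; stationary
  solutions are verified to 1e-8 and rejected otherwise.
- Frame-assignment ties go to the lowest center index; BACE cost ties to
  the lexicographically smallest pair; allocation-remainder ties to the
  lower state index. All randomized routines take explicit integer seeds
  and are byte-reproducible.
- The MFPT solver rejects non-positive solutions (a symptom of a reducible
  chain) rather than returning garbage; the committor clips solutions to
  [0, 1] only to absorb rounding at the boundary.
- Single-macrostate lumping returns the trivial 1×1 model directly, since
  the connected-component machinery requires two states.
- Pipeline stage seeds derive from the master seed by SHA-256 of
  "seed:stage", truncated to 31 bits, so stages are decorrelated and runs
  are reproducible hash-for-hash.

## Known limitations

- No maximum-likelihood reversible estimator, Bayesian MSMs, hidden-state
  models, or continuous-time rate matrices.
- The committor and MFPT solvers are dense; practical up to a few thousand
  states, not for 10⁵-state models.
- CK uncertainties ignore the correlation between sliding-window counts,
  so σ is mildly optimistic at large k.
- The acceleration-factor average weights recorded trace samples
  uniformly; traces with a non-uniform stride should be resampled first.
- Docking scores and structural objectives are inputs; the package neither
  docks ligands nor runs simulations.
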