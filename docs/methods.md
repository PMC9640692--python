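# Methods

## Model scope and cell-cycle scaffold

All model families share one event-driven scaffold. A single cell grows
exponentially, V(t) = V_b e^{λt}, with the growth rate λ a cell-cycle
independent parameter. Replication initiates synchronously at all origins
when the model's initiation signal reaches its threshold; each initiation
starts a replication round whose forks advance at the constant rate 1/T_C,
schedules a division at the fixed cycling time τ_cc = T_C + T_D after the
initiation event, and starts an eclipse clock of duration τ_b during which
the origin cannot refire (SeqA sequestration). At division, volume,
chromosome content and molecule counts are halved and one daughter is
followed; in the mean-field description this leaves every concentration
unchanged, so division does not perturb the replication cycle. Each
simulation starts from one fully replicated chromosome.

Multifork bookkeeping stores no fork positions: a round started with k
origins contributes k·age/T_C genome equivalents while active and turns k
replicating chromosomes into k complete ones at age T_C. Locus copy
numbers follow from this: titration sites are proportional to genome
equivalents (n_s per equivalent, giving the linear N_0 → 2N_0 ramp over
the C period for a single round), datA shares the origin count (it sits
next to oriC), and the DARS1/DARS2 counts increase by the number of
newly fired origins at fixed delays τ_d1, τ_d2 after each initiation.

Default cell-cycle numbers: T_C = 40 min, T_D = 20 min, τ_b = 10 min,
τ_d2 = 16 min (DARS2 near mid-chromosome), τ_d1 = 12 min. Units are
minutes, cubic micrometres and molecules per μm³ throughout; the CLI
accepts growth rates in h⁻¹.

## Numerical scheme

Fixed-step explicit Euler, default dt = 0.01 min (0.02–0.05 min is used
for long statistical runs; halving dt moves the steady-state initiation
volume of every deterministic family by < 0.1%, which the test suite
checks). Event times — threshold crossings and eclipse expiry — are
resolved by linear interpolation inside the step; state updates apply at
step boundaries, and simultaneous events are processed in the order
initiation → replication completion → division. The initiation predicate
is evaluated per cell (initiation is synchronous), uses ≥ with crossing
from below, and is suppressed, not errored, during the eclipse; if the
signal is still above threshold when the eclipse expires, the origin
refires exactly at the eclipse end. The push–pull switch equations become
stiff near the f ∈ {0, 1} boundaries when the (de)activation totals are
large, so the f update substeps adaptively to stay well inside the Euler
stability limit (bound |∂rhs/∂f| ≤ A/K_act + B/K_deact + λ); f may then
overshoot the unit interval by at most 10⁻⁹ before clamping, and any
larger excursion raises an error. Runs abort with a diagnostic naming the
variable and time if a state variable becomes non-finite. Identical
parameters and seed give bit-identical records.

## Titration (AIT) family

Synthesis follows the volume-proportional autoregulated rate law with
gene-allocation density φ̃_p⁰ = 500 μm⁻³, promoter constant K_D^p = 200
μm⁻³ and Hill coefficient n = 5. Binding to the n_s = 300 titration sites
per genome equivalent (K_D^s = 1 μm⁻³) is treated in quasi-equilibrium:
the free concentration is the physical root of the mass-action quadratic
p_f² + p_f(s_tot − p_tot + K_s) − K_s p_tot = 0, verified in the tests
against an independent numeric equilibrium solver to 10⁻⁹ relative.
Origin sites are not counted in s_tot (a handful versus hundreds).
Initiation fires at [p] = K_D^ori = 150 μm⁻³ > K_D^s. With these numbers
the free concentration stays far below threshold while unoccupied sites
remain and rises sharply once N_p exceeds N_s, the slow-growth initiation
volume is ≈ 0.9 μm³ per origin, and the deterministic failure boundary
of the mechanism sits at the fork-overlap point: for τ_d < T_C premature
reinitiation appears (intervals down to ~29 min at τ_d = 35 min) and the
CV of v* rises by orders of magnitude, while for τ_d ≲ ln2·T_C ≈ 27 min
the free concentration no longer falls below threshold during the eclipse
and reinitiation locks to the eclipse end.

Two observations about this family are worth recording. First,
immediately after initiation the free-concentration drift is
d[p]/dt = (λ n_s ĝ − (n_s/T_C) σ)/v*, with ĝ ≤ 1 the genome equivalents
per origin and σ ≥ 1 the fork pairs per pre-initiation origin: the
synthesis-side constants (φ̃_p⁰, K_D^p, K_D^ori) cancel exactly. Eclipse-
limited reinitiation therefore requires λ ĝ T_C ≥ σ, i.e. τ_d ≲ ln2·T_C,
and cannot occur at τ_d = 35 min with T_C = 40 min for any choice of the
binding and synthesis constants — at that doubling time the model fails
by premature (but not eclipse-limited) reinitiation. Second, the SeqA
synthesis-block variant (synthesis silenced while the eclipse clock runs)
stabilizes the fast-growth cycle, and in this implementation it does so
over the whole τ_d = 24–44 min range: the period-one cycle is strongly
attracting and no deterministic alternating (period-two) window was found
in extensive parameter sweeps. The intermediate-growth fragility of
titration+SeqA does appear stochastically: with Poisson expression noise
the CV of v* at λ = 1.2 h⁻¹ is about twice its value at 1.6 h⁻¹.

## Activation switch (LD, LDDR)

The total DnaA concentration is held strictly constant and only the
ATP-bound fraction evolves,

    df/dt = A(t) (1−f)/(K̃_act + 1−f) − B(t) f/(K̃_deact + f) + λ(1−f),

with K̃ = 0.1 on both sides and f* = 0.75. The λ(1−f) term is protein
synthesis (new DnaA binds ATP). LD keeps A = α̃_l [l] (lipid activation,
volume-independent) and B = β̃_datA n_ori/V with the measured scales
β̃_datA = 0.025 μm³/min (10 DnaA/min per datA at 400 total DnaA per μm³)
and α̃_l = 4.6 β̃_datA with mean lipid level 0.3 μm⁻³. Because B falls
with volume while the lipid part of A does not, the steady fraction rises
as the cell grows and v* ≈ β̃_datA r*/(α̃_l⟨l⟩) ≈ 1 μm³; the amplitude
Δf = f* − f_min shrinks with growth rate at these realistic rates
(0.27 at λ = 0.35 h⁻¹ down to 0.06 at 2 h⁻¹) and grows when both rates
are scaled up.

LDDR adds DARS1 (constant α̃_d1), DARS2 and datA two-level activity
windows anchored to the latest initiation, and RIDA active while any
round is replicating. The defaults encode three constraints. (i) Timing:
datA activity is high during [0, 15) min after initiation (IHF bound),
DARS2 is high during [16, 40) min — from its duplication until fork
completion — so that at slow growth the late cycle reduces to an LD-like
lipid-versus-datA balance, while at fast growth (inter-initiation
interval within the window) initiation happens with RIDA and DARS2-high
both active. A single low→high DARS2 step, with no closing edge, leaves
the high activation unopposed once RIDA stops at slow growth and
destabilizes the model, which is why the profiles are windows. (ii)
Balance: α̃_d2^high ≈ r*·β̃_rida + α̃_d2^low (r* ≈ 1.24 is the push–pull
ratio at f*), so DARS2 compensates RIDA and the initiation volume is
comparable in both growth regimes. (iii) Potency: RIDA and DARS2 must be
fast (β̃_rida = 1.5 μm³/min, α̃_d2^high = 1.86, datA window 0.07/0.6)
— at weaker rates the fast-growth fixed point is only marginally coupled
to volume and v* drifts. DARS1 is set far below DARS2 (α̃_d1 = 0.0375);
a DARS1 of a tenth of DARS2, as in vitro activity ratios suggest, would
already out-activate basal datA and break the slow-growth switch-off, so
the constant is read as a lumped in-vivo effective rate. With these
defaults the LDDR model runs stable cycles with v* between 0.93 and 1.32
μm³ and Δf ≈ 0.75 from τ_d = 21 to 120 min.

Zeroing DARS1/2 and RIDA and flattening datA reduces the LDDR code path
bit-for-bit to LD; the test suite asserts this. A flag switches RIDA from
origin-count to replisome-count scaling; the default follows the
fraction equation (origin count).

## Coupled titration–switch model

Total and ATP-bound DnaA copy numbers are explicit. Synthesis uses the
AIT rate law with repression by the free total DnaA concentration (only
DnaA off the titration sites reaches the promoter) and is silenced during
the SeqA block; all new protein enters the ATP pool. Activation and
deactivation act on copy numbers with the LDDR rate set un-normalized by
the 400 μm⁻³ DnaA scale (K_D = 40 μm⁻³, α_l = 46, β_rida = 600 etc.).
Active and inactive DnaA share the site affinity, so the free total
concentration follows the same binding quadratic as AIT and the free
ATP-DnaA concentration factorizes as [D]_ATP,f = [D]_T,f · f. Initiation
fires at [D]*_ATP,f = 50 μm⁻³. In the constant-total, no-titration limit
the fraction dynamics d(N_ATP/N_T)/dt reproduces the LDDR equation at
matched parameters (tested). Titration keeps [D]_ATP,f pinned near zero
until the sites fill and then releases it sharply: at λ = 0.35 h⁻¹ the
coupled model spends a much smaller fraction of the cycle near threshold
than LDDR, which is why lipid noise moves its initiation volume far less
(CV 0.02 versus 0.11 at matched noise).

## Stochastic layer and statistics

Lipid fluctuations are an Ornstein–Uhlenbeck process: production α = λ⟨l⟩,
dilution at λ, additive Gaussian increments with σ = ⟨l⟩·CV_l·√(2λ) so
the stationary coefficient of variation equals CV_l; negative excursions
clip at zero, and an optional zero-mean division kick of relative SD
`partition_kick` models partitioning noise at the concentration level.
The default noise condition CV_l = 0.10 is a calibration: it places the
CV of the LD initiation volume at the experimentally reported ~10%.
DnaA expression noise, where enabled, is a Poisson birth process at the
deterministic synthesis rate with binomial partitioning at division.
Mean-field runs are noise-free and real-valued.

Perturbation-relaxation ensembles impose a common lipid offset (default
0.3⟨l⟩) at a division event after burn-in and record the conditional
means of the lipid level and of v* at the following initiations. The v*
baseline is pooled from the same replicates after relaxation, which is
substantially more precise than a separate reference lineage. Decay
factors are fitted log-linearly over generations 1–4: generation 0 still
carries the finite switch-relaxation lag, and later generations approach
the sampling floor. Measured factors are 0.48 ± 0.02 per generation for
both δl and δv* with 100 replicates at CV_l = 0.015 — the small offset
from exactly ½ is event-time sampling (recovering lineages initiate at
slightly stretched intervals). Because lipids activate the switch, the
steady-state mapping v*([l]) is monotonically decreasing, and a positive
lipid offset depresses the initiation volume.

Statistics: v*_n uses the origin count before doubling; Δv*_n = 2v*_{n+1}
− v*_n; the adder regression reports the least-squares slope and Pearson
R on raw pairs plus equal-count bins (default 10, chosen over equal-width
to stabilize the per-bin SEM in the tails) with mean ± SEM; the CV uses
the population SD (differences to the sample SD are negligible at the
event counts used). All statistics discard a burn-in of 10 generations by
default.

## Problem sizes

Deterministic regime checks use 30–50 generations at dt = 0.02 min.
Stochastic statistics use dt = 0.05 min with ~1000 initiation events for
the adder regression, ~300 events per condition for the CV comparisons,
and 100 replicates for relaxation ensembles. These sizes put Monte-Carlo
errors well below the effect sizes being tested (e.g. SEM of the adder
ratio ~0.003 against a tolerance of 0.02).

## What the simulations do and do not show

The generator is the model: it emulates idealized lineages with constant
growth rate, strictly timed division, synchronous initiation and a single
noise source at a time. It does not emulate growth-rate fluctuations,
division-site noise, initiation asynchrony between sister origins,
growth-rate-dependent eclipse duration, or coupling between division and
birth size beyond the τ_cc timer — so passing tests validate the control
logic of the mechanisms, not a fit to any experimental single-cell data
set. Known limitations: the AIT family cannot produce eclipse-limited
reinitiation at τ_d = 35 min (see the drift identity above — the
implementation places that regime at τ_d ≲ 27 min), and the SeqA
synthesis-block variant does not show a deterministic alternating-interval
window at intermediate growth rates; its fragility there is visible only
under expression noise. Kinetic constants without a measured scale were
fixed once to reproduce the regime structure described above and are all
exposed in the configuration; the emitted run metadata tags which
defaults trace to measured scales and which are calibration decisions.
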