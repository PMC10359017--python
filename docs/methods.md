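# Methods

## Model and assumptions

The package implements the public-assessment model of indirect reciprocity in
an infinitely large, well-mixed population playing one-shot donation games
(cost *c*, benefit *b* > *c*). Reputations are binary and **public**: every
observer applies the same norm to the same interaction, so the population
state reduces to the fraction *h*(*t*) of players in good standing. A norm is
20 probabilities: the action rule *P*(*X*, *Y*) (4 entries) and two
assessment rules *R*₁, *R*₂ (8 entries each) for donor and recipient. Both
players are re-assessed after every game; the recipient-passive rule
*R*₂(*X*, *Y*, *A*) = δ(*Y*, G) recovers the classical donor-only model.

Errors enter as effective rules: P̃ = (1 − μ_e)·P for intended cooperation
misfiring into defection, and R̃ᵢ = (1 − μ_aᵢ)·Rᵢ + μ_aᵢ·(1 − Rᵢ) for flipped
assessments. A recipient-passive *R*₂ is an ordinary assessment table and is
subject to μ_a2 like any other; callers who want literally frozen recipient
reputations pass μ_a2 = 0. This choice is forced by consistency: the
first-order error expansion only reproduces the equal-rate sensitivities of
the classical families (4 for the leading eight, 7 for the secondary sixteen)
and the closed-form sL2 sensitivity 1 + (3 − p₁)/(p₃ + p₄) when the μ_a2 term
acts on the passive table.

## Homogeneous dynamics

Averaging assessments over the donor's effective action gives per-context
good-assignment probabilities R̄ᵢ(*X*, *Y*); their sum s(*X*, *Y*) drives the
quadratic flow

    dh/dt = h² s(G,G) + h(1−h)[s(G,B) + s(B,G)] + (1−h)² s(B,B) − 2h.

With positive assessment error the flow points inward at both boundaries, so
the fixed point *h*\* is unique and stable. The solver uses the closed-form
root of A h² + B h + C = 0, switching to the linear branch when |A| < 10⁻⁹,
then polishes with at most 50 Newton steps on the quadratic residual
(tolerance 10⁻¹⁴) and clamps to [0, 1]; if the preferred root
(−B − √disc)/(2A) leaves [0, 1] by more than 10⁻⁹ the conjugate root is
taken. When all error rates are exactly zero both boundaries can be roots;
the solver reports the limit from positive error by substituting assessment
rates of 10⁻¹². A degenerate linear coefficient falls back to a bracketed
root of the flow itself. Fixed-point residuals stay below 10⁻¹⁰ across the
catalog at μ ∈ {0, 10⁻³, 10⁻²}.

Two independent oracles guard this machinery: direct integration of the flow
(scipy LSODA, tolerances 10⁻¹²; agreement within 10⁻⁸ on 200 seeded random
stochastic norms) and an agent-based simulation of the interaction process
(sequential donor-recipient draws over a finite population, seeded numpy
Generator). The simulation is the only stochastic component in the package;
everything else is closed-form.

## Stability and the CESS verdict

Rare mutants deviate only in their action rule — they are too rare to shift
how the public assigns reputations — and per-context best responses are
deterministic, so the mutant set is the 15 deterministic action rules
differing from the resident's (stochastic residents are rejected by the
numerical check: they are at best payoff-neutral against some deterministic
rule and never strictly stable). The mutant's good fraction follows a linear
flow with fixed point H\*; payoffs π_res = (b−c)·p_res→res and
π_mut = b·p_res→mut − c·p_mut→res turn strict stability into per-mutant
bounds on *b*/*c*, intersected into an interval (L, U) with L initialized at
1 and U at +∞ (serialized as the string "inf"). Ties
|p_res→res − p_res→mut| < 10⁻⁹ use the degenerate branch (stable for every
*b*/*c* iff the mutant cooperates strictly more with residents); the paper-
level notion of "strict" at finite error rates has no canonical numerical
meaning, so this tolerance is this package's convention. The numerical
check runs at μ_e = μ_a1 = μ_a2 = 10⁻³ with self-cooperation threshold
p_th = 0.98 by default and discards numerical edge cases (|U − L| < 10⁻³ or
L > 10); all four parameters are configurable.

The analytic classifier evaluates the same per-context optimality logic in
the rare-error limit with exact entries. Both label orientations are tried
(the G/B relabeling mirrors the dynamics, h → 1 − h), so verdicts are
swap-invariant. Branch P(B,G) = 1 shares the bound numerator
R₁(B,G,C) + R₂(G,B,D); branch P(B,G) = 0 produces bounds of the form
1 + (R₁(B,G,D) + R₂(G,B,D))/denominator. A non-positive denominator makes the
condition unfulfillable and the bound +∞. The deviation bound in the (B,B)
context depends on *b*/*c* itself, so P(B,B) is not free: the classifier
treats the norm's own P(B,B) as a constraint (lower-bound update when 1,
upper-bound update when 0) and reports as `forced_pbb` the value admitting a
feasible interval. For the stochastic sL2 family the caption-level condition
"1 − p₁ > p₃" is strictly stronger than interval feasibility (for
p₃ ≤ 1 − p₁ the bound clamps at max{(p₃+p₄)/p₃, 1}); `sl2_bounds` implements
the full interval and reports the stricter inequality as a separate flag
rather than folding it into the verdict.

## Error sensitivity

χ is the expected total number of defections seeded by one bad player: a
geometric cascade whose denominator equals −d(dh/dt)/dh at h = 1 in the
rare-error limit (asserted numerically in the tests). The first-order
expansion 1 − p_res→res ≈ (1 + [2 − R₁(G,G,D) − R₂(G,G,D)]χ)μ_e + χμ_a1 +
χμ_a2 is derived for CESS norms; the package evaluates it for any norm with
a deterministic P(B,G) but flags non-CESS inputs in reports. The
single-parameter sensitivity uses μ_e = μ_a1 = μ_a2 = μ for every norm
(see above). Agreement between expansion and the exact (1 − p_res→res)/μ is
within 2% at μ = 10⁻⁴ across the deterministic CESS families; the
approximation degrades when the χ denominator approaches 0.

## Enumeration

Deterministic norms are packed into 20-bit integers — contexts ordered
(G,G), (G,B), (B,G), (B,B); C before D within each assessment rule; segments
P (bits 19–16), R₁ (bits 15–8), R₂ (bits 7–0), most significant bit first.
The bit order is this package's convention (any fixed order works; this one
is documented and round-trip tested). The relabeling symmetry is a bit
permutation plus complement, giving 524,800 orbits over the full space
((2²⁰ + 2¹⁰)/2 by Burnside's count, verified by brute force).

The census counts CESS norms directly in the G-majority (h\* = 1)
orientation — that convention makes the nine family multiplicities sum to
the total — and reports the orbit tally alongside (the two coincide: no norm
is CESS in both orientations). The analytic census specializes the
closed-form conditions to bit logic; the numerical census vectorizes the
finite-error check over id chunks of 2¹⁶ (full space ≈ 2 s on one CPU) and
maps each survivor to its h\* ≥ ½ representative before counting, since the
finite-error check is orientation-blind. The recipient-passive scan is its
own 2¹² space (R₂ pinned to the passive byte), not a filtered full scan.

## Synthetic fixtures

`generate_fixtures` produces seeded random norms: uniform stochastic tables,
uniform deterministic bit patterns, or catalog norms with entrywise uniform
noise ≤ 0.05 ("near-CESS"). These probe the solver and the classifiers
across the whole norm space; they emulate no empirical data — the model has
no data inputs — so passing property tests certifies internal consistency of
the closed forms and oracles, not any fit to observed behavior.

## Known limitations

Private or noisy-channel information, reputation systems with more than two
labels, finite-population evolutionary dynamics (fixation probabilities),
and deviations in assessment rules are outside the model. Stochastic norms
are handled parametrically (sL2, sS1, Generous Scoring, arbitrary tables),
not enumerated. The agent-based oracle is a convergence check, not a
finite-size theory: its finite-N deviations from the mean-field fixed point
are expected and untracked beyond sampling error.
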