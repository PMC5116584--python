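# Methods

## Binding model

The logic layer is threshold-Boolean. Each repressor carries a map of
affinity thresholds (mM): a ligand at or above its threshold allosterically
switches the repressor — releasing it if inducer-regulated, arming it if
anti-inducer-regulated. A site is occupied iff its cognate repressor is
present and in the binding state; a circular template is active iff every
site is free; templates in one reaction are independent, and the system
output is 1 iff any template is active. This reflects the on/off behaviour
observed at fixed working concentrations; graded (Hill-type) occupancy is
deliberately not modelled, because nothing in the quantification pipeline
depends on partial occupancy and the exact Boolean layer is what makes the
gate algebra testable. Repressor stoichiometric excess over template
(≥100×) is assumed throughout and carried only as metadata
(`defaults.REPRESSOR_AMOUNTS_PMOL`, 0.05 pmol template).

Default species and thresholds (`rcalogic.defaults`):

| ligand | working conc. | cognate repressor | cognate threshold | cross-talk |
| --- | --- | --- | --- | --- |
| IPTG | 5 mM | LacI (inducer-reg.) | 0.5 mM | — |
| D-Gal | 5 mM | GalR (inducer-reg.) | 0.5 mM | induces LacI above 10 mM |
| SAM | 1 mM | MetJ (anti-ind.-reg.) | 0.5 mM | arms TrpR above 1.5 mM |
| L-Trp | 1 mM | TrpR (anti-ind.-reg.) | 0.5 mM | — |

The two cross-thresholds sit strictly above the working concentrations, so
the 4×4 ligand×repressor switch matrix is diagonal under working
conditions (orthogonality) while high D-Gal or high SAM reproduce the
observed cross-reactivity qualitatively. Cognate thresholds of 0.5 mM are a
convention: any value below the working concentrations yields identical
Boolean behaviour. IPTG and L-Trp working concentrations are config
defaults (5 mM / 1 mM), chosen in line with the other effectors. MetJ
represses less tightly than the other three repressors; this is encoded as
`leak = 0.15` (fraction of the full polymerase rate escaping a bound MetJ
site) and affects only the kinetics layer, never the Boolean layer.

One open point of the chemistry — whether a repressor sitting on the
primer-binding region blocks priming differently from blocking elongation —
is deliberately collapsed: all bound sites stop the polymerase identically.

## Gate algebra and classification

Truth tables enumerate assignments in canonical binary order with the
first-listed input as most significant bit. Classification canonicalizes
over input permutations (identity tried first), under which the 16
two-input Boolean functions collapse onto the 12 constructed names;
asymmetric gates (ANDN, ORN, YES, NOT) are reported with the matching
permutation instead of as mirror variants. Three-input tables either match
the constructed `A ∧ B ∧ ¬C` pattern up to permutation or are labelled
OTHER.

## Derivation engine

Basic modules are the two-atom formulas `m ∨ ¬r` (ORN) and `¬(m ∧ r)`
(NAND). Derivation searches the closure of substituted modules (atoms →
input variables, ⊤ = held present, ⊥ = never supplied; no nested formula
substitution, mirroring what the chemistry can do) under series-∧ and
parallel-∨, breadth-first in the number of composition operations (default
bound 4; all constructed gates need ≤ 2). Equivalence is checked
exhaustively (≤ 10 atoms). Ties among equally deep derivations break on
(implied template count, enumeration order), so traces are reproducible;
deepening the bound can only add derivations, never lose one.

Note that with ⊤/⊥ substitution the ORN form alone already spans all
Boolean functions (`ORN(⊥, x) = ¬x` gives negation, and literals plus
∧/∨ give full DNF); the practical value of the mixed basis is physical,
not logical — negative literals through ORN modules would demand repressor
proteins as circuit inputs, whereas NAND modules realize them with a
constant repressor and a metabolite input.

`realize_trace` closes the proof/chemistry loop: series steps become
co-located sites, parallel steps separate templates (series over parallel
is distributed, which is exactly the DNF identity), and each distinct
substituted module is assigned a repressor of its kind. Before assignment,
tautological leaves are dropped and pure-negation ORN leaves are rewritten
through the anti-inducer channel, both to match the natural chemistry and
because each mode has only two repressors.

## Compiler

`synthesize` computes Quine–McCluskey prime implicants and an exact
minimum cover (brute force over subsets, trivial at n ≤ 4; equal-cost
covers break ties lexicographically on implicant bit patterns, so designs
are deterministic). Each implicant becomes a template; positive literals
use inducer-regulated channels, negative literals anti-inducer-regulated
ones; each input supplies the metabolites of all channels it uses (the XOR
design's composite inputs fall out of this automatically). A constant-true
target is a site-free template. Constant-false supports two encodings: an
inducer-regulated repressor whose inducer is never supplied (default,
matching the reference NONE construction) or an anti-inducer-regulated
repressor with its metabolite held constant. Inputs in synthesized designs
supply metabolites only; designs where an input adds a repressor protein
(the basic modules, XNOR, NONE) are expressed as manual/catalogue designs,
which the document format fully supports. Every feasible synthesis is
verified by exhaustive truth-table evaluation before being returned, and
infeasibility (more inputs needing a polarity than repressors of that
mode) is reported, naming the missing polarity.

## Kinetic model and quantification

The simulator is the package's synthetic-data generator. Signal model per
condition:

```
F(t) = baseline + R_total · max(0, t − lag) + ε_t,   clipped at plateau
ε_t ~ N(0, noise_sd²) i.i.d.
```

`R_total` sums per-template contributions — `k_full` for an active
template, `k_full · max(leak over occupied sites)` for a blocked one — and
is capped at `k_full · enzyme_capacity` (default 1 template-equivalent).
The cap encodes that the polymerase, not the template pool, is limiting
(3 U phi29 on 0.05 pmol template): one running circle out of two produces
essentially the same rate as two, which is why a parallel OR gate with one
open template still reads 1 after normalization. Defaults: baseline 50
RFU, `k_full` 100 RFU/min, 15 min sampled every 0.5 min, lag 1 min, noise
SD 5 RFU (5% of `k_full`), plateau 2000 RFU (never reached at the
defaults, keeping the linear part clean). These values are synthetic —
chosen once as realistic for a SYBR-green plate-reader RCA run — since no
tabulated real fluorescence curves are available to calibrate against.

Rate estimation scans every contiguous window covering ≥ 40% of samples
and takes the steepest slope whose least-squares R² ≥ 0.9 (ties: longer,
then earlier; if nothing reaches the floor, the best-R² window). Zero
variance counts as a perfect fit so flat curves return slope 0. The
window-spanning rule plus slope maximization automatically excludes the
lag region.

Quantification simulates all 2ⁿ conditions plus an always-included
repressor-free control from one seeded generator, normalizes every slope
by the maximum across conditions and control (negative noise slopes clamp
to 0, so RRR ∈ [0, 1]), and thresholds at 0.5 — strictly above for output
1, so an exact 0.5 conservatively reads 0. The control exists because
all-off gates (NOT, NONE) would otherwise normalize by near-zero noise; it
pins RRR ≈ 1 while every gate condition stays at ≤ leak < 0.5. If no
condition and not even the control has a positive rate the experiment is
flagged degenerate rather than silently normalized.

With the shipped defaults the noise-free pipeline reproduces the Boolean
truth table of every catalogue design exactly, and the largest leak (0.15)
cannot cross the 0.5 threshold whenever any template is fully active.

## Sequence layer

Template builds are linearized at the ligation junction:
`primer-binding region + (6-nt A/T spacer + operator)* + padding`, padded
to the target length (default: next multiple of 10 with ≥ 10 nt headroom)
with deterministic pseudorandom sequence kept at 40–60% GC and regenerated
until it introduces no unintended operator occurrence. The splint is the
reverse complement of the last-10 + first-10 junction nucleotides
(head-to-tail), the primer the reverse complement of the primer-binding
region, and the circular strand is flagged 5′-phosphorylated. Operator
scanning matches each motif and its reverse complement over the doubled
sequence (wrap-around hits included; both orientations because repressor
binding is a double-stranded motif and strand orientation is not
constrained), counts distinct start positions, and subtracts intended
sites; assembly fails rather than return a build with nonzero residual.
The shipped operator motifs (lacO1, gal O_E, trpO, tandem met-box) are
canonical literature placeholders and are marked replaceable; swap in
project-specific sequences via `OperatorDB` or a design document.

## What the synthetic data do and do not show

The generator emulates the *structure* of the experiment — lag, linear
rise, saturation, additive noise, leak-through, polymerase limitation —
not fitted reality: no real curves are tabulated in the source, so
rate constants, noise and leak are not calibrated to measurements. Passing
tests therefore demonstrate that the logic, the quantification pipeline
and the designs are mutually consistent and robust to the modelled noise;
they do not certify quantitative agreement with any particular instrument
run. Enzyme-level stochasticity, secondary structure, ligase fidelity and
melting behaviour are out of scope.

## Problem sizes

The test suite exercises: exhaustive enumeration over ≤ 4 sites × all
species subsets; all 16 two-input syntheses (plus 40 random three-input
tables against a brute-force minimal-DNF oracle and a sympy cross-check);
derivation of all 13 gates with full-basis and restricted-basis closure
oracles; 1000 seeded quantification runs per catalogue design at default
noise; and 200 seeded curves for the slope estimator at 10% noise. The
whole suite runs in well under two minutes on one CPU.
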