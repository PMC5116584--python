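# rcalogic

Boolean logic gates built from allosterically regulated repressors that
gate DNA replication on circular templates — modelled, compiled, derived,
simulated and sequence-designed in silico.

## The system

Rolling circle amplification (RCA) is an isothermal reaction in which a
strand-displacing polymerase (phi29) travels round and round a circular
single-stranded template, producing a long tandem-repeat product that can
be read out in real time with an intercalating dye. Embedding a repressor's
recognition sequence (operator) in the circle makes replication
conditional: a bound repressor stalls the polymerase anywhere on the
circle.

Two kinds of allosteric switches drive the logic:

* **inducer-regulated** repressors (LacI, GalR) bind their operator by
  default and are *released* by their metabolite (IPTG, D-galactose);
* **anti-inducer-regulated** repressors (TrpR, MetJ) bind *only in the
  presence* of their metabolite (L-tryptophan, SAM).

With the metabolite and the repressor as inputs and the RCA rate as
output, a single repressor–operator pair is already a logic module: the
inducer type computes `m ∨ ¬r` (ORN), the anti-inducer type `¬(m ∧ r)`
(NAND). Placing several operators **in series on one circle** takes the
conjunction of the modules (every site must be free); mixing several
circles **in parallel in one reaction** takes the disjunction (any running
circle emits signal). From the four basic modules, series/parallel
composition and substitution build twelve two-input gates (AND, OR, NAND,
NOR, ANDN, ORN, XOR, XNOR, YES, NOT, ALL, NONE) and a three-input gate.

The experimental readout is the **relative RCA rate (RRR)**: the slope of
the linear part of each real-time fluorescence curve, normalized to the
maximum rate in the experiment, binarized at a threshold of 0.5.

## What the package provides

| Module | Purpose |
| --- | --- |
| `rcalogic.core` | species, threshold-Boolean binding rules, template activity |
| `rcalogic.logic` | truth-table evaluation and gate classification |
| `rcalogic.catalogue` | the 17 reference designs (4 basic modules + 13 gates) as data |
| `rcalogic.propcalc` | propositional engine: derive every gate from the four basic modules; realize traces back into chemistry |
| `rcalogic.synthesis` | compile any truth table (n ≤ 4) into a template design via exact minimal covers |
| `rcalogic.kinetics` | seeded fluorescence simulation, slope estimation, RRR quantification |
| `rcalogic.seqdesign` | concrete template/splint/primer sequences, circular operator cross-screening, FASTA |
| `rcalogic.designdoc` / `rcalogic.cli` | YAML design documents and the `rcalogic` command-line tool |

## Worked example

Quantify the XOR design — two circles, `LacI+MetJ` sites and `GalR+TrpR`
sites, all four repressors present, input A = {IPTG, L-Trp}, input
B = {D-Gal, SAM} — at the default noise level:

```text
$ rcalogic quantify --gate XOR --seed 7
condition  raw_slope_rfu_per_min      rrr  output
       00              -1.629221 0.000000       0
       01             101.007710 0.999475       1
       10             101.060748 1.000000       1
       11              16.395390 0.162233       0

 control             100.926325 0.998670       1

empirical truth table:
 A  B  output
 0  0       0
 0  1       1
 1  0       1
 1  1       0
```

With no input both circles are blocked (slope ≈ 0 → RRR 0). A single input
releases one circle, which runs at the full polymerase-limited rate
(RRR ≈ 1). With both inputs the anti-inducers park MetJ and TrpR on the
circles; the residual 16 RFU/min is the MetJ leak (15% of the full rate,
the weakest repressor of the four), safely below the 0.5 threshold. The
repressor-free control pins the normalization. The empirical table is XOR.

The same gate can be *derived* rather than simulated — e.g. for AND:

```text
$ rcalogic derive --gate AND
derivation of table (depth 1):
[0] SUBSTITUTE  ORN1(IPTG, D-Gal)            => (IPTG ∨ ¬D-Gal)
[1] SUBSTITUTE  ORN1(D-Gal, ⊤)               => (D-Gal ∨ ¬⊤)
[2] SERIES_AND  [0] , [1]                    => ((IPTG ∨ ¬D-Gal) ∧ (D-Gal ∨ ¬⊤))
```

`rcalogic derive --all` reports `13/13 derivable`. Other entry points:
`truth-table`, `classify`, `simulate`, `synthesize`, `design-sequence`,
`catalogue` (see `rcalogic --help`).

## Scope

The package models the cell-free logic layer and its quantification. It
does not model transcription, wet-lab protein preparation, thermodynamic
binding constants, or layered (cascaded) circuits. See `docs/methods.md`
for the model's assumptions, parameter choices and limitations.
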