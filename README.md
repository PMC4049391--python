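# capskit

Toolkit for two desk-side procedures used when characterizing families of
near-identical transporter gene variants:

1. **CAPS-style paralog discrimination and quantification.** Paralogous or
   homeologous transcripts that differ by a handful of nucleotides cannot be
   told apart on a gel. If the variants carry a restriction-site
   polymorphism, digesting their RT-PCR amplicons yields characteristic
   band patterns with *diagnostic* bands — fragment lengths produced by
   exactly one variant. `capskit` predicts cut sites and fragment patterns
   from FASTA, finds diagnostic bands, screens an enzyme table for the best
   discriminator, and converts per-lane band densitometry into
   reference-normalized per-variant transcript abundances with pairwise
   t-tests under Bonferroni correction.
2. **Growth-constant (k_G) kinetics.** A yeast double mutant lacking its own
   sulfate transporters grows on sulfate only through a heterologously
   expressed transporter. When uptake limits growth, the exponential growth
   rate as a function of external substrate concentration S follows a
   Michaelis–Menten isotherm,

   rate(S) = k_max · S / (k_G + S),

   and the growth constant k_G — the concentration at half-maximal growth
   rate — approximates the transporter's apparent k_M without radiotracers.
   `capskit` fits A600(t) = A600(t0)·e^(k·t) per curve on an automatically
   selected exponential window, converts k to a growth rate in doubling
   times per hour (rate = k/ln 2), fits the isotherm by weighted nonlinear
   least squares, classifies the transporter as high- or low-affinity, and
   runs the transport-limitation validity checks that justify k_G ≈ k_M.

A seeded synthetic-data module generates paralog sets with controlled
cut-site geometry, mechanistic uptake-limited growth curves, and stained-gel
lane intensities (intensity ∝ molar amount × fragment length), so the whole
pipeline is testable without any sequence downloads or instruments.

## Worked example

Generate the default paralog trio — variant `a` (1968 bp, no ClaI site,
9-bp insertion after the start codon), `b` (1959 bp, one ClaI cut 1752 bp
downstream of the start codon) and `c` (1959 bp, cuts at 1098 and 1752) —
and digest it:

```sh
capskit simulate paralogs --seed 3 --out trio.fa
capskit digest trio.fa --enzyme ClaI --out digest.json
```

The report lists, per variant, cut coordinates and fragments —
`a: [1968]`, `b: [1752, 207]`, `c: [1098, 654, 207]` — and the band table:
1968, 1752, 1098 and 654 bp are diagnostic (each traces back to a single
variant), while the 207 bp band is shared between `b` and `c` and is
therefore useless for quantification in diagnostic mode.

Simulate a growth experiment for a transporter with k_G = 1.74 µM across a
0–100 µM sulfate ladder and re-estimate the constant:

```sh
capskit simulate growth --seed 1 --kg 1.74 --out growth.csv
capskit growthfit growth.csv --out kinetics.json
```

`kinetics.json` reports the rate isotherm and the fit

```
k_G  = 1.734 ± 0.003 µM    k_max = 0.4997 dt⁻¹ h⁻¹    affinity: high
```

i.e. the pipeline recovers the generating constant to 0.3% at 2%
multiplicative OD noise, and a micromolar k_G classifies the transporter
as high-affinity (threshold 100 µM, configurable).

In Python the same pipeline is three calls:

```python
from capskit import simulate, growth

curves = simulate.simulate_growth(simulate.GrowthSimConfig(k_G_true=5.46, seed=1))
isotherm, fit, affinity = growth.estimate_kg(curves)
print(fit.k_G, fit.se_kG, affinity)   # 5.453  0.015  high
```

## Layout

| module                | contents |
| --------------------- | -------- |
| `capskit.restriction` | enzyme/variant types, cut-site scan, digestion, band classification, enzyme screening |
| `capskit.gelquant`    | incidence matrix, lane quantification (diagnostic / least-squares), percent change, group statistics |
| `capskit.growth`      | exponential-phase fitting, rate isotherm, Michaelis–Menten fit, affinity call, transport-limitation checks |
| `capskit.simulate`    | seeded generators: paralog sets, growth curves, gel lanes |
| `capskit.io` / `capskit.cli` | FASTA/CSV/JSON readers and writers; `digest`, `screen`, `quantify`, `growthfit`, `simulate` subcommands |
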