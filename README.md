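# startrac

Allele-specific *CYP2D6* copy-number determination from multiplexed digital
PCR (dPCR).

## The problem

*CYP2D6* metabolizes over a fifth of clinically prescribed drugs, and its
structural variants — whole-gene deletions (\*5), duplications (\*2x2),
multiplications (\*41x3) and *CYP2D6::CYP2D7* hybrid genes (\*36, \*68) —
change the predicted metabolizer phenotype. A plain gene-level copy number
of 3 cannot distinguish \*2x2/\*4 (normal metabolizer, activity score 2.0)
from \*2/\*4x2 (intermediate metabolizer, activity score 1.0): what matters
is *which* star allele is duplicated. Allele-specific CN testing answers
this by quantifying star-allele core variants with multiplexed TaqMan
assays on a microchamber dPCR platform. Each 4-plex combines one
genotyping (GT) target detecting both alleles of a core SNV (FAM/VIC), the
variant-only exon-9 target g.4181C (JUN), and a 2-copy reference gene assay
(RNaseP or *TERT*, ABY).

This package implements the computational core of that workflow for
laboratory scientists and pharmacogenomics tool builders:

* a **forward model** predicting the integer copies every dye channel should
  report for any diplotype configuration, including hybrid silencing
  (CYP2D6-specific assays give no signal from *CYP2D7*-derived regions);
* **Poisson partition quantification** — gating partition amplitudes,
  estimating occupancy and copies/µL with confidence intervals;
* the **CN-calling rule** (valid calls lie within ±0.25 of an integer);
* an **inverse resolver** that enumerates the structural configurations
  consistent with observed calls and names the duplicated allele;
* a **partition-level simulator** of the assays, reproducing DNA-input
  saturation behavior and two SNV-interference artifacts, which stands in
  for instrument data.

## The model

Molecules distribute across *N* ≈ 2×10⁴ partitions of volume *v* Poisson-
randomly. With *n*₋ negative partitions, the occupancy and concentration of
a channel are

    λ̂ = −ln(n₋ / N),        C = λ̂ / v × dilution   [copies/µL]

with a Wilson binomial interval on the negative fraction propagated through
−ln. Calculated CN against the 2-copy reference channel is

    CN = 2 · C_target / C_ref

and an integer call *n* is made iff |CN − *n*| ≤ 0.25 (otherwise NO_CALL,
with the raw value preserved). The forward model counts, per gene copy of
the diplotype, REF/VAR status at each target, zeroing copies whose region
at that target is *CYP2D7*-derived; the resolver inverts it by exhaustive
enumeration of per-copy multiplicities. At high DNA input the negative
partitions vanish, λ̂ is censored at −ln(0.5/N), and calculated CN for
true CN > 2 compresses toward 2 — the copy-number-integrity (CNI) decay
mechanism.

## Worked example

Simulate a 10 ng well of the CN_2851 4-plex for the duplication sample
\*1/\*2x2 and fit the model:

```python
from startrac import StarTracModel

res = StarTracModel.from_simulation("*1/*2x2", plexes=["CN_2851"], seed=42).fit()
print(res.summary())
```

```
StarTRAC results — sample *1/*2x2

Consistent configuration(s): *1/*2x2 [unique]
Copy control (g.4181C): expected 2, observed 2 — pass
Informative plexes used: CN_2851

   plex channel  calculated_cn  call flags
CN_2851 g.2851C           1.01     1
CN_2851 g.2851T           2.05     2
CN_2851 g.4181C           1.96     2
```

One copy of g.2851C (the \*1 haplotype), two copies of the \*2-defining
variant g.2851T and two of g.4181C: \*2 is the duplicated allele, the
resolution is unique, and the g.4181C internal copy-control matches the
configuration's expectation.

The same pipeline is scriptable from the shell:

```bash
startrac simulate sheet.csv --out-dir wells
startrac quantify wells/NA19685_CN_2851.csv --out q.tsv
startrac call q.tsv --out cn.tsv
startrac interpret cn.tsv --candidates '*1,*2' --out report.json
startrac cni-sweep --diplotype '*2x2/*2x2' --out sweep.tsv
startrac fixtures --out-dir fixtures
```

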