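# qpcrkit

A Python toolkit for quantitative PCR (qPCR) data processing: planning
reverse-transcription reactions, fitting relative standard curves with
amplification-efficiency estimates, quantifying relative gene expression by
three established methods, attaching group statistics, and drawing
publication-style figures.

## Who it is for

Bench scientists and bioinformaticians who have a plate of Cq values (one
row per reaction: gene, treatment group, biological/technical replicate)
and want reproducible, scriptable answers to the routine questions of a
qPCR experiment: *How much RNA goes into each RT reaction? Are my primers
efficient? How strongly is my gene induced, and is the change significant?*

## The methods

**Amplification efficiency from a dilution series.** Cq is regressed by
ordinary least squares on log10 of relative template concentration. The
slope gives the per-cycle amplification factor and efficiency:

    A = 10^(-1/slope),    E = (A - 1) x 100 %

A slope of -3.32 (= -1/log10 2) means perfect doubling, E = 100 %.

**Standard-curve quantification.** Each gene's mean Cq (over technical
replicates) is inverse-predicted through its own curve,
`quantity = 10^((Cq - intercept)/slope)`, then divided by the reference
gene's quantity in the same sample. Because each gene uses its own curve,
unequal efficiencies between target and reference are handled naturally.

**2^-ddCt (Livak).** `dCt = Cq_target - Cq_reference` per sample;
`ddCt = dCt - mean(dCt over control-group replicates)` per gene;
`fold change = 2^-ddCt`. Assumes both assays amplify near 2.0x per cycle
(an advisory admissibility report compares fitted efficiencies).

**Efficiency-corrected NRQ with multiple references.** Per gene g and
sample s, `RQ = A_g^(mean Cq - Cq_s)`; the normalization factor is the
geometric mean of the reference genes' RQs in that sample;
`NRQ = RQ / NF`, rescaled so the control group's geometric mean is 1.
With one reference and all A = 2 this reduces exactly to 2^-ddCt.

**Statistics.** Per-replicate expression values are compared with a Welch
t-test (two groups, significance stars) or one-way ANOVA with Tukey HSD
(any number of groups, compact letter display: groups sharing a letter are
not significantly different at alpha).

## Worked example

`examples/03_expression_methods.py` simulates a 4-fold induction of a
target gene (Cq noise 0.15 cycles, 6 biological x 3 technical replicates,
every assay at exactly 2.0x per cycle) and quantifies it all three ways:

```
 standard curve:  mock = 0.949   infected = 3.989
        2^-ddCt:  mock = 1.005   infected = 4.191
      RqPCR/NRQ:  mock = 1.005   infected = 4.224
```

All three recover the simulated 4-fold induction; the spread around 4 is
the sampling noise of 6 replicates at 0.15 cycles of Cq noise.
`examples/04_group_stats_and_plots.py` continues to ANOVA/Tukey output:

```
gene    group  n  mean    sd    se signif_label
 PR1     mock  5 1.004 0.098 0.044            b
 PR1   buffer  5 1.183 0.106 0.047            b
 PR1 elicitor  5 5.908 0.773 0.346            a
```

The two null treatments share letter "b"; the 5-fold-induced group gets
its own letter "a" (Tukey-adjusted p < 1e-8 against both).

The same pipelines are available from a thin CLI
(`qpcrkit rtvol | curve | expr-curve | expr-ddct | expr-rqpcr | simulate`);
see `qpcrkit --help`.

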