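# mmbscan

Detecting and dating ancestral sex-chromosome turnovers from the footprint
of male mutation bias on substitution rates.

## The problem

In most amniotes the male germ line goes through more replication cycles
than the female germ line, so mutation rates are male-biased.  The strength
of the bias is written **α**, the ratio of male to female mutation rate.
Because the Y chromosome spends all of its time in males, autosomes half,
and the X only one third, neutral substitution rates are ordered
Y > A > X whenever α > 1.

A lineage that once carried an X chromosome and later lost it in a
sex-chromosome turnover keeps a permanent record of that history: during
the T million years its sequences were X-linked they accumulated fewer
substitutions than autosomes, and after the turnover they evolved at the
autosomal rate again.  Comparing observed substitution rates against rates
simulated under a grid of retention times T dates the turnover.  The
package is aimed at molecular evolutionists working on sex-chromosome
evolution in squamates, mammals, or any clade with suspected turnovers.

## The model

Miyata's equations relate α to observed rate ratios between chromosome
classes:

    α(Y/X) = 2 / (3X/Y − 1)
    α(Y/A) = 1 / (2A/Y − 1)
    α(X/A) = (4 − 3X/A) / (3X/A − 2)

with the inverse forms X/A = 2(2+α)/(3(1+α)), Y/A = 2α/(1+α),
Y/X = 3α/(2+α).

The pipeline has two arms:

* **α estimation** — X-, Y- and autosomal intron alignments between two
  species are filtered (first introns, exon flanks, ambiguous columns, CpG
  dinucleotides, a >1,000-bp length floor), their Tamura–Nei (TN93)
  distances computed, uncertainty propagated by a double bootstrap over
  introns and sites (1,000 replicates), and α estimated through the three
  Miyata comparisons with replicate-matched 95% CIs.

* **turnover dating** — synonymous-rate trees are built from codon
  alignments (TN93 on doubly four-fold-degenerate third positions, codon
  bootstrap, per-branch median consensus), X-linked cumulative branch
  lengths are corrected by matched autosomal trees, and observed values are
  compared with sequence simulations under scenarios in which the focal
  lineage kept the ancestral X for 0, 10, 20, … Myr.  The retention times
  whose simulated Welch 95% CIs overlap the observed bootstrap CI form the
  inferred interval [T_min, T_max]; loss dates follow as
  system age − T.  A time-calibrated tree is converted to expected
  substitutions with μ = 2.22 × 10⁻⁹ substitutions/site/year, and X-linked
  branches are shortened by 0.0091, 0.0151 or 0.0227 per 10 Myr at
  α = 2.4, 4 or 6 (linear calibration), or by the Miyata-implied deficit
  μ·T·(α−1)/(3(1+α)).

Everything runs on plain-text formats (FASTA, newick, TSV) and is fully
seeded.

## Worked example

The packaged demo generates synthetic data with known truth and runs both
arms end to end:

```bash
mmbscan run-all --demo --seed 1 --n-genes 20 --n-boot 200 --out demo_out
```

prints

```
alpha (Y/X): 6.03 [4.00, 10.65] (truth 6.0)
agamid retention interval: (80.0, 110.0) Myr (truth 80), null compatible: False
outputs in demo_out
```

The first line is the α estimate from the intron arm: 20 genes per
chromosome class were generated under a true α of 6, and the Y/X
comparison recovers 6.03 with a double-bootstrap 95% CI of [4.00, 10.65].
The second line is the dating arm: on a 10-taxon tree whose agamid-like
lineage kept the ancestral X for 80 Myr (α = 4), the overlap scan returns
a retention interval of 80–110 Myr — containing the truth — and rejects
the null scenario in which the lineage never carried the system
("null compatible: False").  `demo_out/` holds the α report, the filter
audit ledger, and the per-scenario scan table as TSV.

Individual stages are available as subcommands (`synth`, `preprocess`,
`distances`, `bootstrap`, `alpha`, `simulate`, `correct`, `scan`) and as
library functions under `mmbscan.*`.

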