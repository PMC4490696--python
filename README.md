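# posrnaseq

Positional RNA-seq analysis: predicting **where in the body a transcript is
expressed** from read counts of *nested* body-fragment samples, by in silico
subtraction.

The motivating system is the flatworm *Macrostomum lignano*, a simultaneous
hermaphrodite whose main organ systems lie in four regions along the
anterior–posterior axis (head, testis, ovary, tail). Cutting worms at one of
three levels yields four pooled RNA-seq samples of strictly nested tissue
composition — A = head, B = head+testis, C = head+testis+ovary, D = whole
worm — so that differencing *adjacent* samples attributes transcripts to the
region each larger fragment adds. The approach needs no genome annotation
and is aimed at prioritising candidate transcripts for in situ hybridisation
and RNAi screens of reproductive organs.

## Method

Counts (possibly fractional expected counts from a multi-mapping-aware
quantifier) are normalised per sample:

    level(t, s) = log2( count(t, s) / total(s) × 100 + 1e-5 )

so a zero count sits at the floor log2(1e−5) ≈ −16.61. Adjacent samples are
differenced (B−A, C−B, D−C) and each difference is coded with one symbol —
`+` if diff > 2, `−` if diff < −2, `0` otherwise (strict inequalities; a
two-fold log2 difference is a four-fold linear change). The resulting
three-symbol *class* maps to an organ-region call:

| class | call |
|---|---|
| `[0,0,0]` | non-differential |
| `[+,0,0]` | testis region |
| `[0,+,0]`, `[+,+,0]` | ovary region (`[+,+,0]` arises from cutting contamination of ovarian tissue into fragment B) |
| `[0,0,+]` | tail region |
| anything else (incl. any `−`) | other — negative differences reflect dilution as fragments grow, not localisation |

The package also ships a generative simulator of the whole experiment
(mass-weighted region mixtures, planted region-specific transcripts,
dilution, cutting contamination, multinomial sampling at fixed library
size) and an evaluator that scores calls against the planted truth, so the
full chain is verifiable without sequencing data.

The core is exposed as scikit-learn style estimators
(`ExpressionNormalizer → AdjacentDifferencer → ProfileCoder`, composed by
`PositionalClassifier`), usable in sklearn pipelines; plain functions
(`classify_all`, `encode_profile`, …) wrap them.

## Worked example

Simulate a 2 000-transcript experiment (5 % of transcripts specific to each
of testis, ovary and tail, 64-fold enrichment, 5 × 10⁶ reads per sample),
classify it and score the recovery:

```sh
posrnaseq demo --out demo_out --seed 17
```

prints (and writes under `demo_out/`):

```
Recovery report
  overall accuracy: 1.0000

  per-region scores:
        testis: sensitivity 1.0000  precision 1.0000
         ovary: sensitivity 1.0000  precision 1.0000
          tail: sensitivity 1.0000  precision 1.0000

  mean adjacent differences by truth label (dilution):
               B-A        C-B        D-C
  ovary     0.000000  13.748238  -0.570916
  tail      0.000000   0.000000  13.936799
  testis   15.151686  -0.466284  -0.570768
  uniform  -1.483015  -0.142932  -0.154776
```

All 300 planted region-specific transcripts are recovered
(sensitivity = precision = 1 for each region); the negative means in the
later comparisons are the dilution effect — relative abundance falls as
fragments add tissue — and stay below the two-fold threshold, so uniform
transcripts remain non-differential.

The same steps are available separately (`posrnaseq simulate`, `classify`,
`evaluate`, `summarize`), including per-comparison thresholds such as
`--threshold-override C-B=1` for a less stringent cut-off at the
contamination-prone testis/ovary level.

From Python:

```python
from posrnaseq import encode_profile, call_region, default_lignano_design

code = encode_profile((5.17, -0.03, -0.39))   # ('+', '0', '0')
call_region(code, default_lignano_design())   # 'testis region'
```

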