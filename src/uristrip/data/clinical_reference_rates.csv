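# Per-analyte concordance of the strip-reading program against automated
# urine analyzers in a 1184-specimen clinical comparison (percent), with
# the albumin screening cross-table counts appended below.
analyte,exact_pct,within1_pct,n
protein,83.1,100,1184
glucose,94.8,100,1184
urobilinogen,86,99.9,1184
bilirubin,72.4,99.4,1184
ketone,98,100,1184
specific gravity,14.4,49.7,1184
occult blood,87.8,97.8,1184
pH,80.7,100,1184
leukocytes,86.6,99.1,1182
nitrite,98.5,100,1184
creatinine,64,98.6,214
albumin,76.2,100,42
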