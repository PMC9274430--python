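# Statistical tests (detected, never scored)
t test
t-test
ANOVA
Mann-Whitney
Wilcoxon
chi-square test
Kruskal-Wallis
log-rank test
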