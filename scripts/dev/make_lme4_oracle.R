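# Regenerates the lme4 reference values frozen in tests/test_reml.py.
# The fixture CSV is produced by the deterministic generator in that test
# (seed 42); run the test once with LMMCBP_DUMP_FIXTURE=1 or adapt the
# snippet there to write scratch/lme4_fixture.csv, then:
#   Rscript scripts/dev/make_lme4_oracle.R scratch/lme4_fixture.csv
args <- commandArgs(trailingOnly = TRUE)
suppressMessages(library(lme4))
df <- read.csv(args[1])
m <- lmer(y ~ pred + freq + (1 | subj) + (1 | word), data = df, REML = TRUE)
s <- summary(m)
print(coef(s), digits = 10)
print(as.data.frame(VarCorr(m)), digits = 10)
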