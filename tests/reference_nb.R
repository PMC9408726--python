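# Independent reference: NB2 GLM with log-population offset via MASS::glm.nb.
# Usage: Rscript reference_nb.R <dir-with-nbdat_*.csv>
# Each CSV holds design columns, a count column `y`, and an offset column `off`.
suppressMessages(library(MASS))
args <- commandArgs(trailingOnly = TRUE)
files <- sort(list.files(args[1], pattern = "^nbdat_.*\\.csv$", full.names = TRUE))
for (f in files) {
  d <- read.csv(f)
  dat <- d[, !(names(d) %in% c("const")), drop = FALSE]
  fit <- glm.nb(y ~ . - off + offset(off), data = dat)
  co <- coef(fit)
  cat(
    basename(f),
    sprintf("aic=%.12g", AIC(fit)),
    sprintf("theta=%.12g", fit$theta),
    paste(names(co), sprintf("%.12g", co), sep = "=", collapse = " "),
    "\n"
  )
}
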