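# Mixed-model fits delegated to lme4. Called as:
#   Rscript glmm.R <mode> <in.csv> <out.csv>
# mode "gamma":  columns replicate, y, season, sex, stage, bird, year
#   full: y ~ season + sex + stage + (1|bird) + (1|year), Gamma(log)
#   null: drops season. Reports the LRT per replicate.
# mode "logexp": columns replicate, survived, exposure, group, re
#   binomial GLMM with the logistic-exposure link, random intercept re.
suppressMessages(library(lme4))

args <- commandArgs(trailingOnly = TRUE)
mode <- args[1]
dat <- read.csv(args[2], stringsAsFactors = TRUE)

# logistic-exposure link (Shaffer-style custom link-glm)
logexp <- function(exposure = 1) {
  linkfun <- function(mu) qlogis(mu^(1 / exposure))
  linkinv <- function(eta) plogis(eta)^exposure
  mu.eta <- function(eta) exposure * plogis(eta)^(exposure - 1) *
    binomial()$mu.eta(eta)
  valideta <- function(eta) TRUE
  structure(list(linkfun = linkfun, linkinv = linkinv, mu.eta = mu.eta,
                 valideta = valideta, name = "logexp"), class = "link-glm")
}

fit_one <- function(d) {
  if (mode == "gamma") {
    full <- suppressMessages(suppressWarnings(glmer(
      y ~ season + sex + stage + (1 | bird) + (1 | year),
      data = d, family = Gamma(link = "log"))))
    null <- suppressMessages(suppressWarnings(glmer(
      y ~ sex + stage + (1 | bird) + (1 | year),
      data = d, family = Gamma(link = "log"))))
  } else if (mode == "logexp") {
    fam <- binomial(logexp(d$exposure))
    full <- suppressMessages(suppressWarnings(glmer(
      survived ~ group + (1 | re), data = d, family = fam)))
    null <- suppressMessages(suppressWarnings(glmer(
      survived ~ 1 + (1 | re), data = d, family = fam)))
  } else {
    stop(paste("unknown mode", mode))
  }
  chisq <- max(0, 2 * (as.numeric(logLik(full)) - as.numeric(logLik(null))))
  df <- attr(logLik(full), "df") - attr(logLik(null), "df")
  conv <- is.null(full@optinfo$conv$lme4$code) &&
    is.null(null@optinfo$conv$lme4$code)
  c(chisq = chisq, df = df, p = pchisq(chisq, df, lower.tail = FALSE),
    converged = as.numeric(conv))
}

reps <- sort(unique(dat$replicate))
res <- t(vapply(reps, function(r) {
  out <- tryCatch(fit_one(droplevels(dat[dat$replicate == r, ])),
                  error = function(e) c(chisq = NA, df = NA, p = NA,
                                        converged = 0))
  out
}, numeric(4)))
res <- data.frame(replicate = reps, res)
write.csv(res, args[3], row.names = FALSE)
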