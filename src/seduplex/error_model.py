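"""Background substitution error rates and their Beta-Binomial distribution.

A non-reference consensus allele in a qualified (non-singleton,
consensus-reaching) UMI family is interpreted as a base substitution error
that happened before or during UMI tagging.  Pooling over all panel sites
with a given reference base gives the panel-wise mean rate of each of the
12 ordered substitution types,

    rate(A>G) = sum_i I(R_i = A) n_i / sum_i I(R_i = A) N_i,

with Wilson binomial confidence intervals.  Site-to-site variation of the
rate is modelled as a Beta(alpha, beta) law, fitted by maximum likelihood
on a Beta-Binomial for the observed counts n_i ~ BetaBin(N_i, alpha, beta)
— a fit on counts handles the many zero-count sites that a direct Beta fit
of per-site rates cannot.  Conservatively, a single profile (in practice
the dominant G>A type) is applied to all substitution types at call time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint

from .panel import BASES
from .simdata import SUBSTITUTION_TYPES


@dataclass
class BetaFit:
    alpha: float
    beta: float
    converged: bool
    status: str = "OK"  # OK | UNDETERMINED

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class ErrorDistribution:
    """Fitted background error model used by the variant caller."""

    #: per substitution type: (rate, ci_low, ci_high, n, N); absent types
    #: (no eligible sites) are simply missing from the mapping
    mean_rate_per_type: dict[str, tuple] = field(default_factory=dict)
    beta_alpha: float = float("nan")
    beta_beta: float = float("nan")
    fit_status: str = "OK"

    @property
    def mean(self) -> float:
        return self.beta_alpha / (self.beta_alpha + self.beta_beta)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta_alpha": self.beta_alpha,
            "beta_beta": self.beta_beta,
            "fit_status": self.fit_status,
            "mean_rate_per_type": {
                k: list(v) for k, v in self.mean_rate_per_type.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ErrorDistribution":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean_rate_per_type={
                k: tuple(v) for k, v in payload["mean_rate_per_type"].items()
            },
            beta_alpha=float(payload["beta_alpha"]),
            beta_beta=float(payload["beta_beta"]),
            fit_status=payload.get("fit_status", "OK"),
        )


def wilson_ci(n: int, N: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= n <= N:
        raise ValueError("need 0 <= n <= N")
    lo, hi = proportion_confint(n, N, alpha=1 - conf, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def panel_error_rates(
    counts: pd.DataFrame, exclude_sites: set[tuple[str, int]] | None = None
) -> dict[str, tuple]:
    """Panel-wise mean rate of each substitution type with Wilson CIs.

    ``counts`` has one row per site with columns ``chrom, pos, ref, N_fam``
    and per-base non-reference family counts ``n_A .. n_T`` (as produced by
    :func:`seduplex.consensus.compute_site_counts`).  Known variant sites
    should be excluded via ``exclude_sites`` so real alleles are not counted
    as errors.  Types with no eligible sites are reported as missing.
    """
    if counts.empty:
        raise ValueError("empty panel counts")
    df = counts
    if exclude_sites:
        mask = ~df.apply(lambda r: (r["chrom"], int(r["pos"])) in exclude_sites, axis=1)
        df = df[mask]
    rates: dict[str, tuple] = {}
    for ref in BASES:
        sub = df[df["ref"] == ref]
        N = int(sub["N_fam"].sum()) if not sub.empty else 0
        if N == 0:
            continue
        for alt in BASES:
            if alt == ref:
                continue
            n = int(sub[f"n_{alt}"].sum())
            lo, hi = wilson_ci(n, N)
            rates[f"{ref}>{alt}"] = (n / N, lo, hi, n, N)
    return rates


def _betabin_negloglik(params: np.ndarray, n: np.ndarray, N: np.ndarray) -> float:
    a, b = np.exp(params)
    ll = (
        special.betaln(n + a, N - n + b)
        - special.betaln(a, b)
        + special.gammaln(N + 1)
        - special.gammaln(n + 1)
        - special.gammaln(N - n + 1)
    )
    return -float(np.sum(ll))


def fit_beta(n: np.ndarray, N: np.ndarray) -> BetaFit:
    """Maximum-likelihood Beta-Binomial fit of per-site error counts.

    Requires at least 20 sites with positive total depth.  When no errors
    were observed at all, the dispersion is unidentifiable: the fit is
    flagged UNDETERMINED and only the pooled (zero) mean is meaningful.
    """
    n = np.asarray(n, dtype=float)
    N = np.asarray(N, dtype=float)
    if len(n) < 20:
        raise ValueError("need at least 20 sites to fit a distribution")
    if N.sum() <= 0:
        raise ValueError("total depth must be positive")
    if n.sum() == 0:
        return BetaFit(alpha=float("nan"), beta=float("nan"), converged=False,
                       status="UNDETERMINED")
    # method-of-moments start around the pooled mean with mild dispersion
    m = max(n.sum() / N.sum(), 1e-12)
    a0 = 1.0
    b0 = a0 * (1.0 - m) / m
    res = optimize.minimize(
        _betabin_negloglik,
        x0=np.log([a0, b0]),
        args=(n, N),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    a, b = np.exp(res.x)
    return BetaFit(alpha=float(a), beta=float(b), converged=bool(res.success))


def build_error_model(
    counts: pd.DataFrame,
    exclude_sites: set[tuple[str, int]] | None = None,
    fit_type: str = "G>A",
) -> ErrorDistribution:
    """Estimate per-type mean rates and fit the Beta profile.

    Only the dominant type (``fit_type``) is fitted and its
    Beta(alpha, beta) profile reused for every substitution type — the
    conservative choice when rarer types lack the depth to be fitted.
    Per-type profiles can be obtained by calling :func:`fit_beta` directly
    on each type's counts.
    """
    rates = panel_error_rates(counts, exclude_sites)
    df = counts
    if exclude_sites:
        mask = ~df.apply(lambda r: (r["chrom"], int(r["pos"])) in exclude_sites, axis=1)
        df = df[mask]
    ref, alt = fit_type.split(">")
    sub = df[df["ref"] == ref]
    if len(sub) >= 20 and sub["N_fam"].sum() > 0:
        fit = fit_beta(sub[f"n_{alt}"].to_numpy(), sub["N_fam"].to_numpy())
    else:
        fit = BetaFit(float("nan"), float("nan"), False, "UNDETERMINED")
    if fit.status == "UNDETERMINED" and fit_type in rates:
        # fall back to the pooled mean with a weakly-dispersed profile
        pooled = rates[fit_type][0]
        if pooled > 0:
            fit = BetaFit(1.0, (1.0 - pooled) / pooled, False, "POOLED")
    return ErrorDistribution(
        mean_rate_per_type=rates,
        beta_alpha=fit.alpha,
        beta_beta=fit.beta,
        fit_status=fit.status,
    )


def end_distance_test(
    artifact_distances: np.ndarray, variant_distances: np.ndarray
) -> float:
    """One-sided Welch t-test p-value for 'artifacts sit nearer the 5' end'.

    Compares the distance from the ligated (UMI-bearing) fragment end for
    suspected artifact substitutions against real variant sites; end-repair
    artifacts concentrate near the end, real variants are uniform.
    """
    a = np.asarray(artifact_distances, dtype=float)
    v = np.asarray(variant_distances, dtype=float)
    if len(a) < 2 or len(v) < 2:
        raise ValueError("both groups need at least two observations")
    t = stats.ttest_ind(a, v, equal_var=False, alternative="less")
    p = float(t.pvalue)
    if np.isnan(p):  # zero variance in both groups
        return 0.5 if np.mean(a) == np.mean(v) else (0.0 if np.mean(a) < np.mean(v) else 1.0)
    return p


def rate_table(em: ErrorDistribution) -> pd.DataFrame:
    """Per-type rate table (TSV-ready) in fixed substitution-type order."""
    rows = []
    for t in SUBSTITUTION_TYPES:
        if t in em.mean_rate_per_type:
            rate, lo, hi, n, N = em.mean_rate_per_type[t]
            rows.append((t, rate, lo, hi, n, N))
        else:
            rows.append((t, np.nan, np.nan, np.nan, 0, 0))
    return pd.DataFrame(rows, columns=["type", "rate", "ci_low", "ci_high", "n", "N"])
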