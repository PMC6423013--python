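"""Duplex-aware log-likelihood-ratio SNV calling.

Variant calling is framed as model selection at each site.  Under the null
M0 every non-reference UMI is a background error: the single-plex alt count
n1 follows a Beta-Binomial(N1, alpha, beta) (site-to-site error-rate
variation), and the duplex alt count n2 a Binomial(N2, e_d) with
e_d = max(mean^2, floor) — a duplex error requires the same substitution
independently on both strands, so the null duplex rate is the squared mean
single-strand rate, floored because end-repair copying violates the
independence.  Under the alternative M1 all non-reference UMIs are real
mutation copies: n1 and n2 are Binomial at the plug-in allele fraction
f = (n1+n2)/(N1+N2).  The natural-log likelihood ratio log L(M1) - log L(M0)
scores the site.

SINGLEPLEX mode reproduces calling without strand information ("treating
all UMIs as single-plex"): each duplex contributes its two strand families,
so counts are remapped N1 <- N1 + 2*N2, n1 <- n1 + 2*n2 before scoring with
the Beta-Binomial null alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import special

from .error_model import ErrorDistribution


@dataclass(frozen=True)
class CallerConfig:
    llr_threshold: float = 6.0
    duplex_error_floor: float = 1e-7
    mode: str = "DUPLEX"  # DUPLEX | SINGLEPLEX
    #: minimum non-reference UMIs (n1 + n2) to call, suppressing single-UMI calls
    min_alt_evidence: int = 2

    def __post_init__(self) -> None:
        if self.llr_threshold <= 0:
            raise ValueError("llr_threshold must be > 0")
        if not 0.0 < self.duplex_error_floor < 1.0:
            raise ValueError("duplex_error_floor must be in (0, 1)")
        if self.mode not in ("DUPLEX", "SINGLEPLEX"):
            raise ValueError("mode must be DUPLEX or SINGLEPLEX")


def _binom_logpmf(n: np.ndarray, N: np.ndarray, p: np.ndarray) -> np.ndarray:
    return (
        special.gammaln(N + 1)
        - special.gammaln(n + 1)
        - special.gammaln(N - n + 1)
        + special.xlogy(n, p)
        + special.xlog1py(N - n, -p)
    )


def _betabin_logpmf(n: np.ndarray, N: np.ndarray, a: float, b: float) -> np.ndarray:
    return (
        special.gammaln(N + 1)
        - special.gammaln(n + 1)
        - special.gammaln(N - n + 1)
        + special.betaln(n + a, N - n + b)
        - special.betaln(a, b)
    )


def llr_scores(
    N1: np.ndarray,
    n1: np.ndarray,
    N2: np.ndarray,
    n2: np.ndarray,
    em: ErrorDistribution,
    cfg: CallerConfig = CallerConfig(),
) -> np.ndarray:
    """Vectorised log-likelihood ratios for arrays of site counts.

    Sites with N1 + N2 = 0 yield NaN (no call possible).
    """
    a, b = em.beta_alpha, em.beta_beta
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("error model has no fitted Beta parameters")
    N1 = np.asarray(N1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if cfg.mode == "SINGLEPLEX":
        N1, n1 = N1 + 2 * N2, n1 + 2 * n2
        N2 = np.zeros_like(N2)
        n2 = np.zeros_like(n2)

    total = N1 + N2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, (n1 + n2) / np.maximum(total, 1), np.nan)
        log_m1 = _binom_logpmf(n1, N1, f) + _binom_logpmf(n2, N2, f)
        e_d = max(em.mean**2, cfg.duplex_error_floor)
        log_m0 = _betabin_logpmf(n1, N1, a, b) + _binom_logpmf(
            n2, N2, np.full_like(N2, e_d)
        )
    llr = log_m1 - log_m0
    return np.where(total > 0, llr, np.nan)


def log_likelihood_ratio(sc, em: ErrorDistribution, cfg: CallerConfig = CallerConfig()) -> float:
    """LLR of a single site; NaN means NO_CALL (no qualified UMIs).

    ``sc`` is any object with attributes N1, n1, N2, n2 (e.g.
    :class:`seduplex.consensus.SiteCounts`).
    """
    return float(
        llr_scores(
            np.array([sc.N1]), np.array([sc.n1]), np.array([sc.N2]), np.array([sc.n2]),
            em, cfg,
        )[0]
    )


def call_variants(
    counts: pd.DataFrame,
    em: ErrorDistribution,
    cfg: CallerConfig = CallerConfig(),
) -> pd.DataFrame:
    """Score every site and flag calls.

    ``counts`` needs columns N1, n1, N2, n2 (plus chrom/pos/ref/alt for VCF
    output).  A site is called when llr >= threshold and the non-reference
    UMI evidence n1 + n2 reaches ``min_alt_evidence``.  Returns the input
    with ``llr``, ``vaf_hat`` and ``called`` columns appended.
    """
    out = counts.copy()
    llr = llr_scores(
        out["N1"].to_numpy(), out["n1"].to_numpy(),
        out["N2"].to_numpy(), out["n2"].to_numpy(), em, cfg,
    )
    total = (out["N1"] + out["N2"]).to_numpy()
    n_alt = (out["n1"] + out["n2"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(total > 0, n_alt / np.maximum(total, 1), np.nan)
    out["llr"] = llr
    out["vaf_hat"] = vaf
    out["called"] = (
        np.nan_to_num(llr, nan=-np.inf) >= cfg.llr_threshold
    ) & (n_alt >= cfg.min_alt_evidence)
    return out


def write_calls_vcf(
    calls: pd.DataFrame,
    contigs: dict[str, int],
    path: str | Path,
    called_only: bool = True,
) -> None:
    """Write calls as VCF 4.2 with LLR/VAF/count INFO fields (1-based)."""
    header = pysam.VariantHeader()
    header.add_line("##source=seduplex-call")
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for line in (
        '##INFO=<ID=LLR,Number=1,Type=Float,Description="Log likelihood ratio">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Estimated allele fraction">',
        '##INFO=<ID=N1,Number=1,Type=Integer,Description="Qualified single-plex UMIs">',
        '##INFO=<ID=AD1,Number=1,Type=Integer,Description="Non-reference single-plex UMIs">',
        '##INFO=<ID=N2,Number=1,Type=Integer,Description="Qualified duplex UMIs">',
        '##INFO=<ID=AD2,Number=1,Type=Integer,Description="Non-reference duplex UMIs">',
    ):
        header.add_line(line)
    rows = calls[calls["called"]] if called_only else calls
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, r in rows.iterrows():
            alt = r["alt"] if isinstance(r["alt"], str) and r["alt"] else "N"
            rec = vcf.new_record(
                contig=r["chrom"], start=int(r["pos"]), stop=int(r["pos"]) + 1,
                alleles=(r["ref"], alt),
            )
            rec.info["LLR"] = float(r["llr"])
            rec.info["VAF"] = float(r["vaf_hat"])
            for k in ("N1", "n1", "N2", "n2"):
                rec.info[{"N1": "N1", "n1": "AD1", "N2": "N2", "n2": "AD2"}[k]] = int(r[k])
            vcf.write(rec)


def roc_sweep(scores: pd.DataFrame, truth_sites: set | None = None) -> pd.DataFrame:
    """Sensitivity and false-positive count as the LLR threshold sweeps.

    ``scores`` needs an ``llr`` column and either an ``is_variant`` boolean
    column or ``truth_sites``, a set of (chrom, pos) keys of true variant
    sites.  Thresholds run over the observed llr values (plus +inf); the FP
    column is non-increasing in the threshold.
    """
    df = scores.copy()
    if "is_variant" in df.columns:
        truth = df["is_variant"].to_numpy(bool)
    else:
        if not truth_sites:
            raise ValueError("empty truth")
        truth = df.apply(
            lambda r: (r["chrom"], int(r["pos"])) in truth_sites, axis=1
        ).to_numpy(bool)
    if truth.sum() == 0:
        raise ValueError("empty truth")
    llr = np.nan_to_num(df["llr"].to_numpy(float), nan=-np.inf)
    order = np.argsort(-llr, kind="stable")
    llr_sorted = llr[order]
    truth_sorted = truth[order]
    tp = np.cumsum(truth_sorted)
    fp = np.cumsum(~truth_sorted)
    # keep the last index of each distinct threshold value
    last = np.flatnonzero(np.diff(llr_sorted, append=-np.inf) != 0)
    rows = [(np.inf, 0.0, 0)] + [
        (llr_sorted[i], tp[i] / truth.sum(), int(fp[i])) for i in last
    ]
    return pd.DataFrame(rows, columns=["threshold", "sensitivity", "fp"])


def sensitivity_at_fp(roc: pd.DataFrame, max_fp: int = 0) -> float:
    """Best sensitivity among operating points with at most ``max_fp`` FPs."""
    ok = roc[roc["fp"] <= max_fp]
    return float(ok["sensitivity"].max()) if not ok.empty else 0.0


def fp_at_sensitivity(roc: pd.DataFrame, min_sensitivity: float) -> int:
    """Fewest false positives among points reaching the target sensitivity."""
    ok = roc[roc["sensitivity"] >= min_sensitivity]
    return int(ok["fp"].min()) if not ok.empty else int(roc["fp"].max())
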