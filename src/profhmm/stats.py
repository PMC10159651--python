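"""Significance statistics: p-values, E-values, and calibration.

MSV and Viterbi null scores are modelled as Gumbel (extreme-value)
distributed; the Forward null score tail is approximated by an
exponential with fixed rate ``lambda = ln 2`` (natural when scores are
measured in bits).  Calibration scores a batch of i.i.d. background
sequences and fits these laws by maximum likelihood.

E-values are the Bonferroni correction ``E = p * Z`` over the effective
number of comparisons Z; both the uncorrected p-value and the E-value
are first-class attributes on every hit and domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .model import HMM, Background, EvalueParams, configure

__all__ = [
    "SignificanceOptions",
    "pvalue_gumbel",
    "pvalue_exp_tail",
    "evalue",
    "fit_gumbel",
    "calibrate",
]

#: Tail mass used to anchor the Forward exponential tail.
FORWARD_TAIL_MASS = 0.04
#: Fixed Forward tail rate for bit-valued scores.
FORWARD_LAMBDA = math.log(2.0)


@dataclass
class SignificanceOptions:
    """Reporting/inclusion thresholds and the comparison count Z.

    ``Z = None`` means "use the number of targets actually searched"
    (or the number of models scanned); an explicit value mirrors
    HMMER's -Z override.  ``cutoff_source`` switches thresholding from
    E-values to the model's curated GA/TC/NC bit-score cutoffs.
    """

    Z: Optional[float] = None
    report_E: float = 10.0
    include_E: float = 0.01
    cutoff_source: str = "none"

    def __post_init__(self) -> None:
        if self.Z is not None and self.Z < 1:
            raise ValueError("Z must be >= 1")
        if self.include_E > self.report_E:
            raise ValueError("include_E must not exceed report_E")
        if self.cutoff_source not in ("none", "GA", "TC", "NC"):
            raise ValueError(f"unknown cutoff source {self.cutoff_source!r}")


def pvalue_gumbel(score_bits: float, mu: float, lam: float) -> float:
    """Gumbel survival function: P(S >= score) under the null.

    Computed through ``expm1`` so the tail stays accurate for high
    scores, where ``exp(-lam * (s - mu))`` underflows the naive form.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = lam * (score_bits - mu)
    p = -math.expm1(-math.exp(-y))
    return min(max(p, 1e-300), 1.0)


def pvalue_exp_tail(score_bits: float, tau: float, lam: float) -> float:
    """Exponential-tail survival: ``exp(-lam (s - tau))`` clipped to 1."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p = math.exp(-lam * (score_bits - tau))
    return min(max(p, 1e-300), 1.0)


def evalue(p: float, Z: float) -> float:
    """Bonferroni correction: expected false hits over Z comparisons."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if Z < 1:
        raise ValueError("Z must be >= 1")
    return p * Z


def fit_gumbel(samples: np.ndarray) -> Tuple[float, float]:
    """Maximum-likelihood Gumbel fit of (mu, lambda).

    lambda solves the standard ML stationarity condition

        1/lambda = mean(x) - sum(x exp(-lambda x)) / sum(exp(-lambda x))

    located numerically to 1e-8; mu then follows in closed form.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 samples to fit")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    sd = float(x.std())
    if sd == 0.0:
        raise ValueError("samples have zero variance (degenerate)")
    mean = float(x.mean())
    xmax = float(x.max())

    def stationarity(lam: float) -> float:
        w = np.exp(-lam * (x - xmax))
        return 1.0 / lam - mean + float((x * w).sum() / w.sum())

    # Moment estimate lambda ~ pi / (sd sqrt 6) brackets the root well.
    lam0 = math.pi / (sd * math.sqrt(6.0))
    lo, hi = lam0 / 10.0, lam0 * 10.0
    flo, fhi = stationarity(lo), stationarity(hi)
    while flo * fhi > 0 and hi < 1e6:
        lo /= 4.0
        hi *= 4.0
        flo, fhi = stationarity(lo), stationarity(hi)
    lam = float(brentq(stationarity, lo, hi, xtol=1e-10, rtol=1e-12))
    w = np.exp(-lam * (x - xmax))
    mu = xmax - math.log(float(w.mean())) / lam
    return mu, lam


def calibrate(
    hmm: HMM,
    background: Optional[Background] = None,
    n: int = 200,
    L: int = 100,
    seed: int = 42,
    attach: bool = True,
) -> EvalueParams:
    """Fit null score distributions by scoring random sequences.

    Scores ``n`` i.i.d. background sequences of length ``L`` with the
    MSV, Viterbi and Forward passes; fits a Gumbel to the first two and
    anchors the Forward exponential tail (rate ln 2) at the empirical
    0.04 upper-tail quantile.  Deterministic given the seed.
    """
    from . import dp
    from .simulate import random_sequences

    if n < 100:
        raise ValueError("calibration needs n >= 100")
    if L < 10:
        raise ValueError("calibration needs L >= 10")
    bg = background or Background.amino()
    profile = configure(hmm, bg, mode="multihit", L=L)
    seqs = random_sequences(n, L, bg, seed, alphabet=hmm.alphabet)

    msv = np.array([dp.msv_score(profile, s) for s in seqs])
    vit = np.array([dp.viterbi(profile, s)[0] for s in seqs])
    fwd = np.array([dp.forward_score(profile, s) for s in seqs])

    msv_mu, msv_lambda = fit_gumbel(msv)
    vit_mu, vit_lambda = fit_gumbel(vit)
    # tau is placed so that pvalue_exp_tail equals the tail mass at the
    # empirical (1 - tail-mass) quantile of the Forward null scores.
    q = float(np.quantile(fwd, 1.0 - FORWARD_TAIL_MASS))
    tau = q + math.log(FORWARD_TAIL_MASS) / FORWARD_LAMBDA

    params = EvalueParams(
        msv_mu=msv_mu, msv_lambda=msv_lambda,
        vit_mu=vit_mu, vit_lambda=vit_lambda,
        fwd_tau=tau, fwd_lambda=FORWARD_LAMBDA,
    )
    if attach:
        hmm.stats = params
    return params
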