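"""Allele frequencies, Hardy–Weinberg tests and detection summaries.

Works from genotype count triples ``(n0, n1, n2)`` — individuals homozygous
reference, heterozygous, homozygous alternate — or from per-sample detection
flags grouped by population.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HWEResult", "allele_frequency", "hwe_test", "hwe_exact_test", "detection_summary"]


@dataclass(frozen=True)
class HWEResult:
    chi_square: float
    df: int
    p_value: float
    expected: tuple[float, float, float]
    method: str = "chi2"


def allele_frequency(counts) -> float:
    """Alternate-allele frequency ``(n1 + 2 n2) / 2N`` from genotype counts."""
    n0, n1, n2 = counts
    total = n0 + n1 + n2
    if total <= 0:
        return float("nan")
    return (n1 + 2 * n2) / (2 * total)


def hwe_test(counts, method: str = "chi2") -> HWEResult:
    """Test genotype counts against Hardy–Weinberg proportions.

    The default is a 1-df chi-square without continuity correction against
    expected counts ``(p²N, 2pqN, q²N)`` with the allele frequency estimated
    from the data; ``method="exact"`` switches to the exact conditional test
    (recommended when an expected count is below 5).  Monomorphic input has
    chi-square 0 and p 1 by convention.
    """
    n0, n1, n2 = (int(c) for c in counts)
    total = n0 + n1 + n2
    if total <= 0:
        raise ValueError("total genotype count must be positive")
    q = allele_frequency(counts)
    p = 1 - q
    expected = (p * p * total, 2 * p * q * total, q * q * total)
    if q in (0.0, 1.0):
        return HWEResult(0.0, 1, 1.0, expected, method)
    if method == "exact":
        return hwe_exact_test(counts)
    chi2 = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip((n0, n1, n2), expected) if exp > 0
    )
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(float(chi2), 1, p_value, expected, "chi2")


def hwe_exact_test(counts) -> HWEResult:
    """Exact Hardy–Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, under the hypergeometric-style distribution of
    heterozygotes given the minor-allele count (Wigginton–Cutler–Abecasis).
    """
    n0, n1, n2 = (int(c) for c in counts)
    total = n0 + n1 + n2
    rare = n1 + 2 * min(n0, n2)
    # distribution of the heterozygote count given the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    for i, h in enumerate(hets):
        r_hom = (rare - h) // 2
        c_hom = total - h - r_hom
        # unnormalised log-probability; h-independent factors drop out below
        logp[i] = h * np.log(2) - gammaln(h + 1) - gammaln(r_hom + 1) - gammaln(c_hom + 1)
    # normalise within the conditional distribution
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_p = probs[np.nonzero(hets == n1)[0][0]]
    p_value = float(np.clip(probs[probs <= obs_p + 1e-12].sum(), 0.0, 1.0))
    q = allele_frequency(counts)
    p = 1 - q
    expected = (p * p * total, 2 * p * q * total, q * q * total)
    chi2 = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip((n0, n1, n2), expected) if exp > 0
    )
    return HWEResult(float(chi2), 1, p_value, expected, "exact")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding half away from zero (matches printed tables)."""
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def detection_summary(flags: pd.DataFrame, descriptions: dict | None = None) -> pd.DataFrame:
    """Per-population detection counts and percentages.

    ``flags`` has one row per sample with columns ``population`` and
    ``detected`` (boolean).  Percentage is ``100·detected/total`` rounded
    half-up to one decimal; an empty population yields NA.
    """
    if flags["population"].isna().any():
        raise ValueError("every sample needs a population label")
    grouped = flags.groupby("population", sort=False)["detected"].agg(["sum", "count"])
    rows = []
    for population, (detected, total) in grouped.iterrows():
        pct = round_half_up(100.0 * detected / total) if total > 0 else float("nan")
        rows.append({
            "population": population,
            "description": (descriptions or {}).get(population, population),
            "detected": int(detected),
            "total": int(total),
            "percentage": pct,
        })
    return pd.DataFrame(rows)
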