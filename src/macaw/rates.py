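"""Mutation-rate estimation from counts, callable sites and generations.

The point estimate is the classical MA-experiment ratio

    mu_hat = sum_i n_i / sum_i (L_i * T_i)

where line *i* contributed ``n_i`` validated mutations over ``L_i``
callable sites and ``T_i`` generations (cell divisions).  Assuming
per-line Poisson mutation counts, ``SE(mu_hat) = sqrt(mu_hat / LT)`` with
``LT = sum_i L_i*T_i``; the normal 95% interval is ``mu_hat +/- 1.96 SE``
truncated at zero, and a log-space interval ``mu_hat * exp(+/- 1.96
SE/mu_hat)`` (delta method on the log scale) is reported alongside, since
the normal interval is anti-conservative at small counts.  An exact
Garwood (chi-square) Poisson interval is available as a robust
alternative, particularly for ``n = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

#: haploid macronuclear genome size used for genome-wide conversions (bp)
DEFAULT_GENOME_SIZE = 104_000_000


@dataclass(frozen=True)
class LineInputs:
    """Rate-estimation inputs for one MA line."""

    line: str
    n: int          # validated mutation count
    L: float        # callable sites
    T: float        # generations (cell divisions)

    def __post_init__(self):
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError("n must be a non-negative integer")
        if self.L <= 0 or self.T <= 0:
            raise ValueError("L and T must be positive")


@dataclass
class RateEstimate:
    """Per-site per-generation rate with uncertainty and conversions."""

    mu_hat: float
    se: float
    ci_normal: tuple[float, float]
    ci_log: tuple[float, float]
    total_n: int
    total_LT: float
    genome_size: int
    genome_wide_rate: float                 # per haploid genome per 1000 generations
    genome_wide_ci: tuple[float, float]

    def report(self) -> str:
        lo_n, hi_n = self.ci_normal
        lo_l, hi_l = self.ci_log
        lo_g, hi_g = self.genome_wide_ci
        return (
            f"mutations             : {self.total_n}\n"
            f"site-generations (LT) : {self.total_LT:.4g}\n"
            f"mu_hat (/site/gen)    : {self.mu_hat:.4g}\n"
            f"SE                    : {self.se:.4g}\n"
            f"95% CI (normal)       : [{lo_n:.4g}, {hi_n:.4g}]\n"
            f"95% CI (log-space)    : [{lo_l:.4g}, {hi_l:.4g}]\n"
            f"genome-wide rate      : {self.genome_wide_rate:.3g} "
            f"/haploid genome/1000 gen (95% CI [{lo_g:.3g}, {hi_g:.3g}])\n"
        )


def estimate_rate(
    inputs: Sequence[LineInputs],
    genome_size: int = DEFAULT_GENOME_SIZE,
    conf: float = 0.95,
) -> RateEstimate:
    """Estimate the per-site per-generation mutation rate across lines."""
    if not inputs:
        raise ValueError("at least one line is required")
    total_n = int(sum(li.n for li in inputs))
    total_LT = float(sum(li.L * li.T for li in inputs))
    mu_hat = total_n / total_LT
    z = norm.ppf(0.5 + conf / 2.0)
    if total_n == 0:
        warnings.warn(
            "no mutations observed: normal/log CIs are degenerate; "
            "consider poisson_exact_ci for honest bounds",
            stacklevel=2,
        )
        se = 0.0
        ci_normal = (0.0, 0.0)
        ci_log = (0.0, 0.0)
    else:
        se = float(np.sqrt(mu_hat / total_LT))
        ci_normal = (max(0.0, mu_hat - z * se), mu_hat + z * se)
        half = z * se / mu_hat
        ci_log = (mu_hat * np.exp(-half), mu_hat * np.exp(half))
    scale = genome_size * 1000.0
    return RateEstimate(
        mu_hat=mu_hat,
        se=se,
        ci_normal=ci_normal,
        ci_log=ci_log,
        total_n=total_n,
        total_LT=total_LT,
        genome_size=int(genome_size),
        genome_wide_rate=mu_hat * scale,
        genome_wide_ci=(ci_normal[0] * scale, ci_normal[1] * scale),
    )


def expected_missed_mutations(
    mu_hat: float,
    noncallable_proportions: Sequence[float],
    generations: Sequence[float],
    genome_size: int = DEFAULT_GENOME_SIZE,
) -> float:
    """Extrapolated mutation count in the genome fraction lacking power.

    If the estimated rate holds in the non-callable portion of each
    line's genome, the expected number of undetected mutations is
    ``mu_hat * sum_i (1 - prop_i) * genome_size * T_i`` where ``prop_i``
    is the callable proportion — pass ``1 - prop_i`` here.
    """
    props = np.asarray(noncallable_proportions, dtype=float)
    gens = np.asarray(generations, dtype=float)
    if np.any((props < 0) | (props > 1)):
        raise ValueError("non-callable proportions must lie in [0, 1]")
    if props.shape != gens.shape:
        raise ValueError("proportions and generations must align")
    return float(mu_hat * np.sum(props * genome_size * gens))


def poisson_exact_ci(total_n: int, total_LT: float,
                     level: float = 0.95) -> tuple[float, float]:
    """Garwood chi-square exact Poisson interval for the rate n/LT."""
    if total_n < 0:
        raise ValueError("total_n must be >= 0")
    alpha = 1.0 - level
    lower = 0.0 if total_n == 0 else chi2.ppf(alpha / 2.0, 2 * total_n) / 2.0
    upper = chi2.ppf(1.0 - alpha / 2.0, 2 * total_n + 2) / 2.0
    return (lower / total_LT, upper / total_LT)


def line_inputs_from_frame(
    df: pd.DataFrame, genome_size: int = DEFAULT_GENOME_SIZE
) -> list[LineInputs]:
    """Build LineInputs from a table with columns line, n, T and L or callable_prop."""
    out = []
    for _, row in df.iterrows():
        if "L" in df.columns and not pd.isna(row.get("L", np.nan)):
            L = float(row["L"])
        else:
            L = float(row["callable_prop"]) * genome_size
        out.append(LineInputs(line=str(row["line"]), n=int(row["n"]),
                              L=L, T=float(row["T"])))
    return out
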