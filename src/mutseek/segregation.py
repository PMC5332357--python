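"""Mendelian segregation analysis.

Goodness-of-fit chi-square tests of observed phenotype counts against a
hypothesized ratio (3:1, 15:1, 9:3:3:1, ...), and F3 progeny-test
inference of the F2 genotype underlying a normal-phenotype plant.

No Yates continuity correction is applied: the uncorrected statistic is
the classical test for Mendelian ratios (for 448:130 vs 3:1,
chi2 = 1.94, P = 0.16; for 1038:318, chi2 = 1.73, P = 0.19 at full
precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float

    @property
    def p_value_2dp(self) -> float:
        """P rounded to two decimals, for comparison with printed values."""
        return round(self.p_value, 2)


def chi_square_ratio_test(
    observed: Sequence[int], ratio: Sequence[float]
) -> SegregationResult:
    """Chi-square goodness of fit of counts against arbitrary positive weights.

    ``expected_i = total * ratio_i / sum(ratio)``; the statistic is
    ``sum((obs - exp)^2 / exp)`` with ``len(observed) - 1`` degrees of
    freedom, no continuity correction.
    """
    obs = [int(o) for o in observed]
    if len(obs) < 2:
        raise ValueError("need at least two phenotype classes")
    if len(obs) != len(ratio):
        raise ValueError("observed and ratio must have the same length")
    if any(o < 0 for o in obs):
        raise ValueError("observed counts must be non-negative")
    total = sum(obs)
    if total <= 0:
        raise ValueError("total count must be positive")
    weights = [float(w) for w in ratio]
    if any(w <= 0 for w in weights):
        raise ValueError("ratio weights must be positive (expected count of 0)")
    wsum = sum(weights)
    expected = tuple(total * w / wsum for w in weights)
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return SegregationResult(
        observed=tuple(obs),
        expected=expected,
        chi2=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
    )


@dataclass(frozen=True)
class ProgenyTestCall:
    """F2 genotype inferred from the segregation of its selfed F3 family."""

    n_normal: int
    n_mutant: int
    genotype: str  # heterozygous / homozygous_wt / undetermined / inconsistent
    misclassification_probability: float | None

    @property
    def family_size(self) -> int:
        return self.n_normal + self.n_mutant


def progeny_test_genotype(n_normal: int, n_mutant: int) -> ProgenyTestCall:
    """Call the F2 genotype of a normal-phenotype plant from its F3 family.

    Any mutant progeny proves the parent heterozygous.  Zero mutants in
    ``n`` progeny calls it homozygous wild type, with misclassification
    probability (3/4)^n — the chance a true heterozygote segregating
    3:1 shows no mutant among n plants.  An all-mutant family is
    impossible for a selfed normal-phenotype F2 and is flagged
    inconsistent; an empty family is undetermined.
    """
    if n_normal < 0 or n_mutant < 0:
        raise ValueError("family counts must be non-negative")
    n = n_normal + n_mutant
    if n == 0:
        return ProgenyTestCall(0, 0, "undetermined", None)
    if n_normal == 0:
        return ProgenyTestCall(n_normal, n_mutant, "inconsistent", None)
    if n_mutant > 0:
        return ProgenyTestCall(n_normal, n_mutant, "heterozygous", None)
    return ProgenyTestCall(
        n_normal, n_mutant, "homozygous_wt", math.pow(0.75, n)
    )
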