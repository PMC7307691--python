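"""Mendelian expectations and inheritance statistics for balancer crosses.

The genotype engine models a Drosophila cross as independent assortment of
chromosome pairs with equal gamete probabilities and no recombination
(balancer chromosomes suppress recombination, and Drosophila males do not
recombine). Homozygous-lethal allele combinations (balancers such as CyO
and TM6) are removed and the class distribution renormalized, which is how
the familiar 50% (binary ubiquitous cross) and 25% (two-step Gal4/UAS
cross) transheterozygote expectations arise.

Observed offspring counts are scored with a pooled inheritance rate plus
Wilson confidence interval, a two-sample pooled-proportion z-test with
optional Benjamini-Hochberg adjustment across comparisons, and penetrance
(phenotype-positive fraction among the target class).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

WILD_TYPE = "+"


def _pair(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class CrossScheme:
    """Two parental genotypes over chromosome pairs, lethal pairs, target class.

    ``parent1``/``parent2`` map chromosome name -> (allele, allele).
    ``lethal`` lists unordered allele pairs that are zygote-lethal on the
    same chromosome (e.g. CyO/CyO). ``target`` is the set of alleles that
    must all be present for an offspring to count as the target class.
    """

    parent1: Mapping[str, tuple[str, str]]
    parent2: Mapping[str, tuple[str, str]]
    lethal: frozenset[tuple[str, str]] = frozenset()
    target: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.parent1) != set(self.parent2):
            raise ValueError("parents must carry the same chromosome set")
        for parent in (self.parent1, self.parent2):
            for chrom, alleles in parent.items():
                if len(alleles) != 2:
                    raise ValueError(f"chromosome {chrom}: need exactly 2 alleles")
        known = {a for p in (self.parent1, self.parent2) for pair in p.values() for a in pair}
        for a, b in self.lethal:
            if a not in known or b not in known:
                raise ValueError(f"lethal pair ({a}, {b}) references unknown alleles")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CrossScheme":
        def parse_parent(p: Mapping) -> dict[str, tuple[str, str]]:
            return {str(chrom): (str(al[0]), str(al[1])) for chrom, al in p.items()}

        return cls(
            parent1=parse_parent(data["parent1"]),
            parent2=parse_parent(data["parent2"]),
            lethal=frozenset(_pair(str(a), str(b)) for a, b in data.get("lethal", [])),
            target=frozenset(str(a) for a in data.get("target", [])),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CrossScheme":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _genotype_label(genotype: Mapping[str, tuple[str, str]]) -> str:
    return "; ".join(f"{chrom}:{a}/{b}" for chrom, (a, b) in sorted(genotype.items()))


@dataclass(frozen=True)
class ExpectedResult:
    fractions: Mapping[str, Fraction]
    target_fraction: Fraction
    n_zygotes: int  # zygote combinations enumerated (4 per chromosome)

    def as_floats(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.fractions.items()}


def expected_fractions(cross: CrossScheme) -> ExpectedResult:
    """Exact offspring class probabilities under independent assortment.

    Each parent transmits either allele of each chromosome pair with equal
    probability; chromosomes assort independently; lethal classes are
    dropped and the remainder renormalized. Probabilities are exact
    rationals and sum to 1.
    """
    chroms = sorted(cross.parent1)
    weights: dict[tuple, Fraction] = {}
    per_chrom = [
        [
            _pair(a1, a2)
            for a1 in cross.parent1[chrom]
            for a2 in cross.parent2[chrom]
        ]
        for chrom in chroms
    ]
    n_comb = 1
    for options in per_chrom:
        n_comb *= len(options)
    unit = Fraction(1, n_comb)
    for combo in itertools.product(*per_chrom):
        weights[combo] = weights.get(combo, Fraction(0)) + unit

    surviving: dict[tuple, Fraction] = {
        combo: w for combo, w in weights.items()
        if not any(pair in cross.lethal for pair in combo)
    }
    if not surviving:
        raise ValueError("every offspring class is lethal under this scheme")
    total = sum(surviving.values())

    fractions: dict[str, Fraction] = {}
    target = Fraction(0)
    for combo, w in surviving.items():
        genotype = dict(zip(chroms, combo))
        label = _genotype_label(genotype)
        prob = w / total
        fractions[label] = fractions.get(label, Fraction(0)) + prob
        alleles = {a for pair in combo for a in pair}
        if cross.target and cross.target <= alleles:
            target += prob
    return ExpectedResult(fractions=fractions, target_fraction=target, n_zygotes=n_comb)


def inheritance_rate(
    counts: pd.DataFrame,
    target_class: str,
    class_col: str = "class",
    count_col: str = "count",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Pooled target-class fraction with a Wilson score interval.

    ``counts`` holds one row per (replicate, class) with non-negative
    integer counts; replicates are pooled before estimation.
    """
    total = int(counts[count_col].sum())
    if total <= 0:
        raise ValueError("total offspring count must be > 0")
    hits = int(counts.loc[counts[class_col] == target_class, count_col].sum())
    lo, hi = proportion_confint(hits, total, alpha=alpha, method="wilson")
    return hits / total, (float(lo), float(hi))


def proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = False
) -> float:
    """Two-sided two-sample z-test on the pooled proportion.

    Continuity correction is off by default. Degenerate comparisons where
    the pooled proportion is 0 or 1 (identical saturated groups) return
    p = 1.0.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be > 0")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    diff = abs(x1 / n1 - x2 / n2)
    if continuity:
        diff = max(0.0, diff - 0.5 * (1 / n1 + 1 / n2))
    z = diff / se
    return float(2 * stats.norm.sf(z))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def penetrance(
    counts: pd.DataFrame,
    phenotype_class: str,
    target_classes: Iterable[str],
    class_col: str = "class",
    count_col: str = "count",
) -> float:
    """Phenotype-positive fraction among target-class individuals.

    ``phenotype_class`` must itself be one of ``target_classes`` (it counts
    the target-class individuals showing the expected phenotype).
    """
    target_classes = set(target_classes)
    if phenotype_class not in target_classes:
        raise ValueError("phenotype_class must be one of the target classes")
    denom = int(counts.loc[counts[class_col].isin(target_classes), count_col].sum())
    if denom <= 0:
        raise ValueError("target-class count must be > 0")
    num = int(counts.loc[counts[class_col] == phenotype_class, count_col].sum())
    return num / denom
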