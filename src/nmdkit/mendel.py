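"""Expected genotype ratios under lethality models and chi-square tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from scipy import stats

__all__ = ["CrossModel", "expected_ratios", "ratio_test"]


def _normalize_genotype(genotype: str) -> str:
    alleles = genotype.split("/")
    if len(alleles) != 2:
        raise ValueError(f"genotype {genotype!r} is not biallelic")
    # canonical order: "+" before "-", otherwise lexicographic
    key = {"+": 0, "-": 1}
    alleles.sort(key=lambda a: (key.get(a, 2), a))
    return "/".join(alleles)


@dataclass
class CrossModel:
    """A single-locus biallelic cross with optional lethal genotypes."""

    parents: tuple[str, str] = ("+/-", "+/-")
    lethal_genotypes: frozenset[str] = frozenset()
    observed_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parents = tuple(_normalize_genotype(p) for p in self.parents)
        self.lethal_genotypes = frozenset(
            _normalize_genotype(g) for g in self.lethal_genotypes
        )
        if any(c < 0 for c in self.observed_counts.values()):
            raise ValueError("observed counts must be non-negative")
        possible = set(punnett(self))
        bad = self.lethal_genotypes - possible
        if bad:
            raise ValueError(f"lethal genotypes not producible: {sorted(bad)}")


def punnett(cross: CrossModel) -> dict[str, float]:
    """Offspring genotype fractions of the cross (pre-lethality)."""
    a_alleles = cross.parents[0].split("/")
    b_alleles = cross.parents[1].split("/")
    out: dict[str, float] = {}
    for a, b in product(a_alleles, b_alleles):
        g = _normalize_genotype(f"{a}/{b}")
        out[g] = out.get(g, 0.0) + 0.25
    return out


def expected_ratios(cross: CrossModel) -> tuple[dict[str, float], dict[str, float]]:
    """(pre-lethality, post-lethality) genotype fractions.

    Post-lethality fractions are renormalized over surviving genotypes.
    """
    pre = punnett(cross)
    survivors = {g: f for g, f in pre.items() if g not in cross.lethal_genotypes}
    total = sum(survivors.values())
    if total == 0:
        raise ValueError("all offspring genotypes are lethal")
    post = {g: f / total for g, f in survivors.items()}
    return pre, post


def ratio_test(
    observed_counts: dict[str, int], expected_fractions: dict[str, float]
) -> dict:
    """Pearson chi-square goodness of fit, df = categories - 1."""
    observed = {_normalize_genotype(g): c for g, c in observed_counts.items()}
    expected = {_normalize_genotype(g): f for g, f in expected_fractions.items()}
    total = sum(observed.values())
    if total <= 0:
        raise ValueError("zero total observed count")
    genotypes = sorted(set(observed) | set(expected))
    obs, exp = [], []
    for g in genotypes:
        o = observed.get(g, 0)
        f = expected.get(g, 0.0)
        if f == 0.0:
            if o > 0:
                raise ValueError(f"nonzero count for genotype {g} with expectation 0")
            continue
        obs.append(o)
        exp.append(f * total)
    chi2, p = stats.chisquare(obs, exp)
    return {"chi2": float(chi2), "p": float(p), "df": len(obs) - 1}
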