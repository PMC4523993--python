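"""One-locus quantitative genetics of genomic imprinting.

A biallelic locus with alleles A1 (frequency ``p``) and A2 (frequency
``q = 1 - p``) has four *ordered* genotypes once the parental origin of each
allele is known: A1A1, A2A1, A1A2 and A2A2, with the maternally inherited
allele written first.  Genotypic values are parameterised by the additive
value ``a``, the conventional dominance effect ``d`` and the imprinting
effect ``i``::

    G(A1A1) =  a
    G(A2A1) =  d + i      (maternal A2, paternal A1)
    G(A1A2) =  d - i      (maternal A1, paternal A2)
    G(A2A2) = -a

Equivalently the two heterozygote values are ``d1 = d - i`` and
``d2 = d + i``.  Under Hardy-Weinberg equilibrium the genetic variance
splits into a Mendelian additive part ``2pq(a + (q-p)d)^2``, an imprinting
part ``2pq i^2`` (also transmissible, hence additive in the breeding-value
sense) and a dominance part ``(2pq d)^2``.

All closed forms here are pure functions of ``(a, d, i, p)`` and are
vectorised: the private ``*_arrays`` kernels accept numpy broadcasting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhasedGenotype",
    "LocusEffects",
    "AlleleFrequency",
    "DesignRow",
    "SubstitutionEffects",
    "VarianceDecomposition",
    "code_genotype",
    "genotypic_value",
    "substitution_effects",
    "variance_decomposition",
    "imprinting_fraction",
    "heritability_surface",
    "write_surface_tsv",
]


class PhasedGenotype(Enum):
    """Ordered genotype of a phased biallelic locus, maternal allele first."""

    A1A1 = "A1A1"
    A2A1 = "A2A1"  # maternal A2, paternal A1
    A1A2 = "A1A2"  # maternal A1, paternal A2
    A2A2 = "A2A2"

    @property
    def maternal(self) -> str:
        return self.value[:2]

    @property
    def paternal(self) -> str:
        return self.value[2:]


@dataclass(frozen=True)
class DesignRow:
    """Additive / dominance / imprinting indicators of one ordered genotype.

    The four rows of the genotype coding matrix are (1,0,0), (0,1,1),
    (0,1,-1) and (-1,0,0) for A1A1, A2A1, A1A2 and A2A2 respectively.  The
    imprinting indicator distinguishes the reciprocal heterozygotes; its
    sign convention (A2A1 -> +1) is arbitrary but must be used consistently:
    flipping it negates the estimated imprinting effect and nothing else.
    """

    i_a: int
    i_d: int
    i_i: int

    def as_array(self) -> np.ndarray:
        return np.array([self.i_a, self.i_d, self.i_i], dtype=float)


_DESIGN = {
    PhasedGenotype.A1A1: DesignRow(1, 0, 0),
    PhasedGenotype.A2A1: DesignRow(0, 1, 1),
    PhasedGenotype.A1A2: DesignRow(0, 1, -1),
    PhasedGenotype.A2A2: DesignRow(-1, 0, 0),
}


@dataclass(frozen=True)
class LocusEffects:
    """Genotypic-value parameters (a, d, i) of one biallelic locus."""

    a: float
    d: float = 0.0
    i: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "d", "i"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"locus effect {name!r} must be finite, got {v}")

    @property
    def d1(self) -> float:
        """Genotypic value of the A1A2 heterozygote (maternal A1)."""
        return self.d - self.i

    @property
    def d2(self) -> float:
        """Genotypic value of the A2A1 heterozygote (maternal A2)."""
        return self.d + self.i


@dataclass(frozen=True)
class AlleleFrequency:
    """Frequency of the A1 allele; ``q = 1 - p`` is derived."""

    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"allele frequency must lie in [0, 1], got {self.p}")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class SubstitutionEffects:
    """Parental allele-substitution effects.

    ``alpha_pat = a + i + (q-p)d`` and ``alpha_mat = a - i + (q-p)d``; their
    mean is the ordinary substitution effect ``alpha`` and their half
    difference recovers the imprinting effect ``i``.
    """

    alpha_pat: float
    alpha_mat: float

    @property
    def alpha(self) -> float:
        return 0.5 * (self.alpha_pat + self.alpha_mat)

    @property
    def imprinting(self) -> float:
        return 0.5 * (self.alpha_pat - self.alpha_mat)


@dataclass(frozen=True)
class VarianceDecomposition:
    """Single-locus variance components under Hardy-Weinberg equilibrium."""

    sigma2_men: float
    sigma2_imp: float
    sigma2_dom: float
    mu_G: float

    @property
    def sigma2_A(self) -> float:
        """Total additive (transmissible) variance, Mendelian + imprinting."""
        return self.sigma2_men + self.sigma2_imp

    @property
    def sigma2_G(self) -> float:
        return self.sigma2_men + self.sigma2_imp + self.sigma2_dom


def code_genotype(g: PhasedGenotype) -> DesignRow:
    """Return the (I_a, I_d, I_i) coding row of an ordered genotype.

    Raises
    ------
    TypeError
        If ``g`` is not a :class:`PhasedGenotype` (e.g. an unphased token);
        parental origin is an input contract of the whole model.
    """
    try:
        return _DESIGN[g]
    except (KeyError, TypeError):
        raise TypeError(
            f"expected a PhasedGenotype (phased, maternal allele first), got {g!r}"
        ) from None


def genotypic_value(effects: LocusEffects, g: PhasedGenotype) -> float:
    """Genotypic value of one ordered genotype.

    Defined as the dot product of the coding row with ``(a, d, i)`` so that
    genotype codes and genotypic values can never disagree.
    """
    row = code_genotype(g)
    return row.i_a * effects.a + row.i_d * effects.d + row.i_i * effects.i


def substitution_effects(
    effects: LocusEffects, freq: AlleleFrequency
) -> SubstitutionEffects:
    """Paternal and maternal allele-substitution effects at HWE."""
    qp = freq.q - freq.p
    base = effects.a + qp * effects.d
    return SubstitutionEffects(alpha_pat=base + effects.i, alpha_mat=base - effects.i)


def _variance_arrays(a, d, i, p):
    """Vectorised variance kernels; broadcasts over all four parameters."""
    a, d, i, p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a, d, i, p))
    )
    q = 1.0 - p
    two_pq = 2.0 * p * q
    men = two_pq * (a + (q - p) * d) ** 2
    imp = two_pq * i**2
    dom = (two_pq * d) ** 2
    # with p = Pr(A1) and G(A1A1) = +a the population mean is
    # a(p - q) + 2pq d; this is the orientation consistent with the
    # variance components above (brute-force four-genotype check).
    mu = a * (p - q) + two_pq * d
    return men, imp, dom, mu


def variance_decomposition(
    effects: LocusEffects, freq: AlleleFrequency
) -> VarianceDecomposition:
    """Decompose the genetic variance of one locus at HWE.

    ``sigma2_men = 2pq(a + (q-p)d)^2``, ``sigma2_imp = 2pq i^2``,
    ``sigma2_dom = (2pq d)^2``; the mean is ``a(p-q) + 2pq d``.
    """
    men, imp, dom, mu = _variance_arrays(effects.a, effects.d, effects.i, freq.p)
    return VarianceDecomposition(
        sigma2_men=float(men), sigma2_imp=float(imp), sigma2_dom=float(dom),
        mu_G=float(mu),
    )


def imprinting_fraction(effects: LocusEffects, freq: AlleleFrequency) -> float:
    """Proportion of the total genetic variance contributed by imprinting.

    Equals ``i^2 / (a^2 + i^2)`` whenever ``d = 0`` (then independent of the
    allele frequency).  Undefined for a monomorphic or effect-free locus.
    """
    dec = variance_decomposition(effects, freq)
    if dec.sigma2_G == 0.0:
        raise ZeroDivisionError(
            "imprinting fraction undefined: total genetic variance is zero "
            f"(a={effects.a}, d={effects.d}, i={effects.i}, p={freq.p})"
        )
    return dec.sigma2_imp / dec.sigma2_G


def heritability_surface(
    a: float,
    d_levels: Sequence[float] | None = None,
    i_grid: Iterable[float] | None = None,
    p_grid: Iterable[float] | None = None,
    sigma2_e: float = 4.0,
) -> pd.DataFrame:
    """Evaluate heritability with and without imprinting on a parameter grid.

    For every combination of dominance level, imprinting effect and allele
    frequency the narrow-sense heritability ignoring imprinting is
    ``h2 = sigma2_men / (sigma2_G + sigma2_e)`` and the version crediting
    the transmissible imprinting variance is
    ``h2e = (sigma2_men + sigma2_imp) / (sigma2_G + sigma2_e)``, so
    ``h2e >= h2`` everywhere with equality iff ``i = 0``.

    Parameters
    ----------
    a
        Additive genotypic value anchoring the grid.
    d_levels
        Dominance effects to sweep; default ``(0, a/4, a/2, a)`` spanning
        no dominance to complete dominance.
    i_grid
        Imprinting effects; default 100 evenly spaced values on ``[0, a]``
        (no imprinting to complete imprinting).
    p_grid
        Allele frequencies; default 0.01 ... 0.99 in steps of 0.01.
    sigma2_e
        Environmental variance (default 4, no genotype-environment
        interaction assumed).

    Returns
    -------
    Long-format DataFrame with columns ``a, d, i, p, sigma2_men,
    sigma2_imp, sigma2_dom, sigma2_G, R2e, h2, h2e``.
    """
    if sigma2_e <= 0:
        raise ValueError(f"sigma2_e must be positive, got {sigma2_e}")
    if d_levels is None:
        d_levels = (0.0, a / 4.0, a / 2.0, a)
    if i_grid is None:
        i_grid = np.linspace(0.0, a, 100)
    if p_grid is None:
        p_grid = np.arange(0.01, 1.0, 0.01)

    d_arr = np.asarray(list(d_levels), dtype=float)
    i_arr = np.asarray(list(i_grid), dtype=float)
    p_arr = np.asarray(list(p_grid), dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p_grid values must lie in [0, 1]")

    dd, ii, pp = np.meshgrid(d_arr, i_arr, p_arr, indexing="ij")
    men, imp, dom, _ = _variance_arrays(a, dd, ii, pp)
    g = men + imp + dom
    denom = g + sigma2_e
    with np.errstate(invalid="ignore", divide="ignore"):
        r2e = np.where(g > 0, imp / g, np.nan)
    out = pd.DataFrame(
        {
            "a": np.full(dd.size, float(a)),
            "d": dd.ravel(),
            "i": ii.ravel(),
            "p": pp.ravel(),
            "sigma2_men": men.ravel(),
            "sigma2_imp": imp.ravel(),
            "sigma2_dom": dom.ravel(),
            "sigma2_G": g.ravel(),
            "R2e": r2e.ravel(),
            "h2": (men / denom).ravel(),
            "h2e": ((men + imp) / denom).ravel(),
        }
    )
    return out


def write_surface_tsv(surface: pd.DataFrame, path) -> None:
    """Write a heritability surface to long-format TSV."""
    surface.to_csv(path, sep="\t", index=False, float_format="%.10g")


def plot_surface(surface: pd.DataFrame, path, value: str = "R2e") -> None:
    """Render one heatmap per dominance level of a surface column to file.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d_levels = sorted(surface["d"].unique())
    fig, axes = plt.subplots(1, len(d_levels), figsize=(4 * len(d_levels), 3.2),
                             squeeze=False)
    for ax, d in zip(axes[0], d_levels):
        sub = surface[surface["d"] == d].pivot_table(
            index="i", columns="p", values=value
        )
        im = ax.imshow(
            sub.values, origin="lower", aspect="auto",
            extent=(sub.columns.min(), sub.columns.max(),
                    sub.index.min(), sub.index.max()),
        )
        ax.set_title(f"d = {d:g}")
        ax.set_xlabel("p")
        ax.set_ylabel("i")
        fig.colorbar(im, ax=ax, label=value)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
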