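"""Synthetic phased-genotype datasets with known truth.

Two generators are provided:

``make_validation_dataset`` / ``make_validation_pair``
    The imprinting-detection validation design: a cohort of unrelated
    individuals genotyped at biallelic loci in linkage equilibrium, allele
    frequencies cycling over {0.05, 0.10, ..., 0.95}.  A subset of loci
    receives standard-normal additive effects; within that subset smaller
    subsets (not mutually exclusive) receive dominance and imprinting
    effects.  Environmental noise is drawn with variance equal to the
    realized variance of the total genotypic values, so broad-sense
    heritability is ~0.5 by construction.  The "Dom" companion dataset
    reuses the same genotypes and effects but zeroes the imprinting effects
    before building phenotypes, for false-discovery checks.

``make_mouse_like``
    A two-generation population emulating an F2 heterogeneous-stock mouse
    study: unrelated founder pairs, full-sib litters, a cage grouping with
    its own variance component, sex and a cage-density covariate as fixed
    effects, a pedigree-correlated polygenic term, and a handful of causal
    markers.  The phenotype is rescaled to a BMI-like mean and variance.

Every generator is deterministic given its spec's ``seed`` and stores truth
tables (per-locus effects, per-individual components) on the returned
:class:`~imprintscan.data.Dataset` so detections and variance estimates can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "SimulationSpec",
    "FamilySpec",
    "DEFAULT_FREQ_GRID",
    "locus_frequencies",
    "simulate_genotypes",
    "assign_effects",
    "genotypic_values",
    "simulate_phenotypes",
    "make_validation_dataset",
    "make_validation_pair",
    "make_mouse_like",
]

#: Allele-frequency grid used by the validation design: 0.05 to 0.95 in
#: steps of 0.05.
DEFAULT_FREQ_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class SimulationSpec:
    """Validation-cohort design (defaults are the reference configuration:
    5,000 unrelated individuals, 500 loci, 100 additive of which 50
    dominance and 10 imprinting)."""

    n_individuals: int = 5000
    n_loci: int = 500
    allele_freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID
    n_additive: int = 100
    n_dominance: int = 50
    n_imprinting: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_additive > self.n_loci:
            raise ValueError("n_additive cannot exceed n_loci")
        if max(self.n_dominance, self.n_imprinting) > self.n_additive:
            raise ValueError(
                "dominance/imprinting loci are drawn from the additive causal "
                f"set: need n_dominance ({self.n_dominance}) and n_imprinting "
                f"({self.n_imprinting}) <= n_additive ({self.n_additive})"
            )
        if not all(0.0 <= f <= 1.0 for f in self.allele_freq_grid):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class FamilySpec:
    """Mouse-like family design, scaled down from the 168-family study to a
    desk-scale default of 40 full-sib families of 10."""

    n_families: int = 40
    sibs_per_family: int = 10
    n_loci: int = 1000
    n_cages: int = 80
    allele_freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID
    cage_variance: float = 0.2
    polygenic_variance: float = 0.3
    residual_variance: float = 0.5
    sex_effect: float = 0.25
    covariate_effect: float = 0.1
    n_additive: int = 10
    n_dominance: int = 5
    n_imprinting: int = 2
    effect_sd: float = 0.15
    target_mean: float = -0.4568
    target_variance: float = 0.0357
    scale_to_target: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cage_variance", "polygenic_variance", "residual_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_additive > self.n_loci:
            raise ValueError("n_additive cannot exceed n_loci")
        if max(self.n_dominance, self.n_imprinting) > self.n_additive:
            raise ValueError("dominance/imprinting counts cannot exceed n_additive")


def locus_frequencies(n_loci: int, grid=DEFAULT_FREQ_GRID) -> np.ndarray:
    """Cycle deterministically through the frequency grid so every
    frequency class is represented."""
    grid = np.asarray(grid, dtype=float)
    return grid[np.arange(n_loci) % len(grid)]


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None):
    """Draw phased genotypes for unrelated individuals at HWE.

    Maternal and paternal alleles are independent Bernoulli(p) per locus
    and loci are independent (linkage equilibrium).  Returns the
    ``(maternal, paternal)`` 0/1 allele matrices, shape
    ``(n_individuals, n_loci)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    freqs = locus_frequencies(spec.n_loci, spec.allele_freq_grid)
    shape = (spec.n_individuals, spec.n_loci)
    maternal = (rng.random(shape) < freqs).astype(np.int8)
    paternal = (rng.random(shape) < freqs).astype(np.int8)
    return maternal, paternal


def assign_effects(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Assign per-locus (a, d, i) effects.

    ``n_additive`` loci are picked uniformly without replacement to carry
    standard-normal additive effects; dominance and imprinting carriers are
    picked (independently, so the subsets may overlap) from within that
    causal set, also with standard-normal effects.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    a = np.zeros(spec.n_loci)
    d = np.zeros(spec.n_loci)
    i = np.zeros(spec.n_loci)
    causal = rng.choice(spec.n_loci, size=spec.n_additive, replace=False)
    a[causal] = rng.standard_normal(spec.n_additive)
    dom = rng.choice(causal, size=spec.n_dominance, replace=False)
    d[dom] = rng.standard_normal(spec.n_dominance)
    imp = rng.choice(causal, size=spec.n_imprinting, replace=False)
    i[imp] = rng.standard_normal(spec.n_imprinting)
    return pd.DataFrame(
        {
            "locus": np.arange(spec.n_loci),
            "a": a,
            "d": d,
            "i": i,
            "causal_additive": np.isin(np.arange(spec.n_loci), causal),
            "causal_dominance": np.isin(np.arange(spec.n_loci), dom),
            "causal_imprinting": np.isin(np.arange(spec.n_loci), imp),
        }
    )


def genotypic_values(
    maternal: np.ndarray,
    paternal: np.ndarray,
    effects: pd.DataFrame,
    include_imprinting: bool = True,
) -> np.ndarray:
    """Total genotypic value per individual, summed over loci.

    Uses the coding identity G = I_a*a + I_d*d + I_i*i per locus; with
    ``include_imprinting=False`` the imprinting terms are dropped (the
    "Dom" configuration).
    """
    m = maternal.astype(float)
    p = paternal.astype(float)
    a = effects["a"].to_numpy()
    d = effects["d"].to_numpy()
    i = effects["i"].to_numpy()
    g = (m + p - 1.0) @ a + (m != p).astype(float) @ d
    if include_imprinting:
        g = g + (p - m) @ i
    return g


def simulate_phenotypes(
    maternal: np.ndarray,
    paternal: np.ndarray,
    effects: pd.DataFrame,
    rng: np.random.Generator,
    include_imprinting: bool = True,
    noise: np.ndarray | None = None,
):
    """Phenotypes for the unrelated cohort: y = G + e.

    ``e`` is normal with zero mean and variance equal to the *realized*
    variance of the genotypic values, giving heritability ~0.5 by
    construction.  ``noise`` may supply pre-drawn standard-normal deviates
    (used to share environmental draws between the Imp/Dom pair); they are
    scaled by the realized SD of G.
    """
    g = genotypic_values(maternal, paternal, effects, include_imprinting)
    if noise is None:
        noise = rng.standard_normal(g.shape[0])
    e = noise * g.std()
    y = g + e
    truth = {
        "effects": effects if include_imprinting else effects.assign(i=0.0),
        "G": g,
        "e": e,
        "sigma2_e": float(g.var()),
    }
    return y, truth


def _validation_parts(spec: SimulationSpec):
    rng = np.random.default_rng(spec.seed)
    maternal, paternal = simulate_genotypes(spec, rng)
    effects = assign_effects(spec, rng)
    noise = rng.standard_normal(spec.n_individuals)
    return maternal, paternal, effects, noise


def _assemble_validation(spec, maternal, paternal, effects, noise, include_imprinting):
    rng = np.random.default_rng(spec.seed)  # unused; phenotype noise is passed in
    y, truth = simulate_phenotypes(
        maternal, paternal, effects, rng,
        include_imprinting=include_imprinting, noise=noise,
    )
    n, m = maternal.shape
    phen = pd.DataFrame({"id": [f"ind{k:05d}" for k in range(n)], "trait": y})
    markers = pd.DataFrame(
        {"marker": [f"m{j:04d}" for j in range(m)],
         "chrom": ["1"] * m,
         "pos": np.arange(1, m + 1, dtype=float)}
    )
    return Dataset(
        maternal=maternal, paternal=paternal, markers=markers,
        phenotypes=phen, covariates=(), pedigree=None, truth=truth,
    )


def make_validation_dataset(
    spec: SimulationSpec = SimulationSpec(), include_imprinting: bool = True
) -> Dataset:
    """Build one validation cohort (``include_imprinting=False`` gives the
    Dom configuration with the same genotypes and additive/dominance
    effects)."""
    parts = _validation_parts(spec)
    return _assemble_validation(spec, *parts, include_imprinting)


def make_validation_pair(spec: SimulationSpec = SimulationSpec()):
    """(Imp, Dom) dataset pair sharing genotypes, effects and environmental
    deviates; they differ only in the imprinting contributions to the
    phenotype (and the noise scale, which tracks each realized Var(G))."""
    parts = _validation_parts(spec)
    return (
        _assemble_validation(spec, *parts, True),
        _assemble_validation(spec, *parts, False),
    )


def make_mouse_like(spec: FamilySpec = FamilySpec()) -> Dataset:
    """Simulate a two-generation full-sib family population.

    Unrelated, non-inbred founder pairs produce full-sib litters; each
    offspring's maternal allele is a random gamete of the dam and the
    paternal one of the sire (loci unlinked).  Only offspring are
    phenotyped:

        y = mu + sex*b_sex + density*b_cov + G + u + c + e

    with polygenic u dropped down the pedigree (Mendelian-sampling variance
    ``sigma2_u / 2``), a cage random effect, and the whole phenotype
    affinely rescaled to the target mean/variance (components in the truth
    table are stored on the rescaled scale, including the rescaled true
    variance components).
    """
    rng = np.random.default_rng(spec.seed)
    n_off = spec.n_families * spec.sibs_per_family
    freqs = locus_frequencies(spec.n_loci, spec.allele_freq_grid)
    m = spec.n_loci

    # Founder genotypes at HWE; offspring by Mendelian transmission.
    def founder_genotypes(n):
        return ((rng.random((n, m)) < freqs).astype(np.int8),
                (rng.random((n, m)) < freqs).astype(np.int8))

    sire_m, sire_p = founder_genotypes(spec.n_families)
    dam_m, dam_p = founder_genotypes(spec.n_families)

    fam = np.repeat(np.arange(spec.n_families), spec.sibs_per_family)
    pick_dam = rng.random((n_off, m)) < 0.5
    pick_sire = rng.random((n_off, m)) < 0.5
    maternal = np.where(pick_dam, dam_m[fam], dam_p[fam]).astype(np.int8)
    paternal = np.where(pick_sire, sire_m[fam], sire_p[fam]).astype(np.int8)

    # Causal marker effects (modest scale; a minority of markers).
    eff_spec = SimulationSpec(
        n_individuals=1, n_loci=m, allele_freq_grid=spec.allele_freq_grid,
        n_additive=spec.n_additive, n_dominance=spec.n_dominance,
        n_imprinting=spec.n_imprinting, seed=spec.seed,
    )
    effects = assign_effects(eff_spec, rng)
    for col in ("a", "d", "i"):
        effects[col] *= spec.effect_sd
    g = genotypic_values(maternal, paternal, effects)

    # Pedigree and polygenic effect.
    sires = [f"F{f:03d}_S" for f in range(spec.n_families)]
    dams = [f"F{f:03d}_D" for f in range(spec.n_families)]
    off_ids = [f"F{f:03d}_O{k:02d}" for f in range(spec.n_families)
               for k in range(spec.sibs_per_family)]
    pedigree = pd.DataFrame(
        {
            "id": sires + dams + off_ids,
            "sire": ["0"] * (2 * spec.n_families) + [sires[f] for f in fam],
            "dam": ["0"] * (2 * spec.n_families) + [dams[f] for f in fam],
            "sex": ["M"] * spec.n_families + ["F"] * spec.n_families
                   + ["?"] * n_off,  # offspring sex filled in below
        }
    )
    su = np.sqrt(spec.polygenic_variance)
    u_sire = rng.standard_normal(spec.n_families) * su
    u_dam = rng.standard_normal(spec.n_families) * su
    mendelian = rng.standard_normal(n_off) * np.sqrt(spec.polygenic_variance / 2.0)
    u = 0.5 * (u_sire[fam] + u_dam[fam]) + mendelian

    # Cages crosscut families; cage density (occupancy) is a fixed covariate.
    cage = rng.integers(0, spec.n_cages, size=n_off)
    cage_eff = rng.standard_normal(spec.n_cages) * np.sqrt(spec.cage_variance)
    c = cage_eff[cage]
    occupancy = np.bincount(cage, minlength=spec.n_cages)[cage].astype(float)
    density = (occupancy - occupancy.mean()) / max(occupancy.std(), 1e-12)

    sex = rng.integers(0, 2, size=n_off)
    fixed = sex * spec.sex_effect + density * spec.covariate_effect
    e = rng.standard_normal(n_off) * np.sqrt(spec.residual_variance)

    mu0 = 0.0
    y_raw = mu0 + fixed + g + u + c + e
    if spec.scale_to_target:
        k = np.sqrt(spec.target_variance / y_raw.var())
        mu = spec.target_mean + k * (mu0 - y_raw.mean())
    else:
        k, mu = 1.0, mu0
    y = mu + k * (fixed + g + u + c + e)

    phen = pd.DataFrame(
        {
            "id": off_ids,
            "trait": y,
            "sex": sex,
            "cage_density": density,
            "cage": [f"cage{x:03d}" for x in cage],
        }
    )
    pedigree.loc[2 * spec.n_families:, "sex"] = ["M" if s else "F" for s in sex]
    markers = pd.DataFrame(
        {
            "marker": [f"m{j:04d}" for j in range(m)],
            # spread markers over 19 autosome-like chromosomes
            "chrom": [str(1 + (j * 19) // m) for j in range(m)],
            "pos": [float(1 + j % ((m // 19) + 1)) for j in range(m)],
        }
    )
    scaled = effects.copy()
    for col in ("a", "d", "i"):
        scaled[col] *= k
    truth = {
        "effects": scaled,
        "raw_effects": effects,
        "scale": float(k),
        "mu": float(mu),
        "components": pd.DataFrame(
            {"id": off_ids, "fixed": k * fixed, "G": k * g, "u": k * u,
             "c": k * c, "e": k * e}
        ),
        "varcomps": {
            "sigma2_u": float(k**2 * spec.polygenic_variance),
            "sigma2_c": float(k**2 * spec.cage_variance),
            "sigma2_e": float(k**2 * spec.residual_variance),
        },
        "fixed_effects": {
            "sex": float(k * spec.sex_effect),
            "cage_density": float(k * spec.covariate_effect),
        },
    }
    return Dataset(
        maternal=maternal, paternal=paternal, markers=markers,
        phenotypes=phen, covariates=("sex", "cage_density"),
        pedigree=pedigree, truth=truth,
    )
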