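"""In-memory dataset container shared by the simulator, models and scan.

A :class:`Dataset` holds phased genotypes for the phenotyped individuals as
two 0/1 allele matrices (1 = allele A1): ``maternal[n, j]`` is the
maternally inherited allele of individual ``n`` at marker ``j`` and
``paternal`` its paternal counterpart.  From these the ordered genotype and
the additive/dominance/imprinting design codes follow directly::

    I_a = maternal + paternal - 1        # 1, 0, 0, -1
    I_d = (maternal != paternal)         # heterozygote indicator
    I_i = paternal - maternal            # +1 for A2A1, -1 for A1A2

The phenotype table carries the trait, fixed-effect covariates and the
cage grouping; the optional pedigree feeds the polygenic relationship
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    maternal: np.ndarray
    paternal: np.ndarray
    markers: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: tuple[str, ...] = ()
    pedigree: pd.DataFrame | None = None
    truth: dict | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        if self.maternal.shape != self.paternal.shape:
            raise ValueError("maternal/paternal allele matrices differ in shape")
        n, m = self.maternal.shape
        if len(self.phenotypes) != n:
            raise ValueError(
                f"{len(self.phenotypes)} phenotype rows for {n} genotyped individuals"
            )
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker rows for {m} marker columns")
        for mat, name in ((self.maternal, "maternal"), (self.paternal, "paternal")):
            bad = ~np.isin(mat, (0, 1))
            if bad.any():
                raise ValueError(f"{name} allele matrix has entries outside {{0, 1}}")
        if "id" in self.phenotypes.columns and self.pedigree is not None:
            known = set(map(str, self.pedigree["id"]))
            orphan = [i for i in map(str, self.phenotypes["id"]) if i not in known]
            if orphan:
                raise ValueError(
                    f"{len(orphan)} phenotyped individuals missing from pedigree, "
                    f"e.g. {orphan[:3]}"
                )

    # -- basic shape -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.maternal.shape[0]

    @property
    def n_markers(self) -> int:
        return self.maternal.shape[1]

    @property
    def ids(self) -> list[str]:
        return [str(x) for x in self.phenotypes["id"]]

    @property
    def has_cage(self) -> bool:
        return "cage" in self.phenotypes.columns

    # -- genetics --------------------------------------------------------
    def design_codes(self, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(I_a, I_d, I_i) columns for marker ``j`` over all individuals."""
        m = self.maternal[:, j].astype(float)
        p = self.paternal[:, j].astype(float)
        return m + p - 1.0, (m != p).astype(float), p - m

    def allele_frequency(self, j: int | None = None) -> float | np.ndarray:
        """Maximum-likelihood frequency of allele A1 (allele count / 2n)."""
        counts = self.maternal + self.paternal  # per-individual A1 dosage
        if j is None:
            return counts.mean(axis=0) / 2.0
        return float(counts[:, j].mean() / 2.0)

    def haplotype_matrix(self, marker_idx=None) -> np.ndarray:
        """Stacked (2n, m) haplotype allele matrix for LD computation."""
        mat = np.vstack([self.maternal, self.paternal]).astype(float)
        if marker_idx is not None:
            mat = mat[:, np.asarray(marker_idx)]
        return mat

    def subset_markers(self, marker_idx) -> "Dataset":
        """New dataset restricted to the given marker indices."""
        idx = np.asarray(marker_idx)
        return Dataset(
            maternal=self.maternal[:, idx],
            paternal=self.paternal[:, idx],
            markers=self.markers.iloc[idx].reset_index(drop=True),
            phenotypes=self.phenotypes,
            covariates=self.covariates,
            pedigree=self.pedigree,
            truth=self.truth,
        )
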