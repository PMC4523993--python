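"""File formats, configuration and the end-to-end pipeline.

Native text dialects (all plain, tab/comma separated):

* genotype TSV — one row per marker with columns ``marker, chrom, pos``
  followed by one column per individual holding a phased token
  ``A1|A2`` (maternal allele written first, ``|`` = phased).  An unphased
  separator (``/``) or an unknown allele code is a hard error naming the
  marker and individual, because parental origin is an input contract.
* phenotype CSV — ``id, trait`` plus covariate columns and an optional
  ``cage`` grouping column.
* pedigree CSV — ``id, sire, dam[, sex]`` with ``0``/empty meaning an
  unknown parent.
* truth TSV — the simulator's per-locus effect table.

Phased VCF input is supported through cyvcf2 (optional dependency): the
``GT`` field must be phased and the configuration declares which haplotype
is maternal; the REF allele maps to A1.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome_scan as scan_mod
from .data import Dataset

__all__ = [
    "RunConfig",
    "PipelineError",
    "write_genotypes",
    "read_phased_genotypes",
    "read_phased_genotypes_vcf",
    "write_dataset",
    "read_dataset",
    "read_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_ALLELES = {"A1", "A2"}


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; thresholds default to the
    standard analysis settings (MAF 0.05, genome-wide alpha 0.05,
    LD-pruning r^2 0.99)."""

    genotypes: str = ""
    phenotypes: str = ""
    pedigree: str | None = None
    out_dir: str = "results"
    maf_threshold: float = 0.05
    alpha: float = 0.05
    r2_threshold: float = 0.99
    use_model9: bool = False
    paper_mode: bool = False
    meff_method: str = "liji"
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (the output location does
        not change what is computed)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def _tokens(dataset: Dataset) -> np.ndarray:
    lut = np.array([["A2", "A1"]])
    mat = lut[0][dataset.maternal]
    pat = lut[0][dataset.paternal]
    return np.char.add(np.char.add(mat, "|"), pat)


def write_genotypes(dataset: Dataset, path) -> None:
    """Write the phased genotype table in the native TSV dialect."""
    tok = _tokens(dataset)  # (n, m)
    df = pd.DataFrame(tok.T, columns=dataset.ids)
    out = pd.concat(
        [dataset.markers[["marker", "chrom", "pos"]].reset_index(drop=True), df],
        axis=1,
    )
    out.to_csv(path, sep="\t", index=False)


def read_phased_genotypes(path):
    """Read the native genotype TSV; returns (maternal, paternal, markers,
    individual ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["marker", "chrom", "pos"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"genotype file {path} lacks column {c!r}")
    ids = [c for c in df.columns if c not in meta_cols]
    markers = df[meta_cols].copy()
    markers["pos"] = markers["pos"].astype(float)
    n, m = len(ids), len(df)
    maternal = np.zeros((n, m), dtype=np.int8)
    paternal = np.zeros((n, m), dtype=np.int8)
    for k, ind in enumerate(ids):
        col = df[ind].to_numpy()
        for j, tok in enumerate(col):
            tok = str(tok)
            if "|" not in tok:
                raise ValueError(
                    f"unphased or malformed genotype {tok!r} for individual "
                    f"{ind!r} at marker {markers['marker'].iloc[j]!r} "
                    "(phased 'A1|A2' tokens required)"
                )
            mat, _, pat = tok.partition("|")
            if mat not in _ALLELES or pat not in _ALLELES:
                raise ValueError(
                    f"unknown allele code in {tok!r} for individual {ind!r} "
                    f"at marker {markers['marker'].iloc[j]!r}"
                )
            maternal[k, j] = mat == "A1"
            paternal[k, j] = pat == "A1"
    return maternal, paternal, markers, ids


def read_phased_genotypes_vcf(path, maternal_first: bool = True):
    """Read phased genotypes from a VCF (REF allele mapped to A1).

    ``maternal_first`` declares the haplotype convention of the file: when
    True the first haplotype of each phased GT is the maternal one.
    Unphased genotypes are a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    mrows, prows, meta = [], [], []
    for var in vcf:
        gts = np.asarray(var.genotypes)  # (n, 3): hap0, hap1, phased flag
        if not np.all(gts[:, 2]):
            bad = ids[int(np.flatnonzero(~gts[:, 2].astype(bool))[0])]
            raise ValueError(
                f"unphased genotype for individual {bad!r} at "
                f"{var.ID or var.POS}; phased input required"
            )
        if np.any(gts[:, :2] < 0):
            raise ValueError(f"missing allele at {var.ID or var.POS}")
        first, second = gts[:, 0], gts[:, 1]
        mat, pat = (first, second) if maternal_first else (second, first)
        # REF (code 0) is allele A1
        mrows.append((mat == 0).astype(np.int8))
        prows.append((pat == 0).astype(np.int8))
        meta.append({"marker": var.ID or f"{var.CHROM}:{var.POS}",
                     "chrom": str(var.CHROM), "pos": float(var.POS)})
    markers = pd.DataFrame(meta)
    return (np.array(mrows).T.copy(), np.array(prows).T.copy(), markers, ids)


# ----------------------------------------------------------------------
# whole datasets
# ----------------------------------------------------------------------

def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write genotypes/phenotypes/pedigree/truth files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"genotypes": out / "genotypes.tsv",
             "phenotypes": out / "phenotypes.csv"}
    write_genotypes(dataset, paths["genotypes"])
    dataset.phenotypes.to_csv(paths["phenotypes"], index=False)
    if dataset.pedigree is not None:
        paths["pedigree"] = out / "pedigree.csv"
        dataset.pedigree.to_csv(paths["pedigree"], index=False)
    if dataset.truth is not None and "effects" in dataset.truth:
        paths["truth"] = out / "truth_effects.tsv"
        dataset.truth["effects"].to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_dataset(genotypes, phenotypes, pedigree=None) -> Dataset:
    """Assemble a Dataset from the native files.

    Phenotype rows are aligned to the genotype columns by individual id;
    covariates are all phenotype columns other than id/trait/cage.
    """
    if str(genotypes).endswith(".vcf") or str(genotypes).endswith(".vcf.gz"):
        maternal, paternal, markers, ids = read_phased_genotypes_vcf(genotypes)
    else:
        maternal, paternal, markers, ids = read_phased_genotypes(genotypes)
    phen = pd.read_csv(phenotypes)
    phen["id"] = phen["id"].astype(str)
    phen = phen.set_index("id").reindex(ids).reset_index()
    if phen["trait"].isna().all():
        raise ValueError("no phenotype rows match the genotyped individuals")
    covariates = tuple(c for c in phen.columns
                       if c not in ("id", "trait", "cage"))
    ped = None
    if pedigree is not None:
        ped = pd.read_csv(pedigree, dtype=str)
    return Dataset(maternal=maternal, paternal=paternal, markers=markers,
                   phenotypes=phen, covariates=covariates, pedigree=ped)


# ----------------------------------------------------------------------
# config + pipeline
# ----------------------------------------------------------------------

def read_config(path) -> RunConfig:
    """Read a plain key-value (YAML) config file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Run filter -> null fit -> scan -> prune -> boxes -> marked variance
    -> heritability, writing results TSV, report JSON and a stage log.

    ``dataset`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from the configured paths.  Every output embeds
    the config hash and seed.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if dataset is None:
            dataset = read_dataset(config.genotypes, config.phenotypes,
                                   config.pedigree)
        stage = "maf_filter"
        kept = scan_mod.maf_filter(dataset, config.maf_threshold)
        if kept.size == 0:
            raise PipelineError(stage, "no markers left after the MAF filter")
        stage = "scan"
        cfg = scan_mod.ScanConfig(
            maf_threshold=config.maf_threshold, alpha=config.alpha,
            r2_threshold=config.r2_threshold, use_model9=config.use_model9,
            paper_mode=config.paper_mode, meff_method=config.meff_method,
        )
        results, info = scan_mod.scan(dataset, cfg, marker_idx=kept)
        stage = "prune"
        results = scan_mod.prune_clusters(results, dataset, config.r2_threshold)
        stage = "report"
        report = scan_mod.build_report(results, info)
        report["config_hash"] = config.config_hash()
        report["seed"] = config.seed
        report["stage_counts"] = {
            "markers_input": dataset.n_markers,
            "markers_after_maf": int(kept.size),
            "significant_imprinting": info["n_box1"],
            "significant_additive": info["n_box2"],
            "retained_after_pruning": int(results["retained"].sum()),
        }
        stage = "write"
        results.insert(0, "config_hash", config.config_hash())
        results.insert(1, "seed", config.seed)
        results_path = out / "results.tsv"
        results.to_csv(results_path, sep="\t", index=False, float_format="%.10g")
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "pipeline.log", "w") as fh:
            for k, v in report["stage_counts"].items():
                fh.write(f"{k}\t{v}\n")
            fh.write(f"config_hash\t{config.config_hash()}\n")
            fh.write(f"seed\t{config.seed}\n")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named re-raise
        raise PipelineError(stage, str(exc)) from exc
    logger.info("pipeline finished; results in %s", out)
    return report
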