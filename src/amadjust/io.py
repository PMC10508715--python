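"""File formats and run configuration.

Interchange is deliberately plain text:

* **weight tables** — PLINK-score-style TSV with columns SNP, CHR, A1 (effect
  allele) and one ``WEIGHT_<trait>`` column per trait;
* **genotypes** — an additive-dosage TSV (rows = individuals, first column
  IID, remaining columns = per-SNP counts of the mapped allele) plus a
  companion SNP map TSV with columns SNP, CHR, A1;
* **GWAS tables** — TSV with the columns produced by
  :func:`amadjust.gwas.run_gwas`;
* **run configuration** — a single YAML file.

SNPs are identified by opaque string ids plus integer chromosome labels; no
base-pair positions are needed because the method only uses chromosome
membership.  When a weight table's effect allele disagrees with the genotype
file's counted allele, the count is flipped to ``2 - x`` before scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gwas import default_snp_ids
from .pgi import ChromScoreMatrix
from .sim import PopulationState

__all__ = [
    "SchemaError",
    "build_weight_table",
    "read_weight_table",
    "write_weight_table",
    "weight_columns",
    "write_genotypes",
    "read_genotypes",
    "aligned_weights",
    "scores_from_tables",
    "write_gwas_table",
    "read_gwas_table",
    "RunConfig",
]


class SchemaError(ValueError):
    """A file does not match the expected tabular schema."""


# -- weight tables -----------------------------------------------------------

_WEIGHT_FIXED = ["SNP", "CHR", "A1"]


def build_weight_table(
    snp_ids, chrom, weights: dict[str, np.ndarray], a1: str | list = "A"
) -> pd.DataFrame:
    """Assemble a weight table; ``weights`` maps trait name -> weight vector."""
    if isinstance(a1, str):
        a1 = [a1] * len(snp_ids)
    df = pd.DataFrame({"SNP": list(snp_ids), "CHR": np.asarray(chrom, int), "A1": list(a1)})
    for trait, w in weights.items():
        df[f"WEIGHT_{trait}"] = np.asarray(w, float)
    return df


def write_weight_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def weight_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("WEIGHT_")]


def read_weight_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str})
    missing = [c for c in _WEIGHT_FIXED if c not in df.columns]
    if missing:
        raise SchemaError(f"weight table {path} is missing columns {missing}")
    wcols = weight_columns(df)
    if not wcols:
        raise SchemaError(f"weight table {path} has no WEIGHT_* column")
    if df["SNP"].duplicated().any():
        dups = df.loc[df["SNP"].duplicated(), "SNP"].head().tolist()
        raise SchemaError(f"weight table {path} has duplicate SNP ids, e.g. {dups}")
    for c in wcols:
        if not np.issubdtype(df[c].dtype, np.number) or df[c].isna().any():
            raise SchemaError(f"weight column {c} in {path} is not fully numeric")
    df["CHR"] = df["CHR"].astype(int)
    return df


# -- genotypes ---------------------------------------------------------------


def write_genotypes(
    geno_path,
    map_path,
    pop: PopulationState,
    snp_ids=None,
    a1: str | list = "A",
    iids=None,
) -> None:
    """Export a population as a dosage TSV plus a SNP map TSV."""
    if snp_ids is None:
        snp_ids = default_snp_ids(pop.n_snps)
    if iids is None:
        iids = [f"ind{i + 1}" for i in range(pop.n_individuals)]
    geno = pd.DataFrame(pop.genotypes, columns=list(snp_ids))
    geno.insert(0, "IID", list(iids))
    geno.to_csv(geno_path, sep="\t", index=False)
    if isinstance(a1, str):
        a1 = [a1] * pop.n_snps
    pd.DataFrame(
        {"SNP": list(snp_ids), "CHR": np.asarray(pop.chrom_of_snp, int), "A1": list(a1)}
    ).to_csv(map_path, sep="\t", index=False)


def read_genotypes(geno_path, map_path) -> tuple[PopulationState, pd.DataFrame]:
    """Load a dosage TSV + SNP map into a population.

    Validates that every dosage is an integer 0/1/2 (errors name the offending
    individual and SNP) and that the SNP sets of the two files coincide.
    Returns ``(population, snp_map)`` with genotype columns ordered as in the
    map.  Sexes are not stored in the format; an alternating assignment is
    used as a placeholder (the adjustment estimators never use sex).
    """
    geno = pd.read_csv(geno_path, sep="\t")
    if "IID" not in geno.columns:
        raise SchemaError(f"genotype file {geno_path} lacks an IID column")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"SNP": str, "A1": str})
    missing = [c for c in ("SNP", "CHR") if c not in snp_map.columns]
    if missing:
        raise SchemaError(f"SNP map {map_path} is missing columns {missing}")
    snp_map["CHR"] = snp_map["CHR"].astype(int)

    geno_snps = [c for c in geno.columns if c != "IID"]
    orphans = sorted(set(geno_snps) - set(snp_map["SNP"]))
    if orphans:
        raise SchemaError(f"SNPs present in genotypes but absent from the map: {orphans[:10]}")
    absent = sorted(set(snp_map["SNP"]) - set(geno_snps))
    if absent:
        raise SchemaError(f"SNPs present in the map but absent from genotypes: {absent[:10]}")

    ordered = list(snp_map["SNP"])
    mat = geno[ordered].to_numpy()
    bad = ~np.isin(mat, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SchemaError(
            f"invalid dosage {mat[i, j]!r} for individual {geno['IID'].iloc[i]!r}, "
            f"SNP {ordered[j]!r} (dosages must be 0, 1 or 2)"
        )
    n = mat.shape[0]
    if n % 2:
        raise SchemaError("number of individuals must be even")
    sex = np.arange(n) % 2 == 0
    pop = PopulationState(
        genotypes=mat.astype(np.int8),
        chrom_of_snp=snp_map["CHR"].to_numpy(),
        sex=sex,
        generation=1,
    )
    return pop, snp_map


def aligned_weights(snp_map: pd.DataFrame, weight_df: pd.DataFrame, trait: str) -> np.ndarray:
    """Weight vector for ``trait`` aligned to the SNP-map order (zero for SNPs
    absent from the weight table)."""
    col = f"WEIGHT_{trait}"
    if col not in weight_df.columns:
        raise SchemaError(f"weight table has no column {col}")
    wtab = weight_df.set_index("SNP")
    snp_ids = snp_map["SNP"].to_numpy()
    in_tab = np.array([s in wtab.index for s in snp_ids])
    w = np.zeros(len(snp_ids))
    w[in_tab] = wtab.loc[snp_ids[in_tab], col].to_numpy(float)
    return w


def scores_from_tables(
    pop: PopulationState, snp_map: pd.DataFrame, weight_df: pd.DataFrame, trait: str
) -> ChromScoreMatrix:
    """Chromosome-specific scores for user data, handling allele flips.

    Weights are aligned to the SNP map by id; SNPs where the weight table's
    effect allele differs from the genotype file's counted allele score on
    ``2 - x`` instead of ``x``.  SNPs absent from the weight table get weight
    zero.
    """
    col = f"WEIGHT_{trait}"
    if col not in weight_df.columns:
        raise SchemaError(f"weight table has no column {col}")
    wtab = weight_df.set_index("SNP")
    snp_ids = snp_map["SNP"].to_numpy()
    in_tab = np.array([s in wtab.index for s in snp_ids])
    w = np.zeros(len(snp_ids))
    w[in_tab] = wtab.loc[snp_ids[in_tab], col].to_numpy(float)

    geno_a1 = (
        snp_map["A1"].to_numpy(str)
        if "A1" in snp_map.columns
        else np.full(len(snp_ids), "A")
    )
    flip = np.zeros(len(snp_ids), bool)
    if "A1" in wtab.columns:
        flip[in_tab] = wtab.loc[snp_ids[in_tab], "A1"].to_numpy(str) != geno_a1[in_tab]

    from .sim import _block_weight_matrix

    x = pop.genotypes.astype(np.float64)
    if flip.any():
        x[:, flip] = 2.0 - x[:, flip]
    chroms = np.unique(pop.chrom_of_snp)
    scores = x @ _block_weight_matrix(pop.chrom_of_snp, w)
    return ChromScoreMatrix(scores=scores, chroms=chroms, trait=trait)


# -- GWAS tables -------------------------------------------------------------


def write_gwas_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gwas_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    required = ["SNP", "BETA"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"GWAS table {path} is missing columns {missing}")
    if "VALID" not in df.columns:
        df["VALID"] = True
    return df


# -- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """Every knob of a simulation-plus-analysis run, serializable to YAML.

    Two runs with identical configs produce byte-identical outputs.
    """

    n_individuals: int = 10_000
    n_snps: int = 2_000
    n_chrom: int = 20
    allele_freq: float = 0.5
    pleiotropy_mode: str = "full"
    effect_correlation: float = 0.5
    partial_fraction: float = 0.5
    h2_z: float = 1.0
    h2_y: float = 1.0
    causal_effect: float = 0.0
    sorting: str = "random"
    match_noise: float = 0.0
    generations: int = 4
    phi_grid: list = field(default_factory=lambda: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    n_replicates: int = 20
    n_boot: int = 100
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
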