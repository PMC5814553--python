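"""Delimited-text readers and writers, and the run configuration.

All tabular artifacts are plain tab-separated text so runs can be diffed;
writers can prepend ``#`` comment headers carrying the run's seed and
config hash, and readers skip them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, RelationshipMatrix

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_vcf_genotypes",
    "read_relationship",
    "write_relationship",
    "read_plot_table",
    "write_table",
    "read_adjusted_means",
]

_SEP = "\t"


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, *, meta: dict | None = None,
                index: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep=_SEP, index=index)


def write_genotypes(g: GenotypeMatrix, path, *, meta: dict | None = None) -> None:
    df = pd.DataFrame(g.dosages, index=pd.Index(g.genotype_ids, name="genotype"),
                      columns=g.marker_ids)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep=_SEP, na_rep="NA")


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read dosages from a delimited matrix file or (optionally) a VCF.

    Matrix dialect: header row of marker ids, first column of genotype
    ids, dosages 0/1/2 with NA for missing.  ``format='auto'`` picks VCF
    for ``.vcf``/``.vcf.gz`` suffixes.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "matrix"
    if format == "vcf":
        return read_vcf_genotypes(path)
    if format != "matrix":
        raise ValueError(f"unknown genotype format {format!r}")
    df = pd.read_csv(path, sep=_SEP, index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genotype ids in {path}: {dup}")
    return GenotypeMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)),
                          list(df.columns.astype(str)))


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Convert VCF GT fields to alternate-allele dosages (missing/half-calls -> NaN)."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from e
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        dos = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]
            dos[i] = np.nan if any(a < 0 for a in alleles) else float(sum(alleles))
        rows.append(dos)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
    if n_skipped:
        import warnings
        warnings.warn(f"skipped {n_skipped} non-biallelic VCF records", stacklevel=2)
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, ids)


def write_relationship(a: RelationshipMatrix, path, *, meta: dict | None = None) -> None:
    df = pd.DataFrame(a.values, index=pd.Index(a.genotype_ids, name="genotype"),
                      columns=a.genotype_ids)
    write_table(df, path, meta=meta)


def read_relationship(path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep=_SEP, index_col=0, comment="#")
    return RelationshipMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)))


def read_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_SEP, comment="#",
                     dtype={"genotype": str, "block": str, "trait": str})
    if "year" in df.columns:
        df["year"] = df["year"].astype(str)
    return df


def read_adjusted_means(path) -> pd.DataFrame:
    """Adjusted means as a genotype x trait table (first column genotype ids)."""
    return pd.read_csv(path, sep=_SEP, index_col=0, comment="#")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable as flat YAML."""

    out_dir: str
    genotypes: str
    seed: int
    focal_trait: str
    secondary_traits: list = field(default_factory=list)
    plot_table: str | None = None
    adjusted_means: str | None = None
    max_missing: float = 0.95
    min_maf: float = 0.05
    stage1_candidates: list = field(default_factory=lambda: ["iid", "ar1xar1"])
    scaling: str = "standardize"
    strategies: list = field(default_factory=lambda: ["standard", "trait_assisted"])
    k: int = 5
    n_repeats: int = 30
    intensity: float = 0.20
    verbosity: str = "INFO"

    def validate(self) -> None:
        if not Path(self.genotypes).exists():
            raise FileNotFoundError(f"genotype file not found: {self.genotypes}")
        if self.plot_table is None and self.adjusted_means is None:
            raise ValueError("config needs either plot_table or adjusted_means")
        for p in (self.plot_table, self.adjusted_means):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        if not self.focal_trait:
            raise ValueError("focal_trait is required")
        if self.seed is None:
            raise ValueError("seed is required")
        from .strategies import STRATEGY_NAMES
        bad = set(self.strategies) - set(STRATEGY_NAMES)
        if bad:
            raise ValueError(f"unknown strategies: {sorted(bad)}")
        needs_two = "multi_trait_indirect" in self.strategies
        if needs_two and len(self.secondary_traits) < 2:
            raise ValueError("multi_trait_indirect requires >= 2 secondary traits")
        single = {"indirect", "multi_trait", "trait_assisted"} & set(self.strategies)
        if single and not self.secondary_traits:
            raise ValueError(f"{sorted(single)} require a secondary trait")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis definition (output location and verbosity
        do not change the numbers, so they are excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("verbosity", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
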