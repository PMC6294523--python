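"""Readers/writers for the package's standard text formats.

Genotypes travel either as a minimal single-chromosome VCF 4.2 (GT fields
only) or as a TSV dosage matrix (rows = SNPs with ``snp_id``/``pos``
columns, columns = samples).  Expression is a gene × sample TSV, gene
annotation a ``gene_id``/``chrom``/``tss`` TSV, truth a
``gene_id``/``snp_id``/``beta``/``coding_mode`` TSV.  All writers emit
deterministic byte streams (stable ordering, floats at 6 significant
digits).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError
from .expression import EffectSizeDistribution, ExpressionMatrix
from .genotypes import GenotypeMatrix, LDProfile, TruthAssignments, TruthEntry

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_vcf",
    "read_vcf_dosages",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_genes_tsv",
    "read_genes_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "load_scenario_config",
    "RunManifest",
]

_FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(G: GenotypeMatrix, path, sample_ids=None) -> None:
    path = Path(path)
    if sample_ids is None:
        sample_ids = [f"sample{i + 1:05d}" for i in range(G.n_samples)]
    with path.open("w") as fh:
        fh.write("snp_id\tpos\t" + "\t".join(sample_ids) + "\n")
        for j in range(G.n_snps):
            row = "\t".join(str(int(d)) for d in G.dosages[:, j])
            fh.write(f"{G.snp_ids[j]}\t{int(G.positions[j])}\t{row}\n")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "snp_id" or df.columns[1] != "pos":
        raise InvalidArgumentError("genotype TSV must start with snp_id, pos")
    dosages = df.iloc[:, 2:].to_numpy(dtype=np.int8).T
    return GenotypeMatrix(
        dosages=dosages,
        positions=df["pos"].to_numpy(np.int64),
        snp_ids=df["snp_id"].to_numpy(object),
    )


def write_vcf(G: GenotypeMatrix, path, chrom: str = "chr22", sample_ids=None) -> None:
    """Write dosages as a minimal unphased GT-only VCF 4.2 file."""
    path = Path(path)
    if sample_ids is None:
        sample_ids = [f"sample{i + 1:05d}" for i in range(G.n_samples)]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(G.n_snps):
            calls = "\t".join(gt[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{chrom}\t{int(G.positions[j])}\t{G.snp_ids[j]}\tA\tB\t.\t.\t.\tGT\t"
                f"{calls}\n"
            )


def read_vcf_dosages(G_path, missing: str = "error") -> GenotypeMatrix:
    """Read a single-chromosome biallelic GT-only VCF into dosages.

    ``missing``: 'error' rejects missing genotypes, 'mean' imputes the
    rounded per-SNP mean dosage (for external data).
    """
    from cyvcf2 import VCF

    if missing not in ("error", "mean"):
        raise InvalidArgumentError("missing policy must be 'error' or 'mean'")
    vcf = VCF(str(G_path))
    dosages, positions, snp_ids = [], [], []
    chroms = set()
    for v in vcf:
        chroms.add(v.CHROM)
        if len(chroms) > 1:
            raise InvalidArgumentError("VCF must contain a single chromosome")
        if len(v.ALT) != 1:
            raise InvalidArgumentError(
                f"multiallelic variant at {v.CHROM}:{v.POS} not supported"
            )
        g = np.array(v.genotypes, dtype=object)
        alleles = np.array([[a[0], a[1]] for a in g], dtype=np.int16)
        if (alleles < 0).any():
            if missing == "error":
                raise InvalidArgumentError(
                    f"missing genotype at {v.CHROM}:{v.POS}; "
                    "set missing='mean' to impute"
                )
            d = alleles.sum(axis=1).astype(float)
            bad = (alleles < 0).any(axis=1)
            d[bad] = np.nan
            d[bad] = np.round(np.nanmean(d))
            dos = d.astype(np.int8)
        else:
            dos = alleles.sum(axis=1).astype(np.int8)
        dosages.append(dos)
        positions.append(v.POS)
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"snp{v.POS}")
    if not dosages:
        raise InvalidArgumentError("VCF contains no variants")
    return GenotypeMatrix(
        dosages=np.stack(dosages, axis=1),
        positions=np.array(positions, dtype=np.int64),
        snp_ids=np.array(snp_ids, dtype=object),
    )


# ---------------------------------------------------------------------------
# Expression / genes / truth
# ---------------------------------------------------------------------------

def write_expression_tsv(E: ExpressionMatrix, path, sample_ids=None) -> None:
    path = Path(path)
    if sample_ids is None:
        sample_ids = [f"sample{i + 1:05d}" for i in range(E.n_samples)]
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
        for i, g in enumerate(E.gene_ids):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in E.values[i]) + "\n")


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise InvalidArgumentError("expression TSV must start with gene_id")
    return ExpressionMatrix(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        gene_ids=list(df["gene_id"]),
    )


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "tss"]].to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "chrom", "tss"}
    if not need.issubset(df.columns):
        raise InvalidArgumentError(f"gene annotation needs columns {sorted(need)}")
    return df


def write_truth_tsv(truth: TruthAssignments, path) -> None:
    df = truth.to_frame()
    df["beta"] = df["beta"].map(_fmt)
    with Path(path).open("w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        for g in truth.null_gene_ids:
            fh.write(f"{g}\t.\t0\tadditive\n")


def read_truth_tsv(path) -> TruthAssignments:
    df = pd.read_csv(path, sep="\t")
    entries = []
    nulls = []
    for g, grp in df.groupby("gene_id", sort=False):
        if (grp.snp_id == ".").all():
            nulls.append(g)
            continue
        entries.append(
            TruthEntry(
                gene_id=g,
                snp_ids=tuple(grp.snp_id),
                betas=tuple(float(b) for b in grp.beta),
                coding=grp.coding_mode.iloc[0],
            )
        )
    return TruthAssignments(entries=entries, null_gene_ids=nulls)


# ---------------------------------------------------------------------------
# Scenario config + manifest
# ---------------------------------------------------------------------------

def load_scenario_config(path) -> "ScenarioConfig":
    """Build a ScenarioConfig from a YAML/JSON mapping.

    Nested keys: ``effect`` (family/shape/scale/constant_beta) and
    ``ld_profile`` map onto their dataclasses; all other keys are
    ScenarioConfig fields.  Unknown keys raise with the offending name.
    """
    from .evaluation import ScenarioConfig

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError("scenario config must be a mapping")
    kw = dict(cfg)
    try:
        if "effect" in kw:
            kw["effect"] = EffectSizeDistribution(**kw["effect"])
        if "ld_profile" in kw:
            kw["ld_profile"] = LDProfile(**kw["ld_profile"])
        return ScenarioConfig(**kw)
    except TypeError as exc:
        raise InvalidArgumentError(f"invalid scenario config: {exc}") from exc


class RunManifest:
    """Records config, seeds, outputs (with checksums) and stage timings."""

    def __init__(self, config: dict, seed: int):
        from . import __version__

        self.data = {
            "package_version": __version__,
            "seed": seed,
            "config": config,
            "stages": {},
            "outputs": {},
        }
        self._t0 = time.time()

    def stage_done(self, name: str) -> None:
        self.data["stages"][name] = round(time.time() - self._t0, 3)
        self._t0 = time.time()

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["outputs"][path.name] = {
            "bytes": path.stat().st_size,
            "sha256": digest,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
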