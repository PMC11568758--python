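"""Plain-text readers and writers for the pipeline's exchange formats.

Phased haplotypes travel as VCF (pipe-separated GT, ancestral allele in
INFO/AA) with a sample-to-population TSV and a genetic-map TSV
(position_bp, cM); single-nucleus counts as MatrixMarket MTX plus
cells/genes/donors TSVs; cline, F_ST and correlation tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .haplotypes import HaplotypePanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genetic_map",
    "read_genetic_map",
    "write_sample_populations",
    "read_sample_populations",
    "write_expression_cohort",
    "read_expression_cohort",
]

_REF, _ALT = "A", "T"  # ancestral / derived letters in synthetic VCFs


def write_vcf(
    panels: dict[str, HaplotypePanel],
    path: str | Path,
    chrom: str = "1",
) -> Path:
    """Write per-population panels as one phased VCF.

    Samples are named ``<pop>_<i>``; consecutive haplotype row pairs form a
    diploid sample.  REF is the ancestral allele, annotated again as
    INFO/AA.
    """
    path = Path(path)
    first = next(iter(panels.values()))
    samples, columns = [], []
    for pop, panel in panels.items():
        if panel.n_haplotypes % 2:
            raise ValueError(f"{pop}: odd haplotype count, cannot pair into diploids")
        for i in range(panel.n_haplotypes // 2):
            samples.append(f"{pop}_{i}")
        columns.append(panel.alleles)
    alleles = np.hstack([c.T for c in columns]).reshape(first.n_sites, -1)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(first.n_sites):
            row = alleles[j]
            gts = "\t".join(f"{row[2*i]}|{row[2*i+1]}" for i in range(len(samples)))
            fh.write(
                f"{chrom}\t{first.positions_bp[j]}\t{first.site_ids[j]}\t{_REF}\t{_ALT}"
                f"\t.\t.\tAA={_REF}\tGT\t{gts}\n"
            )
    return path


def read_vcf(
    vcf_path: str | Path,
    sample_populations: pd.Series,
    genetic_map: pd.DataFrame | None = None,
) -> dict[str, HaplotypePanel]:
    """Read a phased VCF back into per-population haplotype panels.

    Parsing goes through cyvcf2.  ``sample_populations`` maps sample name ->
    population.  Alleles are recoded to ancestral = 0 using INFO/AA when
    present (REF assumed ancestral, with a warning, otherwise).  Genetic
    positions are linearly interpolated from ``genetic_map`` (columns
    position_bp, cM); without a map a uniform 1 cM/Mb is assumed.
    """
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    positions, site_ids, rows = [], [], []
    aa_warned = False
    for variant in vcf:
        aa = variant.INFO.get("AA")
        if aa is None and not aa_warned:
            warnings.warn("no INFO/AA annotation; assuming REF is ancestral")
            aa_warned = True
        ancestral = aa if aa is not None else variant.REF
        flip = bool(variant.ALT) and ancestral == variant.ALT[0]
        gts = np.asarray(variant.genotypes)  # (n_samples, 3): a, b, phased
        if not gts[:, 2].all():
            raise ValueError(f"unphased genotype at {variant.CHROM}:{variant.POS}")
        hap = gts[:, :2].reshape(-1).astype(np.int8)
        if flip:
            hap = 1 - hap
        positions.append(variant.POS)
        site_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        rows.append(hap)
    vcf.close()
    alleles = np.array(rows).T  # haplotypes x sites
    positions = np.array(positions)
    if genetic_map is not None:
        cm = np.interp(positions, genetic_map["position_bp"], genetic_map["cM"])
    else:
        cm = positions * 1e-6
    panels = {}
    for pop in pd.unique(sample_populations.values):
        hap_idx = []
        for i, s in enumerate(samples):
            if sample_populations.get(s) == pop:
                hap_idx.extend([2 * i, 2 * i + 1])
        panels[pop] = HaplotypePanel(
            alleles=alleles[hap_idx],
            positions_bp=positions,
            positions_cm=cm,
            site_ids=list(site_ids),
        )
    return panels


def write_genetic_map(panel: HaplotypePanel, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"position_bp": panel.positions_bp, "cM": panel.positions_cm}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_populations(panels: dict[str, HaplotypePanel], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for pop, panel in panels.items():
        for i in range(panel.n_haplotypes // 2):
            rows.append({"sample": f"{pop}_{i}", "population": pop})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_sample_populations(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample")["population"]


def write_expression_cohort(matrix, out_dir: str | Path) -> Path:
    """Write a cell-expression cohort as MTX + cells/genes/donors TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(out_dir / "counts.mtx", sparse.csr_matrix(matrix.counts))
    matrix.cells.to_csv(out_dir / "cells.tsv", sep="\t")
    pd.Series(matrix.genes, name="gene").to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    matrix.donors.to_csv(out_dir / "donors.tsv", sep="\t")
    return out_dir


def read_expression_cohort(out_dir: str | Path):
    from .trans_expr import CellExpressionMatrix

    out_dir = Path(out_dir)
    counts = np.asarray(scipy_io.mmread(out_dir / "counts.mtx").todense())
    cells = pd.read_csv(out_dir / "cells.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(out_dir / "genes.tsv", sep="\t")["gene"].tolist()
    donors = pd.read_csv(out_dir / "donors.tsv", sep="\t", index_col=0)
    donors["risk_carrier"] = donors["risk_carrier"].astype(bool)
    return CellExpressionMatrix(counts=counts, genes=genes, cells=cells, donors=donors)
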