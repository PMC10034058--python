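"""Plain-text interchange: VCF, FAM-like pedigree TSV, BED, LD scores, results.

Panels and trio cohorts are written as uncompressed VCF (GT only, one sample
per individual; trio members are named FAMID_F / FAMID_M / FAMID_C) and read
back with cyvcf2.  The pedigree/phenotype file is a 7-column TSV
(fam, father, mother, child, sex, affected, comorbid).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genesets import SnpAnnotation
from .simulate.panel import ReferencePanel
from .simulate.trios import TrioCohort

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}

FAM_COLUMNS = ["fam", "father", "mother", "child", "sex", "affected", "comorbid"]


def _write_vcf(path, chrom, bp, snp_ids, ref, alt, sample_names, dosage_columns):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for j in range(len(snp_ids)):
            gts = "\t".join(_GT[int(d[j])] for d in dosage_columns)
            fh.write(
                f"{chrom[j]}\t{bp[j]}\t{snp_ids[j]}\t{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_panel_vcf(panel: ReferencePanel, path) -> None:
    """Panel genotypes as VCF; REF is the major allele, ALT the counted minor."""
    samples = [f"IND{i + 1:05d}" for i in range(panel.n_individuals)]
    _write_vcf(
        path, panel.chrom, panel.bp, panel.snp_ids, panel.a2, panel.a1,
        samples, list(panel.genotypes),
    )


def write_trio_vcf(trios: TrioCohort, panel: ReferencePanel, path) -> None:
    samples, cols = [], []
    for i, fam in enumerate(trios.fam_ids):
        for role, mat in (("F", trios.father), ("M", trios.mother), ("C", trios.child)):
            samples.append(f"{fam}_{role}")
            cols.append(mat[i])
    _write_vcf(
        path, panel.chrom, panel.bp, panel.snp_ids, panel.a2, panel.a1, samples, cols
    )


def read_trio_vcf(path, fam: pd.DataFrame) -> TrioCohort:
    """Rebuild a TrioCohort from a trio VCF plus its pedigree table."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    snp_ids, dosages = [], []
    for var in vcf:
        snp_ids.append(var.ID)
        gt = np.asarray(var.genotype.array())[:, :2].sum(axis=1)
        dosages.append(gt)
    G = np.asarray(dosages, dtype=np.int8).T  # samples x snps

    fams = fam["fam"].astype(str).tolist()
    father = np.stack([G[sample_idx[f"{f}_F"]] for f in fams])
    mother = np.stack([G[sample_idx[f"{f}_M"]] for f in fams])
    child = np.stack([G[sample_idx[f"{f}_C"]] for f in fams])
    n = len(fams)
    return TrioCohort(
        fam_ids=np.array(fams, dtype=object),
        father=father,
        mother=mother,
        child=child,
        comorbid=fam["comorbid"].astype(bool).to_numpy(),
        liability=np.full(n, np.nan),
        components=pd.DataFrame(index=range(n)),
        snp_ids=np.array(snp_ids, dtype=object),
    )


def write_fam(trios: TrioCohort, path) -> None:
    df = pd.DataFrame(
        {
            "fam": trios.fam_ids,
            "father": [f"{f}_F" for f in trios.fam_ids],
            "mother": [f"{f}_M" for f in trios.fam_ids],
            "child": [f"{f}_C" for f in trios.fam_ids],
            "sex": 0,
            "affected": 2,
            "comorbid": trios.comorbid.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fam(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    return df


def write_bed(bed: pd.DataFrame, path) -> None:
    """0-based half-open BED, tab-separated, no header."""
    cols = [c for c in ("chrom", "start", "end", "gene") if c in bed.columns]
    bed[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chrom", "start", "end", "gene"][: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_annotation(annot: SnpAnnotation, path) -> None:
    out = annot.membership.astype(int)
    out.insert(0, "SNP", annot.snp_ids)
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> SnpAnnotation:
    df = pd.read_csv(path, sep="\t")
    snp = df.pop("SNP").to_numpy()
    return SnpAnnotation(snp, df.astype(bool).set_index(pd.Index(snp, name="SNP")))


def write_ld_scores(ld, path) -> None:
    with open(path, "w") as fh:
        for c, m in ld.m_by_partition.items():
            fh.write(f"# M_{c} = {m}\n")
        ld.ell.reset_index().rename(columns={"index": "SNP"}).to_csv(
            fh, sep="\t", index=False
        )


def write_covariance_results(results, path) -> None:
    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, sep="\t", index=False)
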