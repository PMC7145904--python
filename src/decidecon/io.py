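"""Readers and writers for the package's plain-text file dialects.

Formats:

* genotype VCF — minimal VCFv4.2: CHROM, POS (1-based), ID ".", REF, ALT,
  QUAL ".", FILTER "PASS", INFO ``GENE=<id>``, FORMAT GT, one sample column
  with GT in {0/0, 0/1, 1/1}.  Read back through :mod:`pysam`.
* pileup TSV — columns chrom, pos, ref, gene_id, count_A..count_T.
* counts TSV — first column gene_id, remaining columns samples; the sample →
  condition map is a separate two-column TSV.
* truth JSON — every :class:`~decidecon.synthetic.SimTruth` field.

All writers guarantee exact round-trips: reading a written file reproduces
the in-memory object.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import DomainError
from .synthetic import (
    BASES,
    FetalGenotype,
    ParentalGenotypes,
    SimTruth,
    Site,
    SitePileup,
)

_PILEUP_COLUMNS = ["chrom", "pos", "ref", "gene_id",
                   "count_A", "count_C", "count_G", "count_T"]

_GT_FROM_DOSAGE = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(sites: Sequence[Site], sample_name: str,
                extra_info: Sequence[str] = ()) -> list[str]:
    contigs = []
    for s in sites:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=decidecon",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">',
    ]
    lines += list(extra_info)
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample_name)
    return lines


def write_genotype_vcf(sites: Sequence[Site], dosages: np.ndarray,
                       sample_name: str, path: str | os.PathLike) -> Path:
    """Write one sample's alt-allele dosages as a minimal VCF."""
    path = Path(path)
    dosages = np.asarray(dosages, dtype=float)
    if len(dosages) != len(sites):
        raise DomainError("dosage array must match the site list in length")
    try:
        with open(path, "w") as fh:
            for line in _vcf_header(sites, sample_name):
                fh.write(line + "\n")
            for site, d in zip(sites, dosages):
                gt = _GT_FROM_DOSAGE[float(d)]
                fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                         f"\t.\tPASS\tGENE={site.gene_id}\tGT\t{gt}\n")
    except OSError as exc:
        raise DomainError(f"cannot write VCF {path}: {exc}") from exc
    return path


def read_genotype_vcf(path: str | os.PathLike) -> tuple[list[Site], np.ndarray, str]:
    """Read a minimal genotype VCF back to (sites, dosages, sample name)."""
    path = Path(path)
    sites: list[Site] = []
    dosages: list[float] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise DomainError(f"{path}: expected exactly one sample column, "
                              f"found {len(samples)}")
        sample = samples[0]
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise DomainError(f"{path}: site {rec.chrom}:{rec.pos} is not "
                                  "bi-allelic")
            gene = rec.info.get("GENE")
            if gene is None:
                raise DomainError(f"{path}: site {rec.chrom}:{rec.pos} lacks "
                                  "INFO/GENE")
            gt = rec.samples[sample]["GT"]
            if gt is None or any(a is None for a in gt):
                raise DomainError(f"{path}: missing GT at {rec.chrom}:{rec.pos}")
            sites.append(Site(rec.chrom, rec.pos, str(gene), rec.ref,
                              rec.alts[0]))
            dosages.append(sum(gt) / 2.0)
    return sites, np.array(dosages), sample


def write_parental_vcfs(parents: ParentalGenotypes,
                        directory: str | os.PathLike) -> tuple[Path, Path]:
    directory = Path(directory)
    mother = write_genotype_vcf(parents.sites, parents.mother_dosage,
                                "mother", directory / "mother.vcf")
    father = write_genotype_vcf(parents.sites, parents.father_dosage,
                                "father", directory / "father.vcf")
    return mother, father


def read_parental_vcfs(mother_path: str | os.PathLike,
                       father_path: str | os.PathLike) -> ParentalGenotypes:
    m_sites, m_dos, _ = read_genotype_vcf(mother_path)
    f_sites, f_dos, _ = read_genotype_vcf(father_path)
    if m_sites != f_sites:
        raise DomainError("mother and father VCFs disagree on the site list")
    return ParentalGenotypes(m_sites, m_dos, f_dos)


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

def write_pileup_tsv(pileups: Sequence[SitePileup],
                     path: str | os.PathLike) -> Path:
    path = Path(path)
    rows = [(p.chrom, p.pos, p.ref, p.gene_id, *p.counts) for p in pileups]
    df = pd.DataFrame(rows, columns=_PILEUP_COLUMNS)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise DomainError(f"cannot write pileup TSV {path}: {exc}") from exc
    return path


def read_pileup_tsv(path: str | os.PathLike) -> list[SitePileup]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"{path}: missing pileup columns {sorted(missing)}")
    return [
        SitePileup(str(r.chrom), int(r.pos), str(r.ref), str(r.gene_id),
                   (int(r.count_A), int(r.count_C), int(r.count_G),
                    int(r.count_T)))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# counts TSV + condition map
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return path


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_conditions_tsv(conditions: pd.Series | Mapping[str, str],
                         path: str | os.PathLike) -> Path:
    path = Path(path)
    ser = pd.Series(dict(conditions), name="condition")
    ser.index.name = "sample"
    ser.to_frame().to_csv(path, sep="\t")
    return path


def read_conditions_tsv(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return df["condition"]


# ---------------------------------------------------------------------------
# truth JSON
# ---------------------------------------------------------------------------

def write_truth_json(truth: SimTruth, path: str | os.PathLike) -> Path:
    path = Path(path)
    payload = {
        "maternal_fraction": truth.maternal_fraction,
        "seq_error": truth.seq_error,
        "mean_depth": truth.mean_depth,
        "expression_levels": truth.expression_levels,
        "planted_gene_sets": {k: sorted(v)
                              for k, v in truth.planted_gene_sets.items()},
        "effect_sizes": truth.effect_sizes,
        "nb_dispersion": truth.nb_dispersion,
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return path


def read_truth_json(path: str | os.PathLike) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    payload["planted_gene_sets"] = {k: set(v)
                                    for k, v in payload["planted_gene_sets"].items()}
    return SimTruth(**payload)


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def write_fixtures(outputs: Mapping[str, object],
                   directory: str | os.PathLike) -> dict[str, Path]:
    """Write a bundle of simulated objects to ``directory``.

    Recognised keys: ``parents`` (ParentalGenotypes), ``fetus``
    (FetalGenotype), ``*_pileups`` (list of SitePileup), ``counts``
    (DataFrame), ``conditions`` (Series/mapping), ``truth`` (SimTruth).
    Returns the mapping from logical name to written path(s).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DomainError(f"cannot create {directory}: {exc}") from exc

    written: dict[str, Path] = {}
    for name, obj in outputs.items():
        if isinstance(obj, ParentalGenotypes):
            mother, father = write_parental_vcfs(obj, directory)
            written[f"{name}.mother"] = mother
            written[f"{name}.father"] = father
        elif isinstance(obj, FetalGenotype):
            written[name] = write_genotype_vcf(obj.sites, obj.fetus_dosage,
                                               "fetus",
                                               directory / f"{name}.vcf")
        elif isinstance(obj, SimTruth):
            written[name] = write_truth_json(obj, directory / f"{name}.json")
        elif isinstance(obj, pd.DataFrame):
            written[name] = write_counts_tsv(obj, directory / f"{name}.tsv")
        elif isinstance(obj, (pd.Series, Mapping)):
            written[name] = write_conditions_tsv(obj, directory / f"{name}.tsv")
        elif isinstance(obj, Sequence) and (not obj or
                                            isinstance(obj[0], SitePileup)):
            written[name] = write_pileup_tsv(obj, directory / f"{name}.tsv")
        else:
            raise DomainError(f"do not know how to write fixture {name!r} "
                              f"of type {type(obj).__name__}")
    return written


# ---------------------------------------------------------------------------
# analysis outputs (frequency table, origin JSON, SNP echo VCF)
# ---------------------------------------------------------------------------

def write_frequency_tsv(records: Sequence, path: str | os.PathLike) -> Path:
    """Write NucleotideFrequencyRecord rows as the per-sample frequency table."""
    path = Path(path)
    rows = [
        (r.chrom, r.pos, r.sample_label, *r.freqs, r.depth)
        for r in records
    ]
    cols = ["chrom", "pos", "sample",
            *(f"freq_{b}" for b in BASES), "depth"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def write_origin_json(estimate, path: str | os.PathLike) -> Path:
    path = Path(path)
    payload = {
        "f_hat": estimate.f_hat,
        "ci95": list(estimate.ci95),
        "n_snps": estimate.n_snps,
        "origin_call": estimate.origin_call,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return path


def write_informative_snps_vcf(snps: Sequence, path: str | os.PathLike) -> Path:
    """Echo discovered informative SNPs as a minimal VCF with GM/GF dosages."""
    path = Path(path)
    sites = [Site(s.chrom, s.pos, s.gene_id, s.ref, s.alt) for s in snps]
    extra = [
        '##INFO=<ID=GM,Number=1,Type=Float,Description="Maternal alt dosage">',
        '##INFO=<ID=GF,Number=1,Type=Float,Description="Fetal alt dosage">',
    ]
    with open(path, "w") as fh:
        for line in _vcf_header(sites, "informative", extra_info=extra):
            fh.write(line + "\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
                     f"GENE={s.gene_id};GM={s.g_m};GF={s.g_f}\tGT\t"
                     f"{_GT_FROM_DOSAGE[float(s.g_m)]}\n")
    return path
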