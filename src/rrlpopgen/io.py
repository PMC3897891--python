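"""Readers and writers for the external formats the pipeline touches.

Dialects: FASTA (optionally gzipped, case preserved — lowercase is
soft-masking); BED 0-based half-open; VCF 4.2 with 1-based positions and
GT/DP/GQ format fields plus a ``##caller=`` header line carrying the call
set's label; small TSVs (read counts, population assignments, truth
genotypes) via pandas.  Internally everything is 0-based half-open except
site positions, which follow VCF (1-based).  Every writer's output
round-trips through the corresponding reader.
"""

from __future__ import annotations

import gzip
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import MISSING, CallSet, SiteCounts

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_vcf",
    "write_vcf",
    "read_counts",
    "write_counts",
    "read_populations",
    "write_populations",
    "read_truth",
    "write_truth",
    "write_provenance",
]

_GT_TO_VCF = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
_VCF_TO_GT = {v: k for k, v in _GT_TO_VCF.items()} | {(1, 0): 1}


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {name: sequence}; names are the first whitespace token, case
    is preserved.  Duplicate names and empty records are errors."""
    genome: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate FASTA record name {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"empty FASTA record {rec.id!r}")
            genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path, genome: dict[str, str] | None = None) -> pd.DataFrame:
    """3+ column BED (0-based half-open) -> sorted interval DataFrame."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
        dtype={0: str, 1: np.int64, 2: np.int64},
    )
    if (bed["start"] >= bed["end"]).any():
        raise ValueError("BED intervals with start >= end")
    if genome is not None:
        for chrom, grp in bed.groupby("chrom"):
            if chrom not in genome:
                raise ValueError(f"BED chromosome {chrom!r} not in genome")
            if (grp["end"] > len(genome[chrom])).any():
                raise ValueError(f"BED interval beyond end of {chrom!r}")
    return bed.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path, extra_columns: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_columns or [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_vcf(callset: CallSet, path, contigs: dict[str, int] | None = None,
              variant_only: bool = False) -> None:
    """Write a call set as VCF 4.2.

    Non-variant and multi-allelic sites are kept (flagged via the NONVAR and
    MULTI info flags) unless ``variant_only`` is set; the caller label goes
    into a ``##caller=`` header line.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##caller={callset.label}")
    names = contigs or {
        c: int(callset.sites.loc[callset.sites["chrom"] == c, "pos"].max()) + 1000
        for c in pd.unique(callset.sites["chrom"])
    }
    for name, length in names.items():
        header.contigs.add(name, length=length)
    header.info.add("NONVAR", 0, "Flag", "No called individual carries the alternative allele")
    header.info.add("MULTI", 0, "Flag", "More than two alleles observed in the read data")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    for ind in callset.individuals:
        header.add_sample(ind)
    sites = callset.sites
    mask = sites["variant"].to_numpy() if variant_only else np.ones(len(sites), dtype=bool)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in np.flatnonzero(mask):
            row = sites.iloc[i]
            rec = vcf.new_record(
                contig=row["chrom"], start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            if not row["variant"]:
                rec.info["NONVAR"] = True
            if row["multiallelic"]:
                rec.info["MULTI"] = True
            for j, ind in enumerate(callset.individuals):
                sample = rec.samples[ind]
                sample["GT"] = _GT_TO_VCF[int(callset.gt[i, j])]
                if callset.dp is not None:
                    sample["DP"] = int(callset.dp[i, j])
                if callset.gq is not None:
                    sample["GQ"] = int(callset.gq[i, j])
            vcf.write(rec)


def read_vcf(path) -> CallSet:
    """Read a (biallelic, GT-bearing) VCF back into a CallSet."""
    with pysam.VariantFile(str(path)) as vcf:
        label = "unknown"
        for line in str(vcf.header).splitlines():
            if line.startswith("##caller="):
                label = line.split("=", 1)[1]
        individuals = list(vcf.header.samples)
        rows, gts, dps, gqs = [], [], [], []
        has_dp = "DP" in vcf.header.formats
        has_gq = "GQ" in vcf.header.formats
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"site {rec.contig}:{rec.pos} is not biallelic")
            rows.append(
                {
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "variant": "NONVAR" not in rec.info,
                    "multiallelic": "MULTI" in rec.info,
                }
            )
            gt_row, dp_row, gq_row = [], [], []
            for ind in individuals:
                sample = rec.samples[ind]
                alleles = tuple(sample["GT"]) if sample.get("GT") is not None else (None, None)
                if alleles not in _VCF_TO_GT:
                    raise ValueError(
                        f"unsupported genotype {alleles} at {rec.contig}:{rec.pos}"
                    )
                gt_row.append(_VCF_TO_GT[alleles])
                dp_row.append(sample.get("DP") if has_dp else None)
                gq_row.append(sample.get("GQ") if has_gq else None)
            gts.append(gt_row)
            dps.append(dp_row)
            gqs.append(gq_row)
    sites = pd.DataFrame(rows)
    gt = np.array(gts, dtype=np.int8) if gts else np.zeros((0, len(individuals)), np.int8)
    dp = None
    gq = None
    if has_dp and gts and not any(v is None for row in dps for v in row):
        dp = np.array(dps, dtype=np.int64)
    if has_gq and gts and not any(v is None for row in gqs for v in row):
        gq = np.array(gqs, dtype=np.int16)
    return CallSet(label=label, sites=sites, individuals=individuals, gt=gt, dp=dp, gq=gq)


def write_counts(counts: SiteCounts, path) -> None:
    """SiteCounts -> long TSV (chrom, pos, ref, alt, individual, ref_count,
    alt_count, other_count)."""
    n_sites, n_inds = counts.ref.shape
    sites = counts.sites
    long = pd.DataFrame(
        {
            "chrom": np.repeat(sites["chrom"].to_numpy(), n_inds),
            "pos": np.repeat(sites["pos"].to_numpy(), n_inds),
            "ref": np.repeat(sites["ref"].to_numpy(), n_inds),
            "alt": np.repeat(sites["alt"].to_numpy(), n_inds),
            "individual": np.tile(np.array(counts.individuals), n_sites),
            "ref_count": counts.ref.ravel(),
            "alt_count": counts.alt.ravel(),
            "other_count": counts.other.ravel(),
        }
    )
    long.to_csv(path, sep="\t", index=False)


def read_counts(path) -> SiteCounts:
    long = pd.read_csv(path, sep="\t")
    if long.duplicated(["chrom", "pos", "individual"]).any():
        raise ValueError("duplicate (site, individual) entries in counts table")
    sites = (
        long[["chrom", "pos", "ref", "alt"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    individuals = list(pd.unique(long["individual"]))  # appearance order round-trips
    key = pd.MultiIndex.from_frame(long[["chrom", "pos", "individual"]])
    shape = (len(sites), len(individuals))
    ref = np.zeros(shape, dtype=np.int64)
    alt = np.zeros(shape, dtype=np.int64)
    other = np.zeros(shape, dtype=np.int64)
    site_pos = {
        (c, p): i for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))
    }
    ind_pos = {ind: j for j, ind in enumerate(individuals)}
    rows = long[["chrom", "pos", "individual"]].itertuples(index=False)
    has_other = "other_count" in long.columns
    for k, (c, p, ind) in enumerate(rows):
        i, j = site_pos[(c, p)], ind_pos[ind]
        ref[i, j] = long["ref_count"].iat[k]
        alt[i, j] = long["alt_count"].iat[k]
        if has_other:
            other[i, j] = long["other_count"].iat[k]
    return SiteCounts(sites=sites, individuals=individuals, ref=ref, alt=alt, other=other)


def read_populations(path) -> pd.Series:
    tab = pd.read_csv(path, sep="\t")
    return pd.Series(
        tab["population"].to_numpy(), index=tab["individual"], name="population"
    )


def write_populations(populations: pd.Series, path) -> None:
    pd.DataFrame(
        {"individual": populations.index, "population": populations.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    """Truth-genotype TSV: chrom, pos, individual, genotype (0/1/2)."""
    return pd.read_csv(path, sep="\t")


def write_truth(truth, path) -> None:
    n_sites, n_inds = truth.gt.shape
    pd.DataFrame(
        {
            "chrom": np.repeat(truth.sites["chrom"].to_numpy(), n_inds),
            "pos": np.repeat(truth.sites["pos"].to_numpy(), n_inds),
            "individual": np.tile(np.array(truth.individuals), n_sites),
            "genotype": truth.gt.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def write_provenance(path, inputs: dict, parameters: dict, seed: int | None = None) -> None:
    """JSON provenance record written next to every CLI output."""
    from . import __version__

    record = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "command": " ".join(sys.argv),
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
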