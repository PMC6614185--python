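"""Cohort genotype container and VCF input/output.

Variants are keyed by rsID throughout; chromosome and position are carried
only so that valid VCF can be emitted.  Only the GT subfield is consumed.
Copy number (needed for the CYP2D6 ultrarapid phenotype) travels in a
sidecar TSV (sample_id, gene, copy_number), not in VCF CNV records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam

from .catalog import VariantSite

MISSING = -1


class VcfFormatError(ValueError):
    pass


@dataclass
class CohortGenotypes:
    """Samples x variants genotype matrix with phase and copy-number side-channels.

    Haplotype entries are 0 (ref), 1 (alt) or -1 (missing).  For unphased
    variants the two haplotype slots are an arbitrary ordering of the
    genotype; only the dosage is meaningful there.
    """

    sample_ids: list[str]
    sites: list[VariantSite]
    hap1: np.ndarray  # (n_samples, n_variants) int8
    hap2: np.ndarray
    phased: np.ndarray  # (n_variants,) bool
    copy_number: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise VcfFormatError("duplicate sample ids")
        n, m = len(self.sample_ids), len(self.sites)
        if self.hap1.shape != (n, m) or self.hap2.shape != (n, m):
            raise VcfFormatError("genotype matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.sites]

    @property
    def variant_index(self) -> dict[str, int]:
        return {s.rsid: j for j, s in enumerate(self.sites)}

    def dosage(self, rsid: str) -> np.ndarray:
        """Risk (ALT) allele dosage 0/1/2 per sample; -1 where missing."""
        j = self.variant_index[rsid]
        h1, h2 = self.hap1[:, j], self.hap2[:, j]
        out = h1 + h2
        out[(h1 == MISSING) | (h2 == MISSING)] = MISSING
        return out

    def is_missing(self, rsid: str) -> np.ndarray:
        j = self.variant_index[rsid]
        return (self.hap1[:, j] == MISSING) | (self.hap2[:, j] == MISSING)

    def copy_number_for(self, gene: str) -> np.ndarray:
        """Per-sample copy number for a gene (defaults to 2)."""
        if gene in self.copy_number:
            return self.copy_number[gene]
        return np.full(self.n_samples, 2, dtype=int)

    def missing_count(self) -> int:
        return int(((self.hap1 == MISSING) | (self.hap2 == MISSING)).sum())

    def equal_genotypes(self, other: "CohortGenotypes") -> bool:
        """Identity on (sample, rsid, genotype, phase), ignoring column order."""
        if self.sample_ids != other.sample_ids:
            return False
        if set(self.rsids) != set(other.rsids):
            return False
        oidx = other.variant_index
        for j, site in enumerate(self.sites):
            k = oidx[site.rsid]
            if bool(self.phased[j]) != bool(other.phased[k]):
                return False
            if self.phased[j]:
                if not (
                    np.array_equal(self.hap1[:, j], other.hap1[:, k])
                    and np.array_equal(self.hap2[:, j], other.hap2[:, k])
                ):
                    return False
            else:
                a = np.sort(np.stack([self.hap1[:, j], self.hap2[:, j]]), axis=0)
                b = np.sort(np.stack([other.hap1[:, k], other.hap2[:, k]]), axis=0)
                if not np.array_equal(a, b):
                    return False
        return True


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**6, chrom)


def read_vcf(path: str | Path, wanted_rsids: Iterable[str]) -> CohortGenotypes:
    """Read bi-allelic SNV genotypes for the wanted rsIDs from a VCF.

    Absent rsIDs become all-missing columns (a warning names each); records
    for a wanted rsID must be bi-allelic.  GT ``|`` marks a variant phased,
    ``/`` unphased; a variant column is flagged phased only if every called
    genotype is phased.
    """
    wanted = list(dict.fromkeys(wanted_rsids))
    wanted_set = set(wanted)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    found: dict[str, tuple[VariantSite, np.ndarray, np.ndarray, bool]] = {}
    for rec in vf:
        rsid = rec.id
        if rsid is None or rsid not in wanted_set:
            continue
        if rsid in found:
            raise VcfFormatError(f"rsid collision: {rsid} occurs more than once")
        alts = rec.alts or ()
        if len(alts) != 1:
            raise VcfFormatError(
                f"{rsid} at {rec.chrom}:{rec.pos} is not bi-allelic (ALT={','.join(alts) or '.'})"
            )
        h1 = np.full(len(samples), MISSING, dtype=np.int8)
        h2 = np.full(len(samples), MISSING, dtype=np.int8)
        phased = True
        for i, name in enumerate(samples):
            sample = rec.samples[name]
            gt = sample.get("GT", (None, None))
            alleles = tuple(a for a in gt)
            if len(alleles) == 2 and alleles[0] is not None and alleles[1] is not None:
                h1[i], h2[i] = alleles
                if not sample.phased:
                    phased = False
        site = VariantSite(rsid=rsid, chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alts[0])
        found[rsid] = (site, h1, h2, phased)
    vf.close()

    sites, h1_cols, h2_cols, phase_flags = [], [], [], []
    n = len(samples)
    for rsid in wanted:
        if rsid in found:
            site, h1, h2, ph = found[rsid]
        else:
            warnings.warn(f"rsid {rsid} absent from VCF; recorded as all-missing", stacklevel=2)
            site = VariantSite(rsid=rsid, chrom="0", pos=0, ref="N", alt="N")
            h1 = np.full(n, MISSING, dtype=np.int8)
            h2 = np.full(n, MISSING, dtype=np.int8)
            ph = False
        sites.append(site)
        h1_cols.append(h1)
        h2_cols.append(h2)
        phase_flags.append(ph)

    hap1 = np.stack(h1_cols, axis=1) if sites else np.zeros((n, 0), dtype=np.int8)
    hap2 = np.stack(h2_cols, axis=1) if sites else np.zeros((n, 0), dtype=np.int8)
    return CohortGenotypes(
        sample_ids=samples, sites=sites, hap1=hap1, hap2=hap2,
        phased=np.asarray(phase_flags, dtype=bool),
    )


def write_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write the cohort as VCF 4.2 (GT only), variants sorted by position."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chroms = sorted({s.chrom for s in cohort.sites}, key=_chrom_sort_key)
    for chrom in chroms:
        maxpos = max(s.pos for s in cohort.sites if s.chrom == chrom)
        header.add_line(f"##contig=<ID={chrom},length={maxpos + 10_000}>")
    for name in cohort.sample_ids:
        header.add_sample(name)

    order = sorted(
        range(len(cohort.sites)),
        key=lambda j: (_chrom_sort_key(cohort.sites[j].chrom), cohort.sites[j].pos),
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            site = cohort.sites[j]
            rec = out.new_record(
                contig=site.chrom, start=site.pos - 1, stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt), id=site.rsid,
            )
            phased = bool(cohort.phased[j])
            for i, name in enumerate(cohort.sample_ids):
                a1, a2 = int(cohort.hap1[i, j]), int(cohort.hap2[i, j])
                if a1 == MISSING or a2 == MISSING:
                    rec.samples[name]["GT"] = (None, None)
                else:
                    rec.samples[name]["GT"] = (a1, a2)
                    rec.samples[name].phased = phased
            out.write(rec)


def read_copy_number(path: str | Path, sample_ids: list[str]) -> dict[str, np.ndarray]:
    """Read a copy-number sidecar TSV (sample_id, gene, copy_number)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str, "copy_number": int})
    out: dict[str, np.ndarray] = {}
    index = {s: i for i, s in enumerate(sample_ids)}
    for gene, sub in df.groupby("gene"):
        arr = np.full(len(sample_ids), 2, dtype=int)
        for _, r in sub.iterrows():
            if r["copy_number"] < 0:
                raise ValueError(f"negative copy number for {r['sample_id']}/{gene}")
            if r["sample_id"] in index:
                arr[index[r["sample_id"]]] = r["copy_number"]
        out[gene] = arr
    return out


def write_copy_number(cohort: CohortGenotypes, path: str | Path) -> None:
    import pandas as pd

    rows = [
        {"sample_id": s, "gene": gene, "copy_number": int(arr[i])}
        for gene, arr in cohort.copy_number.items()
        for i, s in enumerate(cohort.sample_ids)
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene", "copy_number"]).to_csv(
        path, sep="\t", index=False
    )
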