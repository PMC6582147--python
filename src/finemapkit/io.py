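"""Readers and writers for external formats and the core genotype container.

Internal coordinates are 1-based, closed intervals everywhere; BED input is
converted on read and back on write.  Variants are keyed ``chrom:pos:ref:alt``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSet",
    "read_genotypes",
    "read_vcf",
    "read_plink",
    "read_intervals",
    "read_bed_intervals",
    "read_gff3_genes",
    "write_vcf",
    "read_grm",
    "write_grm",
]

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf"]


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


@dataclasses.dataclass
class GenotypeSet:
    """Variant-by-individual additive dosage matrix with variant metadata.

    Parameters
    ----------
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt, maf``; positions
        1-based and sorted within chromosome.
    dosages
        Array of shape ``(n_variants, n_individuals)`` with values in [0, 2].
    individuals
        Individual identifiers, one per dosage column.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    individuals: list[str]

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.individuals)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.individuals)} individuals"
            )
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"]
            raise ValueError(f"duplicate variant ids: {list(dups[:5])}")
        if "maf" not in self.variants or self.variants["maf"].isna().any():
            self.variants = self.variants.assign(maf=self.compute_maf())

    # -- basic properties -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    def compute_maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    # -- views ------------------------------------------------------------
    def take(self, index) -> "GenotypeSet":
        """Subset variants by positional index, preserving order."""
        index = np.asarray(index)
        return GenotypeSet(
            self.variants.iloc[index].reset_index(drop=True),
            self.dosages[index],
            self.individuals,
        )

    def select_ids(self, ids) -> "GenotypeSet":
        pos = pd.Index(self.variants["id"]).get_indexer(ids)
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return self.take(pos)

    def restrict_region(self, chrom, start: int, end: int) -> "GenotypeSet":
        """Variants on ``chrom`` with start <= pos <= end (1-based closed)."""
        mask = (
            (self.variants["chrom"].astype(str) == str(chrom))
            & (self.variants["pos"] >= start)
            & (self.variants["pos"] <= end)
        )
        return self.take(np.flatnonzero(mask.to_numpy()))

    def select_individuals(self, ids) -> "GenotypeSet":
        pos = pd.Index(self.individuals).get_indexer(ids)
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"unknown individuals: {missing[:5]}")
        gs = GenotypeSet(
            self.variants.drop(columns="maf"),
            self.dosages[:, pos],
            [self.individuals[p] for p in pos],
        )
        return gs

    def design_matrix(self, ids=None) -> np.ndarray:
        """(n_individuals x k) dosage columns for the given variant ids."""
        sub = self if ids is None else self.select_ids(ids)
        return sub.dosages.T.copy()

    def n_distinct_genotype_columns(self) -> int:
        """Distinct hard-called genotype rows among the variants."""
        hard = np.rint(np.clip(self.dosages, 0, 2)).astype(np.int8)
        return len({row.tobytes() for row in hard})


# ---------------------------------------------------------------------------
# Genotype readers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str | None = None, split_multiallelic: bool = False) -> GenotypeSet:
    """Read genotypes from VCF or a PLINK binary triplet.

    ``fmt`` is inferred from the extension when omitted (``.vcf``/``.vcf.gz``
    vs ``.bed``).  Dosages come from the DS field when present, else hard GT
    calls.  Multi-allelic records are skipped unless ``split_multiallelic``.
    """
    path = Path(path)
    if fmt is None:
        name = path.name
        if name.endswith((".vcf", ".vcf.gz")):
            fmt = "vcf"
        elif name.endswith(".bed"):
            fmt = "plink-binary"
        else:
            raise ValueError(f"cannot infer genotype format from {name!r}")
    if fmt == "vcf":
        return read_vcf(path, split_multiallelic=split_multiallelic)
    if fmt == "plink-binary":
        return read_plink(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_vcf(path, split_multiallelic: bool = False) -> GenotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows = []
    dosage_rows = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 and not split_multiallelic:
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        for ai, alt in enumerate(alts):
            if ds is not None:
                dose = np.asarray(ds, dtype=float).reshape(len(individuals), -1)
                dose = dose[:, ai] if dose.shape[1] > 1 else dose[:, 0]
            else:
                gts = np.asarray(rec.genotype.array())[:, :2]
                dose = (gts == ai + 1).sum(axis=1).astype(float)
                dose[np.any(gts < 0, axis=1)] = np.nan
            if np.isnan(dose).any():  # mean-impute rare missing calls
                dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
            rows.append(
                {
                    "id": variant_key(rec.CHROM, rec.POS, rec.REF, alt),
                    "chrom": str(rec.CHROM),
                    "pos": int(rec.POS),
                    "ref": rec.REF,
                    "alt": alt,
                    "maf": np.nan,
                }
            )
            dosage_rows.append(dose)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    variants = pd.DataFrame(rows)
    return GenotypeSet(variants, np.vstack(dosage_rows), individuals)


_PLINK_MAGIC = b"\x6c\x1b"
# 2-bit codes in a .bed byte, SNP-major mode: 00=hom A1, 01=missing, 10=het, 11=hom A2
_PLINK_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(bed_path) -> GenotypeSet:
    """Read a PLINK .bed/.bim/.fam triplet (SNP-major .bed)."""
    bed_path = Path(bed_path)
    bim = pd.read_csv(
        bed_path.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "rsid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        bed_path.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:2].tobytes() != _PLINK_MAGIC or raw[2] != 1:
        raise ValueError(f"{bed_path} is not a SNP-major PLINK .bed file")
    n, m = len(fam), len(bim)
    bytes_per_variant = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_variant)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.arange(0, 8, 2, dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _PLINK_DECODE[codes]
    if np.isnan(dosages).any():
        means = np.nanmean(dosages, axis=1, keepdims=True)
        dosages = np.where(np.isnan(dosages), means, dosages)
    variants = pd.DataFrame(
        {
            "id": [
                variant_key(c, p, a2, a1)
                for c, p, a1, a2 in zip(bim.chrom, bim.pos, bim.a1, bim.a2)
            ],
            "chrom": bim.chrom.astype(str),
            "pos": bim.pos.astype(int),
            "ref": bim.a2,  # A2 is the PLINK major/reference allele
            "alt": bim.a1,
            "maf": np.nan,
        }
    )
    return GenotypeSet(variants, dosages, list(fam.iid))


def write_vcf(genotypes: GenotypeSet, path) -> None:
    """Write hard-called genotypes as a minimal VCF (GT field only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individuals)
            + "\n"
        )
        gt_strings = np.array(["0/0", "0/1", "1/1"])
        hard = np.rint(np.clip(genotypes.dosages, 0, 2)).astype(int)
        for (_, v), row in zip(genotypes.variants.iterrows(), hard):
            fields = [
                str(v.chrom),
                str(int(v.pos)),
                v.id,
                str(v.ref),
                str(v.alt),
                ".",
                "PASS",
                ".",
                "GT",
            ] + list(gt_strings[row])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Interval readers (BED, GFF3)
# ---------------------------------------------------------------------------

def read_intervals(path, fmt: str | None = None) -> pd.DataFrame:
    """Read intervals as a DataFrame (chrom, start, end, name), 1-based closed."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.name.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        return read_bed_intervals(path)
    if fmt == "gff3":
        return read_gff3_genes(path)
    raise ValueError(f"unknown interval format {fmt!r}")


def read_bed_intervals(path) -> pd.DataFrame:
    """BED (0-based half-open) -> internal 1-based closed intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
            "name": df[3].astype(str) if df.shape[1] > 3 else "",
        }
    )
    if (out["end"] < out["start"]).any():
        bad = out[out["end"] < out["start"]].iloc[0]
        raise ValueError(f"interval end < start at {bad.chrom}:{bad.start}")
    return out


def write_bed_intervals(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1  # back to 0-based half-open
    out[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


GFF3_COLUMNS = [
    "chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff3_attr(attr: str, key: str) -> str | None:
    for field in attr.split(";"):
        k, _, v = field.strip().partition("=")
        if k == key:
            return v
    return None


def read_gff3(path) -> pd.DataFrame:
    """Raw GFF3 feature table with 1-based closed coordinates (native to GFF3)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=GFF3_COLUMNS,
        dtype={"chrom": str},
    )
    if df.empty:
        return df
    if (df["end"] < df["start"]).any():
        raise ValueError("GFF3 feature with end < start")
    return df


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene intervals (chrom, start, end, name, strand) from a GFF3 file."""
    df = read_gff3(path)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
    genes = df[df["type"] == "gene"].copy()
    names = [
        _gff3_attr(a, "Name") or _gff3_attr(a, "ID") or f"gene{i}"
        for i, a in enumerate(genes["attributes"])
    ]
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].astype(str).to_numpy(),
            "start": genes["start"].astype(int).to_numpy(),
            "end": genes["end"].astype(int).to_numpy(),
            "name": names,
            "strand": genes["strand"].to_numpy(),
        }
    )


def derive_introns(features: pd.DataFrame) -> pd.DataFrame:
    """Intron intervals for each gene: the gene span minus its exons."""
    introns = []
    genes = features[features["type"] == "gene"]
    exons = features[features["type"] == "exon"]
    for _, g in genes.iterrows():
        gid = _gff3_attr(g.attributes, "ID")
        sub = exons[
            exons["attributes"].str.contains(f"Parent={gid}", regex=False)
            if gid
            else (exons["chrom"] == g.chrom)
            & (exons["start"] >= g.start)
            & (exons["end"] <= g.end)
        ]
        sub = sub.sort_values("start")
        last_end = None
        for _, e in sub.iterrows():
            if last_end is not None and e.start > last_end + 1:
                introns.append(
                    {"chrom": g.chrom, "start": last_end + 1, "end": e.start - 1,
                     "name": gid or ""}
                )
            last_end = e.end if last_end is None else max(last_end, e.end)
    return pd.DataFrame(introns, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Dense relationship matrices
# ---------------------------------------------------------------------------

_GRM_MAGIC = b"FMKGRM01"  # 8-byte header for the binary layout


def write_grm(grm: np.ndarray, path, binary: bool = False) -> None:
    grm = np.asarray(grm, dtype=float)
    if binary:
        with open(path, "wb") as fh:
            fh.write(_GRM_MAGIC)
            fh.write(np.array(grm.shape[0], dtype="<i8").tobytes())
            fh.write(grm.astype("<f8").tobytes())
    else:
        np.savetxt(path, grm, fmt="%.15g")


def read_grm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic == _GRM_MAGIC:
            n = int(np.frombuffer(fh.read(8), dtype="<i8")[0])
            grm = np.frombuffer(fh.read(), dtype="<f8").reshape(n, n).copy()
            return grm
    grm = np.loadtxt(path)
    if grm.ndim != 2 or grm.shape[0] != grm.shape[1]:
        raise ValueError(f"{path} is not a square matrix")
    return grm


# ---------------------------------------------------------------------------
# Small-table helpers
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
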