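"""Readers and writers for the pipeline's file formats.

Supported formats:

* PoPoolation2 "sync" pooled allele counts (whitespace-delimited, one
  ``A:T:C:G:N:del`` count column per pool),
* VCF 4.x individual genotypes (via :mod:`cyvcf2`),
* tab-separated tables for pool frequencies, genotypes, sample labels
  and panel manifests (UTF-8, ``#``-prefixed header line).

All genomic positions are 1-based.  Pool frequencies are stored as
*reference*-allele frequencies; the minor allele is resolved downstream
where the relevant pool subset is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

NUCLEOTIDES = ("A", "C", "G", "T")
#: sync column order within each pool field
SYNC_BASES = ("A", "T", "C", "G")
#: sentinel for a missing genotype call
MISSING = -1


class SnpKey(NamedTuple):
    """Identity of a biallelic SNP: chromosome, 1-based position, alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validated(self) -> "SnpKey":
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValidationError(
                f"alleles must be one of {NUCLEOTIDES}, got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt allele identical at {self.chrom}:{self.pos}")
        return self

    def __str__(self) -> str:  # used as a column id in TSVs
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "SnpKey":
        chrom, pos, ref, alt = text.rsplit(":", 3)
        return cls(chrom, int(pos), ref, alt).validated()


class SampleLabel(NamedTuple):
    pool: str
    subspecies: str
    lineage: str


@dataclass
class PoolFreqTable:
    """Biallelic allele depths per (SNP, pool) with derived frequencies.

    ``ref_depth`` and ``alt_depth`` are ``(n_snps, n_pools)`` integer
    arrays.  The reference-allele frequency is ``ref / (ref + alt)`` and
    is undefined (NaN) exactly where the total depth is zero.
    """

    snps: list[SnpKey]
    pools: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        shape = (len(self.snps), len(self.pools))
        if self.ref_depth.shape != shape or self.alt_depth.shape != shape:
            raise ValidationError(
                f"depth arrays must have shape {shape}, got "
                f"{self.ref_depth.shape} / {self.alt_depth.shape}"
            )
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValidationError("allele depths must be non-negative")
        if len(set(self.pools)) != len(self.pools):
            raise ValidationError("pool ids must be unique")
        for snp in self.snps:
            snp.validated()

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    @property
    def freq(self) -> np.ndarray:
        """Reference-allele frequency, NaN where total depth is zero."""
        total = self.depth
        with np.errstate(invalid="ignore"):
            f = np.where(total > 0, self.ref_depth / np.maximum(total, 1), np.nan)
        return f

    def pool_index(self, pool_id: str) -> int:
        try:
            return self.pools.index(pool_id)
        except ValueError:
            raise KeyError(f"unknown pool id {pool_id!r}") from None

    # ---- sync ---------------------------------------------------------

    def to_sync(self, path: str | Path) -> None:
        """Write as PoPoolation2 sync; ref/alt depths go to their base slots."""
        with open(path, "w", encoding="utf-8") as fh:
            for i, snp in enumerate(self.snps):
                cols = [snp.chrom, str(snp.pos), snp.ref]
                ref_slot = SYNC_BASES.index(snp.ref)
                alt_slot = SYNC_BASES.index(snp.alt)
                for j in range(self.n_pools):
                    counts = [0, 0, 0, 0, 0, 0]
                    counts[ref_slot] = int(self.ref_depth[i, j])
                    counts[alt_slot] = int(self.alt_depth[i, j])
                    cols.append(":".join(map(str, counts)))
                fh.write("\t".join(cols) + "\n")

    # ---- frequency TSV ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            header = ["snp"]
            for p in self.pools:
                header += [f"{p}:ref", f"{p}:alt"]
            fh.write("#" + "\t".join(header) + "\n")
            for i, snp in enumerate(self.snps):
                row = [str(snp)]
                for j in range(self.n_pools):
                    row += [str(self.ref_depth[i, j]), str(self.alt_depth[i, j])]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PoolFreqTable":
        header, rows = _read_hashed_tsv(path)
        pool_cols = header[1:]
        if len(pool_cols) % 2 != 0:
            raise FormatError(f"{path}: expected ref/alt column pairs")
        pools = [c[:-4] for c in pool_cols[::2]]
        snps, ref, alt = [], [], []
        for row in rows:
            snps.append(SnpKey.parse(row[0]))
            vals = list(map(int, row[1:]))
            ref.append(vals[::2])
            alt.append(vals[1::2])
        return cls(snps, pools, np.array(ref, dtype=np.int64).reshape(len(snps), len(pools)),
                   np.array(alt, dtype=np.int64).reshape(len(snps), len(pools)))


def read_sync(
    path: str | Path,
    ref_alleles: Mapping[tuple[str, int], str] | None = None,
    noise_floor: int = 1,
    drop_multiallelic: bool = True,
) -> PoolFreqTable:
    """Parse a sync file into a biallelic :class:`PoolFreqTable`.

    The alternate allele at each site is the non-reference base with the
    highest summed count across pools (ties broken in A<C<G<T order).
    Sites where more than one non-reference base exceeds ``noise_floor``
    total reads are flagged as multiallelic and, by default, dropped.

    Parameters
    ----------
    ref_alleles
        Optional ``(chrom, pos) -> base`` map overriding the reference
        base recorded in the file.
    """
    snps: list[SnpKey] = []
    ref_rows: list[list[int]] = []
    alt_rows: list[list[int]] = []
    n_pools: int | None = None
    n_multi = 0

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected chrom, pos, ref and >=1 pool")
            chrom, pos_s, ref = parts[0], parts[1], parts[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            if ref_alleles is not None:
                ref = ref_alleles.get((chrom, pos), ref)
            if ref not in NUCLEOTIDES:
                raise FormatError(f"{path}:{lineno}: reference base {ref!r} not in {NUCLEOTIDES}")

            pool_fields = parts[3:]
            if n_pools is None:
                n_pools = len(pool_fields)
            elif len(pool_fields) != n_pools:
                raise FormatError(
                    f"{path}:{lineno}: {len(pool_fields)} pool columns, expected {n_pools}"
                )

            counts = np.zeros((len(pool_fields), 4), dtype=np.int64)
            for j, fieldtxt in enumerate(pool_fields):
                bits = fieldtxt.split(":")
                if len(bits) != 6:
                    raise FormatError(
                        f"{path}:{lineno}: pool column {j + 1} has {len(bits)} fields, expected 6"
                    )
                try:
                    counts[j] = [int(b) for b in bits[:4]]  # A,T,C,G; N/del ignored
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count in pool column {j + 1}"
                    ) from None
            if (counts < 0).any():
                raise FormatError(f"{path}:{lineno}: negative allele count")

            totals = counts.sum(axis=0)  # per base, across pools
            ref_slot = SYNC_BASES.index(ref)
            nonref = [b for b in NUCLEOTIDES if b != ref]  # A<C<G<T order
            observed = [b for b in nonref if totals[SYNC_BASES.index(b)] > noise_floor]
            if len(observed) > 1:
                n_multi += 1
                if drop_multiallelic:
                    continue
            # alt = non-ref base with maximal summed count; ties by A<C<G<T
            alt = max(nonref, key=lambda b: (totals[SYNC_BASES.index(b)], -nonref.index(b)))
            if totals[SYNC_BASES.index(alt)] == 0:
                alt = nonref[0]
            snps.append(SnpKey(chrom, pos, ref, alt).validated())
            ref_rows.append(counts[:, ref_slot].tolist())
            alt_rows.append(counts[:, SYNC_BASES.index(alt)].tolist())

    if n_pools is None:
        raise FormatError(f"{path}: empty sync file")
    if n_multi:
        warnings.warn(
            f"{path}: {n_multi} site(s) with >2 alleles above the noise floor"
            + (" were dropped" if drop_multiallelic else ""),
            stacklevel=2,
        )
    return PoolFreqTable(
        snps,
        [f"pool{j + 1}" for j in range(n_pools)],
        np.array(ref_rows, dtype=np.int64).reshape(len(snps), n_pools),
        np.array(alt_rows, dtype=np.int64).reshape(len(snps), n_pools),
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix with optional labels.

    ``g`` holds values in {0, 1, 2, MISSING} (MISSING == -1).  ``labels``
    maps each sample id to its (pool, subspecies, lineage) of origin.
    """

    samples: list[str]
    snps: list[SnpKey]
    g: np.ndarray
    labels: dict[str, SampleLabel] | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int8)
        if self.g.shape != (len(self.samples), len(self.snps)):
            raise ValidationError(
                f"genotype array must have shape {(len(self.samples), len(self.snps))}, "
                f"got {self.g.shape}"
            )
        ok = np.isin(self.g, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.g[~ok])
            raise ValidationError(f"genotype values outside {{0,1,2,missing}}: {bad}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample ids must be unique")
        if self.labels is not None:
            missing = [s for s in self.samples if s not in self.labels]
            if missing:
                raise ValidationError(f"samples without labels: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def label_series(self, level: str) -> pd.Series:
        """Per-sample labels at ``level`` in {'pool','subspecies','lineage'}."""
        if self.labels is None:
            raise ValidationError("genotype matrix carries no sample labels")
        return pd.Series(
            [getattr(self.labels[s], level) for s in self.samples], index=self.samples
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present") from None
        return GenotypeMatrix(list(ids), list(self.snps), self.g[rows], self.labels)

    def subset_snps(self, keys: Sequence[SnpKey]) -> "GenotypeMatrix":
        index = {snp: i for i, snp in enumerate(self.snps)}
        try:
            cols = [index[k] for k in keys]
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]} not present in genotype matrix") from None
        return GenotypeMatrix(list(self.samples), list(keys), self.g[:, cols], self.labels)

    # ---- TSV ----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#" + "\t".join(["sample"] + [str(s) for s in self.snps]) + "\n")
            for i, sample in enumerate(self.samples):
                row = ["NA" if v == MISSING else str(v) for v in self.g[i]]
                fh.write("\t".join([sample] + row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 labels: dict[str, SampleLabel] | None = None) -> "GenotypeMatrix":
        header, rows = _read_hashed_tsv(path)
        snps = [SnpKey.parse(c) for c in header[1:]]
        samples = [r[0] for r in rows]
        g = np.full((len(rows), len(snps)), MISSING, dtype=np.int8)
        for i, row in enumerate(rows):
            for j, v in enumerate(row[1:]):
                if v != "NA":
                    g[i, j] = int(v)
        return cls(samples, snps, g, labels)

    # ---- VCF ----------------------------------------------------------

    def to_vcf(self, path: str | Path) -> None:
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(s.chrom for s in self.snps):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples) + "\n"
            )
            for j, snp in enumerate(self.snps):
                gts = "\t".join(gt_map[int(v)] for v in self.g[:, j])
                fh.write(
                    f"{snp.chrom}\t{snp.pos}\t{snp}\t{snp.ref}\t{snp.alt}\t.\t.\t.\tGT\t{gts}\n"
                )


def read_vcf_genotypes(path: str | Path,
                       labels: dict[str, SampleLabel] | None = None) -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are skipped with a warning.  0/0 -> 0, 0/1 -> 1,
    1/1 -> 2, ./. -> missing; sample and record order are preserved.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")
    snps: list[SnpKey] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            n_multi += 1
            continue
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        if gt.shape[0] != len(samples):
            raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks GT calls")
        gt[gt == 3] = MISSING
        snps.append(SnpKey(rec.CHROM, rec.POS, ref, alt).validated())
        cols.append(gt)
    vcf.close()
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} non-biallelic-SNP record(s)", stacklevel=2)
    g = (np.stack(cols, axis=1) if cols
         else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, snps, g, labels)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------


def read_labels(path: str | Path, hierarchy=None) -> dict[str, SampleLabel]:
    """Read a sample->(pool, subspecies, lineage) map from a labels TSV.

    When a :class:`~aimpanel.hierarchy.HierarchyConfig` is supplied, every
    class is validated against it.
    """
    header, rows = _read_hashed_tsv(path)
    expected = ["sample_id", "pool_id", "subspecies", "lineage"]
    if header != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {header}")
    out: dict[str, SampleLabel] = {}
    for row in rows:
        if len(row) != 4:
            raise FormatError(f"{path}: malformed row {row!r}")
        sample, pool, sub, lin = row
        if sample in out:
            raise ValidationError(f"{path}: duplicate sample_id {sample!r}")
        out[sample] = SampleLabel(pool, sub, lin)
    if hierarchy is not None:
        for sample, lab in out.items():
            if lab.pool not in hierarchy.pool_to_subspecies:
                raise ValidationError(f"{path}: sample {sample}: unknown pool {lab.pool!r}")
            if lab.subspecies != hierarchy.pool_to_subspecies[lab.pool]:
                raise ValidationError(
                    f"{path}: sample {sample}: subspecies {lab.subspecies!r} does not match "
                    f"pool {lab.pool!r}"
                )
            if lab.lineage != hierarchy.subspecies_to_lineage[lab.subspecies]:
                raise ValidationError(
                    f"{path}: sample {sample}: lineage {lab.lineage!r} does not match "
                    f"subspecies {lab.subspecies!r}"
                )
    return out


def write_labels(labels: Mapping[str, SampleLabel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#sample_id\tpool_id\tsubspecies\tlineage\n")
        for sample, lab in labels.items():
            fh.write(f"{sample}\t{lab.pool}\t{lab.subspecies}\t{lab.lineage}\n")


# ---------------------------------------------------------------------------
# panel manifest
# ---------------------------------------------------------------------------

PANEL_SOURCES_PREFIXES = ("pca_", "fst_")


class PanelEntry(NamedTuple):
    snp: SnpKey
    source: str      # pca_global, pca_<lineage>, fst_loose, fst_stringent
    focal_unit: str  # "global", a lineage, or a pool id
    score: float


@dataclass
class PanelManifest:
    """The selected AIM set, with the branch, level and score of each SNP."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.snp for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = pd.Series(keys).value_counts()
            dupes = dupes[dupes > 1].index.tolist()
            raise ValidationError(f"duplicate SNPs in panel manifest: {dupes[:5]}")
        for e in self.entries:
            e.snp.validated()
            if not e.source.startswith(PANEL_SOURCES_PREFIXES):
                raise ValidationError(f"unknown panel source {e.source!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def snps(self) -> list[SnpKey]:
        return [e.snp for e in self.entries]

    def validate_against(self, hierarchy) -> None:
        units = {"global"} | set(hierarchy.lineages) | set(hierarchy.pool_to_subspecies)
        for e in self.entries:
            if e.focal_unit not in units:
                raise ValidationError(
                    f"panel entry {e.snp}: focal unit {e.focal_unit!r} not in hierarchy"
                )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#chrom\tpos\tref\talt\tsource\tfocal_unit\tscore\n")
            for e in self.entries:
                fh.write(
                    f"{e.snp.chrom}\t{e.snp.pos}\t{e.snp.ref}\t{e.snp.alt}\t"
                    f"{e.source}\t{e.focal_unit}\t{e.score!r}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "PanelManifest":
        header, rows = _read_hashed_tsv(path)
        expected = ["chrom", "pos", "ref", "alt", "source", "focal_unit", "score"]
        if header != expected:
            raise FormatError(f"{path}: expected columns {expected}, got {header}")
        entries = []
        for row in rows:
            if len(row) != 7:
                raise FormatError(f"{path}: malformed row {row!r}")
            chrom, pos, ref, alt, source, unit, score = row
            entries.append(
                PanelEntry(SnpKey(chrom, int(pos), ref, alt).validated(),
                           source, unit, float(score))
            )
        return cls(entries)


def merge_panels(*panels: PanelManifest) -> PanelManifest:
    """Concatenate panels, skipping SNPs already taken by an earlier panel."""
    seen: set[SnpKey] = set()
    merged: list[PanelEntry] = []
    for panel in panels:
        for e in panel.entries:
            if e.snp not in seen:
                seen.add(e.snp)
                merged.append(e)
    return PanelManifest(merged)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_hashed_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a TSV whose first line is a '#'-prefixed tab-joined header."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path}: missing '#'-prefixed header line")
        header = first[1:].rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    return header, rows
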