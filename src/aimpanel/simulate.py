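"""Hierarchical Balding-Nichols simulation of pool-seq data and genotypes.

Ancestral allele frequencies drift independently down the
lineage -> subspecies -> pool tree under the Balding-Nichols Beta model:
a child frequency given parent frequency ``p`` and divergence ``F`` is

    child ~ Beta(p (1-F)/F, (1-p) (1-F)/F)

so that ``E[child] = p`` and ``Var[child] = F p (1-p)``.  Pooled
sequencing is emulated with Poisson read depths and binomial reference
read counts; individual genotypes are Hardy-Weinberg draws
``Binomial(2, p_pool)``.  Subspecies-specific null alleles (markers that
never produce a genotype call in a subspecies) are modelled as an
all-or-none subspecies x SNP mask.

All randomness flows from a single integer seed, so identical
``(config, seed)`` pairs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .hierarchy import HierarchyConfig
from .io_formats import MISSING, GenotypeMatrix, PoolFreqTable, SampleLabel, SnpKey


def drift_freqs(parent_freqs: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """Drift a frequency vector one level down under Balding-Nichols.

    Frequencies exactly 0 or 1 are already fixed and are passed through
    unchanged; interior frequencies are Beta-distributed around the
    parent value with variance ``F p (1-p)``.
    """
    if not 0.0 < F < 1.0:
        raise ParameterError(f"divergence parameter F must be in (0, 1), got {F}")
    p = np.asarray(parent_freqs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("parent frequencies must lie in [0, 1]")
    child = p.copy()
    interior = (p > 0) & (p < 1)
    scale = (1.0 - F) / F
    child[interior] = rng.beta(p[interior] * scale, (1.0 - p[interior]) * scale)
    return child


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    ancestral: np.ndarray                       # (n_snps,)
    lineage_freqs: pd.DataFrame                 # lineages x snps
    subspecies_freqs: pd.DataFrame              # subspecies x snps
    pool_freqs: pd.DataFrame                    # pools x snps
    planted: np.ndarray                         # (n_snps,) bool
    planted_lineage: list[str | None]           # per planted SNP, its high lineage
    null_mask: pd.DataFrame                     # subspecies x snps bool

    def __post_init__(self) -> None:
        for df in (self.lineage_freqs, self.subspecies_freqs, self.pool_freqs):
            vals = df.to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError("truth frequencies must lie in [0, 1]")
        if self.null_mask.shape[1] != len(self.ancestral):
            raise ValidationError("null mask must be subspecies x n_snps")

    def write(self, directory: str | Path, snps: list[SnpKey]) -> None:
        directory = Path(directory)
        cols = [str(s) for s in snps]
        for name, df in (
            ("truth_lineage_freqs", self.lineage_freqs),
            ("truth_subspecies_freqs", self.subspecies_freqs),
            ("truth_pool_freqs", self.pool_freqs),
        ):
            out = df.copy()
            out.columns = cols
            _write_hashed(out, directory / f"{name}.tsv", index_name="unit")
        mask = self.null_mask.astype(int)
        mask.columns = cols
        _write_hashed(mask, directory / "truth_null_mask.tsv", index_name="subspecies")
        anc = pd.DataFrame(
            {"ancestral_freq": self.ancestral,
             "planted": self.planted.astype(int),
             "planted_lineage": [x if x is not None else "." for x in self.planted_lineage]},
            index=cols,
        )
        _write_hashed(anc, directory / "truth_ancestral.tsv", index_name="snp")


class SimulatedDataset(NamedTuple):
    pool_table: PoolFreqTable
    genotypes: GenotypeMatrix
    labels: dict[str, SampleLabel]
    truth: SimTruth


def simulate_dataset(config: HierarchyConfig, seed: int) -> SimulatedDataset:
    """Simulate pool frequencies, pooled depths and individual genotypes.

    Sites are independent (no linkage).  Planted lineage-diagnostic SNPs,
    if requested, overwrite the drifted lineage frequencies with values
    ``0.5 +/- planted_gap/2`` (one elevated lineage per planted SNP, in
    rotation) before the within-lineage drift.
    """
    rng = np.random.default_rng(seed)
    n = config.n_snps
    lo, hi = config.ancestral_freq_range

    snps = [SnpKey("chr1", i + 1, "A", "C") for i in range(n)]
    p0 = rng.uniform(lo, hi, size=n)

    lineages = config.lineages
    lineage_p = {lin: drift_freqs(p0, config.f_lineage, rng) for lin in lineages}

    planted = np.zeros(n, dtype=bool)
    planted_lineage: list[str | None] = [None] * n
    if config.n_planted:
        idx = rng.choice(n, size=config.n_planted, replace=False)
        lo_f = 0.5 - config.planted_gap / 2
        hi_f = 0.5 + config.planted_gap / 2
        for rank, i in enumerate(np.sort(idx)):
            focal = lineages[rank % len(lineages)]
            planted[i] = True
            planted_lineage[i] = focal
            for lin in lineages:
                lineage_p[lin][i] = hi_f if lin == focal else lo_f

    sub_p: dict[str, np.ndarray] = {}
    pool_p: dict[str, np.ndarray] = {}
    for lin, subs in config.tree.items():
        for sub, pools in subs.items():
            sub_p[sub] = drift_freqs(lineage_p[lin], config.f_subspecies, rng)
            for pool in pools:
                pool_p[pool] = drift_freqs(sub_p[sub], config.f_pool, rng)

    pools = config.pools
    P = np.column_stack([pool_p[p] for p in pools])  # (n_snps, n_pools)

    depth = rng.poisson(config.pool_coverage, size=P.shape)
    ref_depth = rng.binomial(depth, P)
    alt_depth = depth - ref_depth
    pool_table = PoolFreqTable(snps, list(pools), ref_depth, alt_depth)

    # individual genotypes (alt-allele dosage), drawn from the true pool freqs
    p2s = config.pool_to_subspecies
    s2l = config.subspecies_to_lineage
    sample_ids: list[str] = []
    blocks: list[np.ndarray] = []
    labels: dict[str, SampleLabel] = {}
    for pool in pools:
        m = config.n_individuals_per_pool
        g = rng.binomial(2, 1.0 - pool_p[pool], size=(m, n)).astype(np.int8)
        blocks.append(g)
        sub = p2s[pool]
        for i in range(m):
            sid = f"{pool}_{i + 1:03d}"
            sample_ids.append(sid)
            labels[sid] = SampleLabel(pool, sub, s2l[sub])
    genotypes = GenotypeMatrix(sample_ids, snps, np.vstack(blocks), labels)

    subspecies = config.subspecies
    mask = np.zeros((len(subspecies), n), dtype=bool)
    for k, sub in enumerate(subspecies):
        rate = config.null_rate_of(sub)
        if rate > 0:
            mask[k] = rng.random(n) < rate
    null_mask = pd.DataFrame(mask, index=subspecies)
    genotypes = apply_null_alleles(genotypes, null_mask)

    truth = SimTruth(
        ancestral=p0,
        lineage_freqs=pd.DataFrame(
            np.vstack([lineage_p[l] for l in lineages]), index=lineages),
        subspecies_freqs=pd.DataFrame(
            np.vstack([sub_p[s] for s in subspecies]), index=subspecies),
        pool_freqs=pd.DataFrame(P.T, index=list(pools)),
        planted=planted,
        planted_lineage=planted_lineage,
        null_mask=null_mask,
    )
    return SimulatedDataset(pool_table, genotypes, labels, truth)


def sample_individuals_from_freqs(
    pool_table: PoolFreqTable, n: int, seed: int
) -> GenotypeMatrix:
    """Draw ``n`` individuals per pool from the observed pool frequencies.

    Genotypes are Hardy-Weinberg draws ``Binomial(2, p)`` from each
    pool's reference-allele frequency; SNPs with undefined frequency
    (zero depth) in a pool come out missing for that pool's individuals.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    freq = pool_table.freq
    sample_ids: list[str] = []
    blocks: list[np.ndarray] = []
    labels: dict[str, SampleLabel] = {}
    for j, pool in enumerate(pool_table.pools):
        p = freq[:, j]
        defined = ~np.isnan(p)
        g = np.full((n, pool_table.n_snps), MISSING, dtype=np.int8)
        g[:, defined] = rng.binomial(2, 1.0 - p[defined], size=(n, defined.sum()))
        blocks.append(g)
        for i in range(n):
            sid = f"{pool}_sim{i + 1:03d}"
            sample_ids.append(sid)
            labels[sid] = SampleLabel(pool, pool, pool)
    return GenotypeMatrix(sample_ids, pool_table.snps, np.vstack(blocks), labels)


def estimate_f_between(p1: np.ndarray, p2: np.ndarray) -> float:
    """Estimate the per-branch divergence F between two sibling demes.

    Under Balding-Nichols, two demes that each drifted with parameter F
    from a common parent have an expected heterozygosity-form pairwise
    F_ST of about F/2 (the two-deme mean allele frequency absorbs half
    the between-deme variance).  The ratio-of-means estimator across
    loci, doubled, therefore recovers F itself:

        F_hat = 2 * sum(H_T - H_S) / sum(H_T).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    ok = ~(np.isnan(p1) | np.isnan(p2))
    p1, p2 = p1[ok], p2[ok]
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    if ht.sum() <= 0:
        return 0.0
    return float(2.0 * (ht - hs).sum() / ht.sum())


def apply_null_alleles(gm: GenotypeMatrix, mask: pd.DataFrame) -> GenotypeMatrix:
    """Blank out null-allele cells: for every masked (subspecies, SNP),
    all samples of that subspecies become missing at that SNP."""
    mask_arr = mask.to_numpy(dtype=bool)
    if mask_arr.shape[1] != gm.n_snps:
        raise ValidationError(
            f"null mask has {mask_arr.shape[1]} SNP columns, genotype matrix has {gm.n_snps}"
        )
    if gm.labels is None:
        raise ValidationError("genotype matrix needs labels to apply a subspecies mask")
    g = gm.g.copy()
    sub_index = {s: k for k, s in enumerate(mask.index)}
    for i, sample in enumerate(gm.samples):
        sub = gm.labels[sample].subspecies
        if sub in sub_index:
            g[i, mask_arr[sub_index[sub]]] = MISSING
    return GenotypeMatrix(list(gm.samples), list(gm.snps), g, gm.labels)


def _write_hashed(df: pd.DataFrame, path: Path, index_name: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join([index_name] + [str(c) for c in df.columns]) + "\n")
        df.to_csv(fh, sep="\t", header=False)
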