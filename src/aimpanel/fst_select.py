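"""F_ST branch of ancestry-informative marker selection.

Per-SNP pairwise F_ST between all pools uses the heterozygosity form

    F_ST = (H_T - H_S) / H_T,   H_T = 2 p_bar (1 - p_bar),
    H_S = (2 p1 (1 - p1) + 2 p2 (1 - p2)) / 2,   p_bar = (p1 + p2) / 2,

which is 1 for a fixed difference and 0 for identical frequencies.  For
each pool the pairwise values against all other pools are summed per
SNP (a SNP fixed in the focal pool and absent everywhere else in a
22-pool design saturates the bound at 21), SNPs are ranked by the sum,
and each pool contributes its top-ranked SNPs under two site-filter
settings (loose and stringent), skipping SNPs already selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ShortfallError, ValidationError
from .io_formats import PanelEntry, PanelManifest, PoolFreqTable


@dataclass(frozen=True)
class FstSettings:
    """Site-filter thresholds for one F_ST pass.

    A pool pair is eligible at a SNP iff both pools reach ``min_depth``
    and the pair's combined minor-allele read count reaches
    ``min_minor_count``.  Ineligible pairs contribute 0 to the sum.
    """

    mode: str
    min_depth: int
    min_minor_count: int

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ParameterError("min_depth must be >= 1")
        if self.min_minor_count < 0:
            raise ParameterError("min_minor_count must be >= 0")


LOOSE = FstSettings("loose", min_depth=10, min_minor_count=2)
STRINGENT = FstSettings("stringent", min_depth=30, min_minor_count=4)


def pairwise_fst(p1, p2):
    """Heterozygosity-form F_ST between two allele frequencies.

    Accepts scalars or arrays; returns 0 where total heterozygosity is 0
    (both frequencies jointly fixed on the same allele).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for p in (p1, p2):
        valid = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not valid.all():
            raise ParameterError("allele frequencies must lie in [0, 1]")
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    if fst.ndim == 0:
        return float(fst)
    return fst


def site_filter(table: PoolFreqTable, settings: FstSettings) -> np.ndarray:
    """Pair eligibility tensor of shape ``(n_snps, n_pools, n_pools)``.

    ``out[i, j, k]`` is True iff pools j and k both have depth >=
    ``min_depth`` at SNP i and the pair's combined minor-allele count is
    >= ``min_minor_count``.  The diagonal is False.
    """
    depth = table.depth                                   # (S, P)
    deep = depth >= settings.min_depth
    pair_deep = deep[:, :, None] & deep[:, None, :]

    ref_pair = table.ref_depth[:, :, None] + table.ref_depth[:, None, :]
    alt_pair = table.alt_depth[:, :, None] + table.alt_depth[:, None, :]
    minor = np.minimum(ref_pair, alt_pair)
    eligible = pair_deep & (minor >= settings.min_minor_count)

    n_pools = table.n_pools
    eligible[:, np.arange(n_pools), np.arange(n_pools)] = False
    return eligible


def _fst_tensor(table: PoolFreqTable) -> np.ndarray:
    """All pairwise F_ST values, shape ``(n_snps, n_pools, n_pools)``;
    pairs with an undefined frequency come out NaN."""
    p = table.freq
    return np.asarray(pairwise_fst(p[:, :, None], p[:, None, :]))


def summed_fst_all(table: PoolFreqTable, settings: FstSettings) -> np.ndarray:
    """Summed pairwise F_ST ``S[i, j] = sum_{k != j} F_ST(snp i; j, k)``
    over eligible pairs only; shape ``(n_snps, n_pools)``."""
    fst = _fst_tensor(table)
    eligible = site_filter(table, settings)
    contrib = np.where(eligible & ~np.isnan(fst), fst, 0.0)
    return contrib.sum(axis=2)


def _ranking(table: PoolFreqTable, scores: np.ndarray) -> np.ndarray:
    """Indices of SNPs sorted by descending score, ties by (chrom, pos)."""
    chroms = np.array([s.chrom for s in table.snps])
    pos = np.array([s.pos for s in table.snps])
    # lexsort: last key is primary
    return np.lexsort((pos, chroms, -scores))


def summed_fst(table: PoolFreqTable, pool_id: str, settings: FstSettings) -> pd.DataFrame:
    """Ranked summed-F_ST table for one focal pool.

    Returns a DataFrame with columns ``snp_index`` and ``summed_fst``,
    ordered by descending sum with (chrom, pos) tie-breaking.
    """
    j = table.pool_index(pool_id)
    scores = summed_fst_all(table, settings)[:, j]
    order = _ranking(table, scores)
    return pd.DataFrame({"snp_index": order, "summed_fst": scores[order]})


def select_fst_panel(
    table: PoolFreqTable,
    k_loose: int = 20,
    k_stringent: int = 80,
    loose: FstSettings = LOOSE,
    stringent: FstSettings = STRINGENT,
    exclude: set | frozenset = frozenset(),
) -> PanelManifest:
    """Per-pool top-k selection from both F_ST passes, skipping duplicates.

    Pools are processed in table order; for each pool the stringent
    ranking is consumed first (top ``k_stringent``), then the loose
    ranking (top ``k_loose``).  A SNP already selected — by an earlier
    pool, the other setting, or listed in ``exclude`` — is skipped and
    the walk continues down the ranking, so every pool contributes
    exactly ``k_loose + k_stringent`` unique SNPs.
    """
    if loose.mode != "loose" or stringent.mode != "stringent":
        raise ValidationError("settings must be tagged loose / stringent")
    if not (stringent.min_depth >= loose.min_depth
            and stringent.min_minor_count >= loose.min_minor_count):
        raise ValidationError("stringent thresholds must be >= loose thresholds")

    scores = {s.mode: summed_fst_all(table, s) for s in (stringent, loose)}
    if table.n_pools > 1:
        eligible_any = {
            s.mode: site_filter(table, s).any(axis=2) for s in (stringent, loose)
        }
    else:  # degenerate single-pool table: no pairs, rank by depth alone
        eligible_any = {
            s.mode: table.depth >= s.min_depth for s in (stringent, loose)
        }

    selected: set = set(exclude)
    entries: list[PanelEntry] = []
    for j, pool in enumerate(table.pools):
        for settings, quota in ((stringent, k_stringent), (loose, k_loose)):
            if quota == 0:
                continue
            col = scores[settings.mode][:, j]
            order = _ranking(table, col)
            taken = 0
            for i in order:
                if taken == quota:
                    break
                if not eligible_any[settings.mode][i, j]:
                    continue
                snp = table.snps[i]
                if snp in selected:
                    continue
                selected.add(snp)
                entries.append(
                    PanelEntry(snp, f"fst_{settings.mode}", pool, float(col[i]))
                )
                taken += 1
            if taken < quota:
                raise ShortfallError(
                    f"pool {pool!r}: only {taken} eligible unselected SNPs for the "
                    f"{settings.mode} quota of {quota}"
                )
    return PanelManifest(entries)
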