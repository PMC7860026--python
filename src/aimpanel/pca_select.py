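"""PCA branch of ancestry-informative marker selection.

Pools are observations and SNP minor-allele frequencies are variables.
A scaled PCA (columns centred, unit variance) is run on the full pool
set to capture lineage-level structure, then separately on each
lineage's pool subset for within-lineage structure.  At every level the
SNPs with the highest contributions to the significant principal
components are taken, up to a per-level quota, skipping SNPs already
selected at an earlier level.

The contribution of SNP j to component k follows the variable-
contribution convention of scaled PCA: ``ctr(j,k) = 100 coord(j,k)^2 /
lambda_k`` where ``coord`` is the variable coordinate (correlation with
the component), so contributions sum to 100 over SNPs for each PC.
Contributions across several significant PCs are aggregated with
eigenvalue-share weights, so dominant axes dominate selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ShortfallError, ValidationError
from .hierarchy import HierarchyConfig
from .io_formats import PanelEntry, PanelManifest, PoolFreqTable


@dataclass
class MafMatrix:
    """Pools x SNPs minor-allele frequency matrix for one pool subset."""

    values: np.ndarray           # (n_pools_subset, n_kept_snps)
    pool_ids: list[str]
    snp_indices: np.ndarray      # column -> row index into the source table


def build_maf_matrix(table: PoolFreqTable, pool_subset: list[str] | None = None) -> MafMatrix:
    """Minor-allele frequencies over a pool subset, mean-imputed.

    The minor allele of each SNP is the allele whose mean frequency
    across the subset is <= 0.5 (ties resolved to the alt allele, so the
    stored reference-allele frequency is flipped).  Cells with undefined
    frequency (zero depth) are imputed with the SNP's subset mean; SNPs
    undefined in every subset pool are dropped with a warning.
    """
    if pool_subset is None:
        pool_subset = list(table.pools)
    if not pool_subset:
        raise ParameterError("pool subset must be non-empty")
    cols = [table.pool_index(p) for p in pool_subset]
    p_ref = table.freq[:, cols]                     # (n_snps, n_subset)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        mean_ref = np.nanmean(p_ref, axis=1)
    defined = ~np.isnan(mean_ref)
    if not defined.all():
        warnings.warn(
            f"{(~defined).sum()} SNP(s) undefined in all subset pools were dropped",
            stacklevel=2,
        )
    p_ref = p_ref[defined]
    mean_ref = mean_ref[defined]

    minor_is_ref = mean_ref < 0.5                   # tie (0.5) -> minor is alt
    maf = np.where(minor_is_ref[:, None], p_ref, 1.0 - p_ref)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(maf, axis=1)
    nan_cells = np.isnan(maf)
    maf[nan_cells] = np.broadcast_to(col_mean[:, None], maf.shape)[nan_cells]

    return MafMatrix(maf.T, list(pool_subset), np.flatnonzero(defined))


@dataclass
class PcaResult:
    """Eigenvalues, variable coordinates and pool scores of one level.

    ``coords`` has one row per input SNP column (zeros for columns
    dropped as zero-variance) and one column per retained PC.  With
    unit-variance scaling the eigenvalues sum to the number of retained
    (non-constant) columns.
    """

    eigenvalues: np.ndarray      # (n_components,), descending
    coords: np.ndarray           # (n_snps, n_components)
    scores: np.ndarray           # (n_pools, n_components)
    pool_ids: list[str]
    snp_indices: np.ndarray
    level: str = "global"

    def __post_init__(self) -> None:
        if (self.eigenvalues < -1e-9).any():
            raise ValidationError("eigenvalues must be non-negative")
        if (np.diff(self.eigenvalues) > 1e-9).any():
            raise ValidationError("eigenvalues must be non-increasing")


def run_pca(matrix: MafMatrix, level: str = "global") -> PcaResult:
    """Scaled PCA of a pools x SNPs matrix.

    Columns are centred and scaled to unit variance (population
    normalisation, 1/n); zero-variance columns are dropped from the
    decomposition and reported with zero coordinates.  Eigenvalues are
    those of the correlation structure, so they sum to the retained
    column count and at most ``n_pools - 1`` of them are nonzero.
    """
    X = np.asarray(matrix.values, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 pools")
    if p < 2:
        raise ParameterError("PCA needs at least 2 SNPs")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)              # ddof=0: eigenvalues sum to retained count
    keep = sd > 1e-12
    Z = (X[:, keep] - mean[keep]) / sd[keep]

    n_comp = min(n - 1, int(keep.sum()))
    coords = np.zeros((p, n_comp))
    scores = np.zeros((n, n_comp))
    eig = np.zeros(n_comp)
    if n_comp > 0:
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        eig = (S[:n_comp] ** 2) / n
        # variable coordinate = correlation of variable with component
        coords[keep, :] = Vt[:n_comp].T * np.sqrt(eig)
        scores = U[:, :n_comp] * S[:n_comp]
    return PcaResult(eig, coords, scores, list(matrix.pool_ids),
                     matrix.snp_indices, level)


def significant_pcs(result: PcaResult) -> list[int]:
    """Kaiser-style rule: components with eigenvalue strictly above the
    mean eigenvalue; falls back to the first PC when none qualifies."""
    lam = result.eigenvalues
    if lam.size == 0:
        return [0]
    above = np.flatnonzero(lam > lam.mean())
    return above.tolist() if above.size else [0]


def snp_contribution(result: PcaResult, pcs: list[int]) -> np.ndarray:
    """Eigenvalue-weighted aggregate contribution score per SNP.

    Per-PC contributions ``100 coord^2 / lambda`` sum to 100 over SNPs;
    the aggregate weighs each requested PC by its eigenvalue share.
    PCs with zero eigenvalue are skipped.
    """
    lam = result.eigenvalues
    if any(k < 0 or k >= lam.size for k in pcs):
        raise ParameterError(f"requested PCs {pcs} outside available range 0..{lam.size - 1}")
    usable = [k for k in pcs if lam[k] > 1e-12]
    if not usable:
        return np.zeros(result.coords.shape[0])
    weights = lam[usable] / lam[usable].sum()
    score = np.zeros(result.coords.shape[0])
    for w, k in zip(weights, usable):
        ctr = 100.0 * result.coords[:, k] ** 2 / lam[k]
        score += w * ctr
    return score


def hierarchical_pca_select(
    table: PoolFreqTable,
    hierarchy: HierarchyConfig,
    quotas: dict[str, int] | None = None,
    exclude: set | frozenset = frozenset(),
) -> PanelManifest:
    """Quota selection at the global level, then within each lineage.

    The global level uses all pools of the table that appear in the
    hierarchy; each lineage level uses only that lineage's pools.  At
    every level the top-quota SNPs by aggregate contribution to the
    significant PCs are taken (ties broken by (chrom, pos)), skipping
    SNPs selected at an earlier level or listed in ``exclude``.
    """
    if quotas is None:
        quotas = hierarchy.quotas
    levels: list[tuple[str, list[str]]] = []
    if quotas.get("global", 0) > 0:
        levels.append(("global", [p for p in table.pools if p in hierarchy.pool_to_lineage]))
    for lineage in hierarchy.lineages:
        if quotas.get(lineage, 0) > 0:
            pools = [p for p in table.pools if hierarchy.pool_to_lineage.get(p) == lineage]
            if len(pools) < 2:
                raise ValidationError(
                    f"lineage {lineage!r} has {len(pools)} pool(s) in the table; "
                    "quota must be 0"
                )
            levels.append((lineage, pools))

    chroms = np.array([s.chrom for s in table.snps])
    pos = np.array([s.pos for s in table.snps])

    selected: set = set(exclude)
    entries: list[PanelEntry] = []
    for level, pools in levels:
        quota = quotas["global"] if level == "global" else quotas[level]
        matrix = build_maf_matrix(table, pools)
        result = run_pca(matrix, level=level)
        pcs = significant_pcs(result)
        score_kept = snp_contribution(result, pcs)
        scores = np.zeros(table.n_snps)
        scores[matrix.snp_indices] = score_kept
        kept = set(matrix.snp_indices.tolist())
        order = np.lexsort((pos, chroms, -scores))
        source = "pca_global" if level == "global" else f"pca_{level}"
        taken = 0
        for i in order:
            if taken == quota:
                break
            snp = table.snps[i]
            if snp in selected or i not in kept:
                continue
            selected.add(snp)
            entries.append(PanelEntry(snp, source, level, float(scores[i])))
            taken += 1
        if taken < quota:
            raise ShortfallError(
                f"level {level!r}: only {taken} unselected SNPs available for quota {quota}"
            )
    return PanelManifest(entries)
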