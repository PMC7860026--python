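"""Hierarchical population structure: lineages -> subspecies -> pools.

European honey bees (*Apis mellifera*) fall into four deeply diverged
evolutionary lineages (A, C, M, O) that each contain one or more
recently diverged subspecies; each subspecies was pool-sequenced as one
or more population pools.  :class:`HierarchyConfig` carries that tree
together with the per-level drift parameters, simulation sizes and
per-level SNP selection quotas used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ParameterError, ValidationError

Tree = dict[str, dict[str, list[str]]]


@dataclass
class HierarchyConfig:
    """Population tree plus simulation and selection parameters.

    Parameters
    ----------
    tree
        ``{lineage: {subspecies: [pool ids]}}``.  Every pool belongs to
        exactly one subspecies and every subspecies to one lineage.
    f_lineage, f_subspecies, f_pool
        Balding-Nichols divergence parameters in (0, 1) applied at each
        branching level.  Defaults reflect deep lineage divergence with
        shallow differentiation below it.
    n_snps
        Number of independent SNPs to simulate.
    ancestral_freq_range
        Ancestral reference-allele frequencies are drawn uniformly from
        this open subinterval of (0, 1) so that sites segregate.
    pool_coverage
        Mean pooled read depth per SNP per pool (Poisson).
    n_individuals_per_pool
        Individuals genotyped per pool in the simulated reference set.
    null_allele_rate
        Probability that a SNP is a null allele (always missing) in a
        given subspecies; either one global rate or a per-subspecies map.
        The default of 0.13 reproduces a mean individual call rate of
        about 0.87.
    quotas
        Per-level PCA selection quotas: key ``"global"`` plus lineage
        names.  Lineages with fewer than two pools must have quota 0
        (or no entry).
    n_planted, planted_gap
        Optional planted lineage-diagnostic SNPs: ``n_planted`` sites
        receive lineage frequencies separated by ``planted_gap`` before
        the within-lineage drift, providing a known ground truth for
        marker-recovery tests.
    """

    tree: Tree
    f_lineage: float = 0.15
    f_subspecies: float = 0.05
    f_pool: float = 0.02
    n_snps: int = 5000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    pool_coverage: float = 50.0
    n_individuals_per_pool: int = 20
    null_allele_rate: float | dict[str, float] = 0.13
    quotas: dict[str, int] = field(default_factory=dict)
    n_planted: int = 0
    planted_gap: float = 0.8

    def __post_init__(self) -> None:
        if not self.tree:
            raise ValidationError("hierarchy tree is empty")
        pools_seen: set[str] = set()
        subs_seen: set[str] = set()
        for lineage, subs in self.tree.items():
            if not subs:
                raise ValidationError(f"lineage {lineage!r} has no subspecies")
            for sub, pools in subs.items():
                if sub in subs_seen:
                    raise ValidationError(f"subspecies {sub!r} appears in two lineages")
                subs_seen.add(sub)
                if not pools:
                    raise ValidationError(f"subspecies {sub!r} has no pools")
                for pool in pools:
                    if pool in pools_seen:
                        raise ValidationError(f"pool {pool!r} appears twice in the tree")
                    pools_seen.add(pool)
        for name in ("f_lineage", "f_subspecies", "f_pool"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {f}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ParameterError(f"ancestral_freq_range must satisfy 0 < lo < hi < 1, got {lo, hi}")
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        if self.pool_coverage <= 0:
            raise ParameterError("pool_coverage must be positive")
        if self.n_individuals_per_pool < 1:
            raise ParameterError("n_individuals_per_pool must be >= 1")
        rates = (self.null_allele_rate.values()
                 if isinstance(self.null_allele_rate, dict) else [self.null_allele_rate])
        if any(not 0.0 <= r < 1.0 for r in rates):
            raise ParameterError("null_allele_rate must be in [0, 1)")
        if isinstance(self.null_allele_rate, dict):
            unknown = set(self.null_allele_rate) - subs_seen
            if unknown:
                raise ValidationError(f"null_allele_rate for unknown subspecies: {unknown}")
        for level, q in self.quotas.items():
            if level != "global" and level not in self.tree:
                raise ValidationError(f"quota for unknown level {level!r}")
            if q < 0:
                raise ParameterError(f"quota for {level!r} must be >= 0")
            if level != "global" and q > 0 and len(self.pools_of_lineage(level)) < 2:
                raise ValidationError(
                    f"lineage {level!r} has < 2 pools and must have quota 0"
                )
        if self.n_planted < 0 or self.n_planted > self.n_snps:
            raise ParameterError("n_planted must be in [0, n_snps]")
        if not 0.0 < self.planted_gap < 1.0:
            raise ParameterError("planted_gap must be in (0, 1)")

    # ---- derived views ------------------------------------------------

    @property
    def lineages(self) -> list[str]:
        return list(self.tree)

    @property
    def subspecies(self) -> list[str]:
        return [s for subs in self.tree.values() for s in subs]

    @property
    def pools(self) -> list[str]:
        return [p for subs in self.tree.values() for ps in subs.values() for p in ps]

    @property
    def pool_to_subspecies(self) -> dict[str, str]:
        return {p: s for subs in self.tree.values() for s, ps in subs.items() for p in ps}

    @property
    def subspecies_to_lineage(self) -> dict[str, str]:
        return {s: lin for lin, subs in self.tree.items() for s in subs}

    @property
    def pool_to_lineage(self) -> dict[str, str]:
        p2s, s2l = self.pool_to_subspecies, self.subspecies_to_lineage
        return {p: s2l[s] for p, s in p2s.items()}

    def pools_of_lineage(self, lineage: str) -> list[str]:
        return [p for ps in self.tree[lineage].values() for p in ps]

    def null_rate_of(self, subspecies: str) -> float:
        if isinstance(self.null_allele_rate, dict):
            return self.null_allele_rate.get(subspecies, 0.0)
        return self.null_allele_rate

    # ---- (de)serialization --------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ancestral_freq_range"] = list(self.ancestral_freq_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HierarchyConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ValidationError(f"{path}: expected a mapping at top level")
        data = dict(data)
        if "ancestral_freq_range" in data:
            data["ancestral_freq_range"] = tuple(data["ancestral_freq_range"])
        return cls(**data)


def reference_tree() -> Tree:
    """The 4-lineage / 14-subspecies / 22-pool European reference design."""
    return {
        "A": {"ruttneri": ["rut_mlt"]},
        "M": {
            "iberiensis": ["ibe_esp_west_prt", "ibe_esp_eus", "ibe_esp_north",
                           "ibe_esp_south"],
            "mellifera": ["mel_dnk", "mel_irl", "mel_imn", "mel_rus", "mel_che"],
        },
        "C": {
            "adami": ["ada_grc"],
            "carnica": ["car_aut_hun", "car_svn_hrv"],
            "carpatica": ["carp_rou_mda"],
            "cecropia": ["cec_grc"],
            "ligustica": ["lig_ita"],
            "macedonica": ["mac_mkd_grc"],
            "rodopica": ["rod_bgr"],
        },
        "O": {
            "anatoliaca": ["ana_tur"],
            "remipes": ["rem_arm"],
            "caucasia": ["cau_tur_geo"],
            "cypria": ["cyp_cyp"],
        },
    }


#: per-level PCA quotas of the reference panel design (lineage A has a
#: single pool, hence no within-lineage quota)
REFERENCE_QUOTAS = {"global": 300, "M": 200, "O": 600, "C": 1100}


def reference_config(**overrides) -> HierarchyConfig:
    """The default study design: 22 pools, 14 subspecies, 4 lineages."""
    kwargs = dict(tree=reference_tree(), quotas=dict(REFERENCE_QUOTAS))
    kwargs.update(overrides)
    return HierarchyConfig(**kwargs)
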