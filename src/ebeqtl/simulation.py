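"""Synthetic eQTL data and the realized-FDR calibration study.

The generator emulates a dominant-model screen: 10 SNPs typed on 140
samples split 70 carriers / 70 non-carriers, 10,000 transcripts whose
log expression is N(0, 1) for equivalently expressed (EE) pairs and
N(4, 0.5) in the carrier group for differentially expressed (DE) pairs,
with each (SNP, transcript) pair DE independently with probability p1.
Nulls come from 40 balanced permutations of 35 samples per side.  The
study measures the realized (true) FDR — the fraction of declared pairs
that are actually EE — against the controlled level, for the parametric
mixture screen and its nonparametric comparator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GenotypeTable, dominant_groups
from .fdr_inference import npeb_fdr, peb_discoveries
from .null_model import fit_null, null_statistics
from .peb_mixture import apply_pi0_cap, ecme_fit
from .zstats import z_row

__all__ = [
    "SimConfig",
    "SimDataset",
    "StudyResult",
    "simulate_dataset",
    "run_fdr_study",
    "maf_null_quantiles",
]

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions; defaults are the dominant-model design above."""

    n_transcripts: int = 10_000
    n_snps: int = 10
    n_per_group: int = 70
    mafs: tuple[float, ...] | None = None   # default: evenly spaced in [0.25, 0.35]
    p1: float = 0.05
    de_mean: float = 4.0
    de_sd: float = math.sqrt(0.5)
    n_perms: int = 40
    n_swap: int = 35
    controlled_fdr: tuple[float, ...] = (0.01, 0.05, 0.10)
    n_replicates: int = 10
    seed: int = 0
    balance_groups: bool = False            # True: condition on exactly n_per_group carriers

    def __post_init__(self) -> None:
        if not (0 <= self.p1 < 1):
            raise ValueError("p1 must be in [0, 1)")
        if self.de_sd <= 0:
            raise ValueError("de_sd must be positive")
        if self.n_swap > self.n_per_group:
            raise ValueError("n_swap cannot exceed the group size")
        if self.mafs is None:
            # carrier fractions 1-(1-f)^2 in [0.44, 0.58]: dominant groups
            # near the 70/70 design point, so swapping 35 is a balanced
            # half-swap for every SNP without being an exact half-swap
            self.mafs = tuple(np.linspace(0.25, 0.35, self.n_snps))
        if any(not (0 < m <= 0.5) for m in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group


@dataclass
class SimDataset:
    expression: ExpressionMatrix
    genotypes: GenotypeTable
    truth: np.ndarray         # I x J boolean, True = DE
    config: SimConfig = field(repr=False)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _simulate_genotype_row(config: SimConfig, maf: float, rng: np.random.Generator) -> np.ndarray:
    """One SNP's 0/1/2 codes for all samples."""
    n = config.n_samples
    if config.balance_groups:
        # exactly n_per_group carriers; het vs hom among carriers by
        # HWE conditional on carrying: P(hom | carrier) = maf / (2 - maf)
        codes = np.zeros(n, dtype=np.int64)
        carriers = rng.permutation(n)[: config.n_per_group]
        hom = rng.random(config.n_per_group) < maf / (2.0 - maf)
        codes[carriers] = np.where(hom, 2, 1)
        return codes
    probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
    floor = max(2, config.n_swap)
    for _ in range(100):
        codes = rng.choice(3, size=n, p=probs)
        n1 = int((codes >= 1).sum())
        if min(n1, n - n1) >= floor:
            return codes.astype(np.int64)
    raise RuntimeError(f"could not draw a non-degenerate genotype at MAF {maf}")


def simulate_dataset(config: SimConfig, seed: int | np.random.Generator | None = None) -> SimDataset:
    """Draw genotypes, DE truth and log expression under the study design.

    A sample's expression for transcript j follows the DE law
    N(de_mean, de_sd^2) when it carries the minor allele of any SNP for
    which j is DE, and the EE law N(0, 1) otherwise; with at most one DE
    SNP per transcript this is exactly the two-group design.
    """
    rng = _rng(config.seed if seed is None else seed)
    I, J, n = config.n_snps, config.n_transcripts, config.n_samples
    codes = np.vstack([_simulate_genotype_row(config, m, rng) for m in config.mafs])
    truth = rng.random((I, J)) < config.p1
    carriers = codes >= 1
    shifted = (truth.T.astype(np.int8) @ carriers.astype(np.int8)) > 0   # J x n
    ee = rng.standard_normal((J, n))
    de = config.de_mean + config.de_sd * rng.standard_normal((J, n))
    values = np.where(shifted, de, ee)
    expr = ExpressionMatrix(
        [f"T{j + 1}" for j in range(J)], [f"S{s + 1}" for s in range(n)], values
    )
    # population MAF is stored explicitly: at MAF near 0.5 the realized
    # sample frequency of the designated minor allele can exceed 0.5
    geno = GenotypeTable(
        [f"G{i + 1}" for i in range(I)], list(expr.sample_ids), codes,
        maf=np.asarray(config.mafs, dtype=float),
    )
    return SimDataset(expression=expr, genotypes=geno, truth=truth, config=config)


@dataclass
class StudyResult:
    """Realized FDR grid over (DE fraction x controlled FDR x method)."""

    table: pd.DataFrame       # columns: p1, controlled_fdr, method, realized_fdr,
    #                           mc_se, n_discoveries, n_fits
    n_failed: int = 0

    def pivot(self, value: str = "realized_fdr") -> pd.DataFrame:
        """The grid in the layout of the published calibration table."""
        return self.table.pivot_table(
            index="p1", columns=["method", "controlled_fdr"], values=value
        )

    def cell(self, p1: float, alpha: float, method: str) -> float:
        t = self.table
        row = t[
            (np.isclose(t.p1, p1)) & (np.isclose(t.controlled_fdr, alpha)) & (t.method == method)
        ]
        return float(row.realized_fdr.iloc[0])


def _fdp(mask: np.ndarray, truth_row: np.ndarray) -> float:
    """False discovery proportion; 0 when nothing is declared."""
    n_disc = int(mask.sum())
    if n_disc == 0:
        return 0.0
    return float((mask & ~truth_row).sum() / n_disc)


def run_fdr_study(
    config: SimConfig,
    p1_values: tuple[float, ...] | None = None,
    methods: tuple[str, ...] = ("peb", "npeb"),
) -> StudyResult:
    """Realized FDR of the FDR-controlled screens over the study grid.

    For every replicate and SNP the full pipeline runs from scratch:
    regularized statistics, balanced-permutation null, ECME mixture fit
    (with the pi0 cap), discovery at each controlled level, and the
    nonparametric comparator on the same statistics.  Realized FDR in a
    cell averages the false discovery proportion over all (replicate,
    SNP) fits; the Monte-Carlo SE is computed across replicate means.
    A SNP whose mixture fit fails is skipped and counted.
    """
    p1_grid = tuple(p1_values) if p1_values is not None else (config.p1,)
    rows = []
    n_failed = 0
    for p1 in p1_grid:
        cfg = replace(config, p1=p1)
        # cell accumulators: (alpha, method) -> list of per-replicate FDP lists
        fdps: dict[tuple[float, str], list[list[float]]] = {
            (a, m): [] for a in cfg.controlled_fdr for m in methods
        }
        ndisc: dict[tuple[float, str], list[int]] = {
            (a, m): [] for a in cfg.controlled_fdr for m in methods
        }
        p_tag = int(round(p1 * 1000))
        for rep in range(cfg.n_replicates):
            rep_fdp: dict[tuple[float, str], list[float]] = {k: [] for k in fdps}
            for i in range(cfg.n_snps):
                # each SNP is an independent screen: DE shifts for one
                # SNP must not leak into another SNP's null as they
                # would in a single shared expression matrix
                ss = np.random.SeedSequence([cfg.seed, p_tag, rep, i])
                data_rng, perm_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
                snp_cfg = replace(cfg, n_snps=1, mafs=(cfg.mafs[i],))
                ds = simulate_dataset(snp_cfg, data_rng)
                groups = dominant_groups(ds.genotypes, 0)
                try:
                    z_raw, _, a0 = z_row(ds.expression.values, groups)
                    z_null = null_statistics(
                        ds.expression.values, groups, a0, cfg.n_swap, cfg.n_perms, perm_rng
                    )
                    null = fit_null(z_null, n_perms=cfg.n_perms, n_swap=cfg.n_swap)
                    z = null.standardize(z_raw)
                    params, _ = ecme_fit(z, nu0=null.nu0)
                    params = apply_pi0_cap(z, params)
                except Exception:
                    log.warning("fit failed for SNP %d (p1=%g, rep=%d); skipped", i, p1, rep)
                    n_failed += 1
                    continue
                z_null_std = null.standardize(z_null)
                truth_row = ds.truth[0]
                for alpha in cfg.controlled_fdr:
                    if "peb" in methods:
                        disc = peb_discoveries(z, params, alpha)
                        rep_fdp[(alpha, "peb")].append(_fdp(disc.mask, truth_row))
                        ndisc[(alpha, "peb")].append(disc.n_discoveries)
                    if "npeb" in methods:
                        nfit = npeb_fdr(z, z_null_std, alpha)
                        rep_fdp[(alpha, "npeb")].append(_fdp(nfit.discoveries.mask, truth_row))
                        ndisc[(alpha, "npeb")].append(nfit.discoveries.n_discoveries)
            for key, vals in rep_fdp.items():
                if vals:
                    fdps[key].append(vals)
        for (alpha, method), rep_lists in fdps.items():
            flat = [v for rep in rep_lists for v in rep]
            if not flat:
                continue
            rep_means = np.array([np.mean(r) for r in rep_lists])
            mc_se = (
                float(rep_means.std(ddof=1) / np.sqrt(len(rep_means)))
                if len(rep_means) > 1
                else float("nan")
            )
            rows.append(
                {
                    "p1": p1,
                    "controlled_fdr": alpha,
                    "method": method,
                    "realized_fdr": float(np.mean(flat)),
                    "mc_se": mc_se,
                    "n_discoveries": float(np.mean(ndisc[(alpha, method)])),
                    "n_fits": len(flat),
                }
            )
    return StudyResult(table=pd.DataFrame(rows), n_failed=n_failed)


QUANTILE_LEVELS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.50, 0.80, 0.85, 0.90, 0.95, 0.99)


def maf_null_quantiles(
    mafs: tuple[float, ...],
    config: SimConfig | None = None,
    levels: tuple[float, ...] = QUANTILE_LEVELS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation-null quantiles of the statistic across MAF choices.

    For each MAF a pure-noise dataset is simulated with genotypes drawn
    unconditionally under Hardy-Weinberg equilibrium (so the dominant
    groups are as unbalanced as that MAF implies), the balanced
    permutation null is computed, and its quantiles are tabulated.
    Rows are MAFs, columns quantile levels.
    """
    config = config or SimConfig(n_transcripts=2000, n_replicates=1)
    out = {}
    base_seed = config.seed if seed is None else seed
    for idx, maf in enumerate(mafs):
        cfg = replace(
            config, p1=0.0, n_snps=1, mafs=(maf,), balance_groups=False, n_swap=0
        )
        ss = np.random.SeedSequence([base_seed, idx])
        data_rng, perm_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        ds = simulate_dataset(cfg, data_rng)
        groups = dominant_groups(ds.genotypes, 0)
        n = groups.n1 + groups.n0
        n_swap = round(groups.n1 * groups.n0 / n)  # effect-cancelling balanced swap
        _, _, a0 = z_row(ds.expression.values, groups)
        z_null = null_statistics(
            ds.expression.values, groups, a0, n_swap, config.n_perms, perm_rng
        )
        out[maf] = np.quantile(z_null, levels)
    return pd.DataFrame(out, index=list(levels)).T.rename_axis("maf")
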