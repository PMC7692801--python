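"""QTN power/MSE simulation framework.

Genotypes emulate an inbred-line (selfing) panel with an Arabidopsis-like
allele-frequency spectrum: each marker draws an allele frequency uniformly
on a configurable range (default 0.1-0.5) and individuals are homozygous,
so calls are 0 or 2 with P(2) equal to that frequency, independently across
markers (no linkage disequilibrium by default; an optional block-copy
generator adds local LD for sensitivity runs).

Phenotypes follow ``y = mu + sum_k x_k beta_k + u + eps`` with iid residual
noise of variance sigma_e^2 = 10, population mean 10, fixed QTN effects,
and an optional polygenic draw ``u ~ MVN(0, sigma_pg^2 K)`` with K the
realized relatedness matrix of the simulated genotypes.

The default eight-QTN design uses heritabilities (0.01, 0.03, 0.03, 0.05,
0.08, 0.01, 0.05, 0.05), whose sum gives a total genetic heritability of
0.31, with the corresponding effects 0.4328, 0.7497, 0.9679 and 1.2243
(effects scale with the square root of the heritability).

Power for a QTN is the fraction of replicates in which a final call matches
it (same simulated marker by default; a +/- window under the LD generator);
MSE averages the squared estimation error over the replicates in which the
QTN was detected and is undefined (NaN, rendered "na") when never detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hrepml.io_formats import GenotypeTable, PhenotypeVector
from hrepml.kinship import compute_kinship, spectral_decompose
from hrepml.pipeline import AssociationConfig, run_association

__all__ = [
    "QTNSpec",
    "SimulationConfig",
    "EvaluationSummary",
    "default_qtns",
    "total_heritability",
    "simulate_genotypes",
    "simulate_phenotype",
    "compute_power",
    "compute_mse",
    "run_power_study",
]


@dataclass(frozen=True)
class QTNSpec:
    """One simulated causal marker: its index, fixed effect and bookkeeping h^2."""

    index: int
    effect: float
    heritability: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("QTN effect must be finite")
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("QTN heritability must lie in [0, 1)")


#: (heritability, effect) of the eight-QTN reference design; marker indices
#: are placed at these genome fractions, spread over five chromosomes the
#: way the published layout is (two on chromosome 1, two on 3, three on 4,
#: one on 5).
_DESIGN_FRACTIONS = (0.040, 0.064, 0.451, 0.493, 0.608, 0.646, 0.661, 0.828)
_DESIGN_H2_EFFECT = (
    (0.01, 0.4328),
    (0.03, 0.7497),
    (0.03, 0.7497),
    (0.05, 0.9679),
    (0.08, 1.2243),
    (0.01, 0.4328),
    (0.05, 0.9679),
    (0.05, 0.9679),
)


def default_qtns(n_markers: int = 10_000) -> list[QTNSpec]:
    """The eight-QTN reference design mapped onto ``n_markers`` markers."""
    qtns = []
    for frac, (h2, eff) in zip(_DESIGN_FRACTIONS, _DESIGN_H2_EFFECT):
        qtns.append(QTNSpec(index=int(round(frac * n_markers)), effect=eff, heritability=h2))
    if len({q.index for q in qtns}) != len(qtns):
        raise ValueError(f"QTN indices collide at n_markers={n_markers}; use more markers")
    return qtns


def total_heritability(qtns) -> float:
    """Bookkeeping total genetic heritability: the sum of per-QTN h^2."""
    return float(sum(q.heritability for q in qtns))


@dataclass
class SimulationConfig:
    """One simulation design (sample size, marker panel, QTNs, variances).

    ``polygenic_variance`` of 0 disables the polygenic draw.  ``ld_rho``
    (0 by default) turns on the block-LD generator: each marker copies its
    left neighbour's calls with that probability.  ``match_window`` is the
    +/- marker-index window for declaring a call a detection of a QTN
    (0 = exact marker).
    """

    n_individuals: int = 500
    n_markers: int = 10_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    qtns: list[QTNSpec] | None = None
    residual_variance: float = 10.0
    population_mean: float = 10.0
    polygenic_variance: float = 0.0
    n_replicates: int = 100
    seed: int = 1
    n_chromosomes: int = 5
    ld_rho: float = 0.0
    match_window: int = 0

    def __post_init__(self) -> None:
        if self.qtns is None:
            self.qtns = default_qtns(self.n_markers)
        if self.residual_variance <= 0:
            raise ValueError("residual variance must be positive")
        if self.polygenic_variance < 0:
            raise ValueError("polygenic variance must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < low <= high < 1")
        idx = [q.index for q in self.qtns]
        if len(set(idx)) != len(idx):
            raise ValueError("QTN marker indices must be distinct")
        if any(i < 0 or i >= self.n_markers for i in idx):
            raise ValueError("QTN marker indices must lie within the marker panel")


@dataclass
class EvaluationSummary:
    """Per-QTN and average power/MSE over the completed replicates."""

    qtns: list[QTNSpec]
    power: np.ndarray  # per-QTN detection fraction, percent
    mse: np.ndarray  # per-QTN MSE over detections; NaN when never detected
    detections: np.ndarray  # per-QTN detection counts
    n_replicates: int
    n_failed: int = 0
    chromosome: np.ndarray | None = None
    position: np.ndarray | None = None

    @property
    def average_power(self) -> float:
        """Average detection power over QTNs, percent."""
        return float(np.mean(self.power))

    @property
    def average_mse(self) -> float:
        """Average MSE over the QTNs that were detected at least once."""
        return float(np.nanmean(self.mse))

    def to_frame(self) -> pd.DataFrame:
        """Tabular summary (one QTN per row, 'na' for undefined MSE)."""
        return pd.DataFrame(
            {
                "qtn": np.arange(1, len(self.qtns) + 1),
                "chromosome": self.chromosome if self.chromosome is not None else pd.NA,
                "position": self.position if self.position is not None else pd.NA,
                "heritability": [q.heritability for q in self.qtns],
                "effect": [q.effect for q in self.qtns],
                "power_pct": self.power,
                "mse": ["na" if np.isnan(v) else v for v in self.mse],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _marker_metadata(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    m = config.n_markers
    per = int(np.ceil(m / config.n_chromosomes))
    idx = np.arange(m)
    chrom = idx // per + 1
    pos = (idx % per + 1) * 1000
    return chrom, pos


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator) -> GenotypeTable:
    """Draw an inbred-panel genotype table under the configured MAF spectrum."""
    m, n = config.n_markers, config.n_individuals
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    calls = 2.0 * (rng.random((m, n)) < freqs[:, None])
    if config.ld_rho > 0.0:
        chrom, _ = _marker_metadata(config)
        copy = rng.random(m) < config.ld_rho
        for j in range(1, m):
            if copy[j] and chrom[j] == chrom[j - 1]:
                calls[j] = calls[j - 1]
    chrom, pos = _marker_metadata(config)
    return GenotypeTable(chrom, pos, calls)


def simulate_phenotype(
    G: GenotypeTable,
    config: SimulationConfig,
    rng: np.random.Generator,
    kinship=None,
) -> tuple[PhenotypeVector, np.ndarray]:
    """Phenotype draw; returns (y, polygenic component u) for diagnostics.

    ``u`` is identically zero when the polygenic variance is zero; otherwise
    it is a multivariate-normal draw with covariance sigma_pg^2 times the
    (supplied or freshly computed) relatedness matrix of ``G``.
    """
    n = G.sample_count
    idx = np.array([q.index for q in config.qtns], dtype=int)
    effects = np.array([q.effect for q in config.qtns], dtype=float)
    genetic = G.sample_major()[:, idx] @ effects
    u = np.zeros(n)
    if config.polygenic_variance > 0.0:
        if kinship is None:
            kinship = compute_kinship(G)
        basis = spectral_decompose(kinship)
        z = rng.standard_normal(n)
        u = basis.eigenvectors @ (np.sqrt(basis.eigenvalues * config.polygenic_variance) * z)
    eps = rng.normal(0.0, np.sqrt(config.residual_variance), size=n)
    y = config.population_mean + genetic + u + eps
    return PhenotypeVector(y), u


def compute_power(calls_per_replicate, qtns, window: int = 0) -> np.ndarray:
    """Per-QTN detection fraction (in [0, 1]) over replicates.

    ``calls_per_replicate`` is a sequence of arrays of called marker
    indices; a QTN counts as detected in a replicate when some call lies
    within ``window`` markers of its index.
    """
    n_rep = len(calls_per_replicate)
    out = np.zeros(len(qtns))
    if n_rep == 0:
        return out
    for calls in calls_per_replicate:
        calls = np.asarray(calls)
        for k, q in enumerate(qtns):
            if calls.size and np.any(np.abs(calls - q.index) <= window):
                out[k] += 1.0
    return out / n_rep


def compute_mse(estimates_per_qtn, qtns) -> np.ndarray:
    """Per-QTN mean squared error of the effect estimates over detections.

    ``estimates_per_qtn[k]`` collects the estimated effect of QTN k in each
    replicate that detected it; an empty collection yields NaN ("na").
    """
    out = np.full(len(qtns), np.nan)
    for k, q in enumerate(qtns):
        est = np.asarray(estimates_per_qtn[k], dtype=float)
        if est.size:
            out[k] = float(np.mean((est - q.effect) ** 2))
    return out


def run_power_study(
    config: SimulationConfig,
    assoc_config: AssociationConfig | None = None,
) -> EvaluationSummary:
    """Monte-Carlo power/MSE evaluation of the full two-stage pipeline.

    Every replicate draws fresh genotypes and phenotypes, runs the complete
    association pipeline (kinship, spectral scan, screening, penalized fit,
    LOD >= cutoff calls) and records which QTNs were matched and with what
    effect estimates.  Replicate seeds derive deterministically from the
    master seed.  Replicate-level failures are warned about and excluded.
    """
    if config.n_replicates <= 0:
        raise ValueError("need at least one replicate")
    assoc_config = assoc_config or AssociationConfig()
    qtns = config.qtns
    window = config.match_window
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    calls_per_rep: list[np.ndarray] = []
    estimates: list[list[float]] = [[] for _ in qtns]
    failed = 0
    chrom = pos = None
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        try:
            G = simulate_genotypes(config, rng)
            K = compute_kinship(G)
            y, _ = simulate_phenotype(G, config, rng, kinship=K)
            res = run_association(G, y, kinship=K, config=assoc_config)
        except Exception as exc:  # pragma: no cover - defensive
            failed += 1
            warnings.warn(f"replicate failed and was excluded: {exc}", RuntimeWarning)
            continue
        if chrom is None:
            chrom = G.chromosome[[q.index for q in qtns]]
            pos = G.position[[q.index for q in qtns]]
        called = res.selected_markers
        effects = {int(i): rec.effect for i, rec in zip(called, res.records)}
        calls_per_rep.append(called)
        for k, q in enumerate(qtns):
            if called.size:
                near = called[np.abs(called - q.index) <= window]
                if near.size:
                    hit = int(near[np.argmin(np.abs(near - q.index))])
                    estimates[k].append(effects[hit])
    power = compute_power(calls_per_rep, qtns, window) * 100.0
    mse = compute_mse(estimates, qtns)
    detections = np.array([len(e) for e in estimates])
    return EvaluationSummary(
        qtns=list(qtns),
        power=power,
        mse=mse,
        detections=detections,
        n_replicates=len(calls_per_rep),
        n_failed=failed,
        chromosome=chrom,
        position=pos,
    )
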